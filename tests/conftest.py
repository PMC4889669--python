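import numpy as np
import pandas as pd
import pytest

from dmscan import (
    CrossDesign,
    CrossKind,
    GenotypeTable,
    MarkerDef,
    MarkerPanel,
    SimConfig,
    default_panel,
    simulate_cross,
)
from dmscan.markers import META_COLUMNS


@pytest.fixture(scope="session")
def panel25() -> MarkerPanel:
    return default_panel()


@pytest.fixture(scope="session")
def panel2() -> MarkerPanel:
    """Two unlinked markers on distinct chromosomes."""
    return MarkerPanel([MarkerDef("A", "1", 0.0), MarkerDef("B", "2", 0.0)])


def make_meta(n: int, **overrides) -> pd.DataFrame:
    base = {
        "individual_id": [f"ind{i}" for i in range(n)],
        "cross_id": "c1",
        "design": CrossKind.F2_INTERCROSS.value,
        "f1_parent_sex": "NA",
        "recurrent_population": "NA",
        "maternal_population": "P2",
        "sex": "F",
        "stage": "ADULT",
        "temperature_C": 20.0,
    }
    base.update(overrides)
    return pd.DataFrame(base, columns=list(META_COLUMNS))


@pytest.fixture
def tiny_table(panel2) -> GenotypeTable:
    """3 individuals x 2 markers, one missing call."""
    calls = np.array([[0, 1], [1, -1], [2, 2]], dtype=np.int8)
    return GenotypeTable(panel2, make_meta(3), calls)


@pytest.fixture(scope="session")
def f2_table(panel25) -> GenotypeTable:
    """Null (no-selection) F2 intercross, n=400, fixed seed."""
    cfg = SimConfig(
        panel=panel25,
        design=CrossDesign(kind=CrossKind.F2_INTERCROSS),
        n_offspring=400,
        seed=20260921,
    )
    return simulate_cross(cfg)
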