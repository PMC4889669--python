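#!/usr/bin/env python
"""Simulate the reciprocal F2 intercross dataset used by the later steps.

Two reciprocal F2 crosses (DA: P2/SD grandmother; AD: P1/AB grandmother) at
sample sizes in the range of the motivating experiment (388 and 298 adults),
with:

* near-lethal P2/P2 viability across all five chromosome-3 markers
  (w = (1, 1, 0.05) at each), the study system's dominant signal;
* one epistatic double-homozygote lethal pair (4b x 8a), placed on
  otherwise-neutral chromosomes so the interacting genotype class actually
  segregates (an interaction nested inside a near-lethal marginal class is
  undetectable in principle);
* a polygenic sex effect at a chromosome-2 marker, producing a biased sex
  ratio and sex-genotype association.

Writes results/markers.tsv and results/genotypes_f2.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from dmscan import (
    CrossDesign,
    CrossKind,
    SexModel,
    SimConfig,
    ViabilityModel,
    default_panel,
    write_genotype_table,
    write_marker_panel,
)
from dmscan.io import META_COLUMNS
from dmscan.markers import GenotypeTable
from dmscan.simulate import simulate_cross

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260921

CHR3 = ("3a", "3b", "3c", "3d", "3e")


def study_like_viability() -> ViabilityModel:
    epi = np.ones((3, 3))
    epi[2, 2] = 0.0  # P2/P2 x P2/P2 jointly lethal
    return ViabilityModel(
        single_locus={m: (1.0, 1.0, 0.05) for m in CHR3},
        epistatic=[(("4b", "8a"), epi)],
    )


def main() -> None:
    panel = default_panel()
    vm = study_like_viability()
    sex = SexModel(kind="polygenic", effects=(("2a", 0.8),))
    tables = []
    for cross_id, maternal, n, seed_off in (("DA1", "P2", 388, 1), ("AD1", "P1", 298, 2)):
        cfg = SimConfig(
            panel=panel,
            design=CrossDesign(kind=CrossKind.F2_INTERCROSS),
            n_offspring=n,
            seed=SEED + seed_off,
            viability=vm,
            sex_model=sex,
            maternal_population=maternal,
            cross_id=cross_id,
            temperature_C=20.0,
        )
        tables.append(simulate_cross(cfg))
    merged = GenotypeTable(
        panel,
        pd.concat([t.meta for t in tables], ignore_index=True)[list(META_COLUMNS)],
        np.vstack([t.calls for t in tables]),
    )
    OUT.mkdir(exist_ok=True)
    write_marker_panel(panel, OUT / "markers.tsv")
    write_genotype_table(merged, OUT / "genotypes_f2.tsv")
    for t in tables:
        f = (t.meta["sex"] == "F").mean()
        print(
            f"{t.meta['cross_id'].iloc[0]}: {t.n_individuals} F2 adults, "
            f"female fraction {f:.2f}"
        )
    print(f"wrote {OUT / 'genotypes_f2.tsv'}")


if __name__ == "__main__":
    main()
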