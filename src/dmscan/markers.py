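"""Marker panels, cross metadata and genotype tables.

Genotypes in an inter-population cross are scored as population-of-origin
classes, not nucleotide alleles: an individual at a marker is homozygous for
parental population 1 (``HOM_P1``, code 0), heterozygous (``HET``, code 1),
homozygous for population 2 (``HOM_P2``, code 2) or unscored (``MISSING``,
code -1).  The two population labels ("P1"/"P2") are dataset-level constants
(for the motivating system they are the AB and SD *Tigriopus californicus*
populations).

A :class:`GenotypeTable` couples a :class:`MarkerPanel` with an
individuals x markers call matrix and per-individual stratification metadata
(cross identity, cross design, maternal population / mtDNA background, sex,
life stage, temperature).  This module never drops rows; complete-case
handling belongs to the statistics modules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Callable, Dict, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .results import GenotypeCounts

POP1 = "P1"
POP2 = "P2"

HOM_P1 = 0
HET = 1
HOM_P2 = 2
MISSING = -1

VALID_CODES = frozenset({HOM_P1, HET, HOM_P2, MISSING})

SEXES = ("F", "M", "UNKNOWN")
STAGES = ("NAUPLIUS_D1", "NAUPLIUS_D2", "NAUPLIUS", "ADULT")

#: canonical metadata columns of a genotype table, in file order
META_COLUMNS = (
    "individual_id",
    "cross_id",
    "design",
    "f1_parent_sex",
    "recurrent_population",
    "maternal_population",
    "sex",
    "stage",
    "temperature_C",
)


class CrossKind(str, Enum):
    F2_INTERCROSS = "F2_INTERCROSS"
    BACKCROSS = "BACKCROSS"
    BC2_INTERCROSS = "BC2_INTERCROSS"


@dataclass(frozen=True)
class CrossDesign:
    """Experimental cross design and its Mendelian expectation.

    ``f1_parent_sex`` records, for a backcross, which parent is the F1
    hybrid; ``recurrent_population`` which parental population the F1 was
    crossed back to.  Both are "NA" where not applicable.
    """

    kind: CrossKind
    f1_parent_sex: str = "NA"
    recurrent_population: str = "NA"

    def __post_init__(self) -> None:
        if self.f1_parent_sex not in ("F", "M", "NA"):
            raise ConfigError(f"invalid f1_parent_sex {self.f1_parent_sex!r}")
        if self.recurrent_population not in (POP1, POP2, "NA"):
            raise ConfigError(
                f"invalid recurrent_population {self.recurrent_population!r}"
            )
        if self.kind is CrossKind.BACKCROSS and self.recurrent_population == "NA":
            raise ConfigError("BACKCROSS requires a recurrent_population")

    def expected_ratio(self) -> Tuple[float, float, float]:
        """Expected (HOM_P1, HET, HOM_P2) class proportions under Mendel.

        F2 intercross and the focal chromosome of a het x het second-
        generation backcross intercross segregate 1:2:1; a backcross
        segregates 1:1 between the heterozygote and the homozygote for the
        recurrent population, the other homozygote class being impossible.
        """
        if self.kind in (CrossKind.F2_INTERCROSS, CrossKind.BC2_INTERCROSS):
            return (0.25, 0.5, 0.25)
        if self.recurrent_population == POP1:
            return (0.5, 0.5, 0.0)
        return (0.0, 0.5, 0.5)


@dataclass(frozen=True)
class MarkerDef:
    """One mapped SNP marker: id, chromosome label, map position in cM."""

    marker_id: str
    chromosome: str
    position_cM: float

    def __post_init__(self) -> None:
        if not self.marker_id:
            raise DataError("marker_id must be non-empty")
        if not (math.isfinite(self.position_cM) and self.position_cM >= 0):
            raise DataError(
                f"marker {self.marker_id!r}: position_cM must be finite and >= 0, "
                f"got {self.position_cM!r}"
            )


class MarkerPanel:
    """Ordered marker set spanning a finite set of chromosomes.

    Order is file order; within a chromosome, map positions must be
    nondecreasing in that order.
    """

    def __init__(self, markers: Sequence[MarkerDef]):
        markers = tuple(markers)
        if not markers:
            raise DataError("a marker panel needs at least one marker")
        seen: Dict[str, int] = {}
        for i, m in enumerate(markers):
            if m.marker_id in seen:
                raise DataError(f"duplicate marker_id {m.marker_id!r} in panel")
            seen[m.marker_id] = i
        last_pos: Dict[str, float] = {}
        for m in markers:
            prev = last_pos.get(m.chromosome)
            if prev is not None and m.position_cM < prev:
                raise DataError(
                    f"marker {m.marker_id!r}: position {m.position_cM} cM "
                    f"decreases along chromosome {m.chromosome!r}"
                )
            last_pos[m.chromosome] = m.position_cM
        self.markers: Tuple[MarkerDef, ...] = markers
        self._index = seen
        # chromosomes in order of first appearance
        self.chromosomes: Tuple[str, ...] = tuple(dict.fromkeys(m.chromosome for m in markers))

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_ids(self) -> List[str]:
        return [m.marker_id for m in self.markers]

    def index_of(self, marker_id: str) -> int:
        try:
            return self._index[marker_id]
        except KeyError:
            raise DataError(f"unknown marker {marker_id!r}") from None

    def marker(self, marker_id: str) -> MarkerDef:
        return self.markers[self.index_of(marker_id)]

    def chromosome_of(self, marker_id: str) -> str:
        return self.marker(marker_id).chromosome

    def chrom_indices(self) -> Dict[str, np.ndarray]:
        """Column indices of each chromosome's markers, in panel order."""
        out: Dict[str, List[int]] = {c: [] for c in self.chromosomes}
        for i, m in enumerate(self.markers):
            out[m.chromosome].append(i)
        return {c: np.asarray(v, dtype=int) for c, v in out.items()}

    def chrom_sizes(self) -> Dict[str, int]:
        return {c: len(v) for c, v in self.chrom_indices().items()}

    def positions(self, chromosome: str) -> np.ndarray:
        return np.asarray(
            [m.position_cM for m in self.markers if m.chromosome == chromosome],
            dtype=float,
        )

    def __eq__(self, other: object) -> bool:
        return isinstance(other, MarkerPanel) and self.markers == other.markers


#: a stratum may be: None (everyone), a metadata column->value mapping,
#: a callable over the metadata frame returning a boolean mask, or a mask.
StratumSpec = Union[None, Mapping[str, object], Callable[[pd.DataFrame], Sequence[bool]], np.ndarray]


def resolve_stratum(table: "GenotypeTable", stratum: StratumSpec) -> np.ndarray:
    """Turn a stratum specification into a boolean individual mask."""
    n = table.n_individuals
    if stratum is None:
        return np.ones(n, dtype=bool)
    if isinstance(stratum, Mapping):
        mask = np.ones(n, dtype=bool)
        for col, val in stratum.items():
            if col not in table.meta.columns:
                raise DataError(f"unknown metadata column {col!r} in stratum")
            mask &= (table.meta[col] == val).to_numpy()
        return mask
    if callable(stratum):
        mask = np.asarray(stratum(table.meta), dtype=bool)
    else:
        mask = np.asarray(stratum, dtype=bool)
    if mask.shape != (n,):
        raise DataError(f"stratum mask has shape {mask.shape}, expected ({n},)")
    return mask


class GenotypeTable:
    """Individuals x markers genotype calls plus per-individual metadata."""

    def __init__(self, panel: MarkerPanel, meta: pd.DataFrame, calls: np.ndarray):
        calls = np.asarray(calls, dtype=np.int8)
        if calls.ndim != 2 or calls.shape[1] != panel.n_markers:
            raise DataError(
                f"call matrix shape {calls.shape} does not match panel of "
                f"{panel.n_markers} markers"
            )
        if len(meta) != calls.shape[0]:
            raise DataError(
                f"{len(meta)} metadata rows for {calls.shape[0]} call rows"
            )
        missing_cols = [c for c in META_COLUMNS if c not in meta.columns]
        if missing_cols:
            raise DataError(f"metadata missing columns: {missing_cols}")
        bad = set(np.unique(calls)) - VALID_CODES
        if bad:
            raise DataError(f"invalid genotype codes in call matrix: {sorted(bad)}")
        meta = meta.reset_index(drop=True)
        self._validate_meta(meta)
        self.panel = panel
        self.meta = meta
        self.calls = calls

    @staticmethod
    def _validate_meta(meta: pd.DataFrame) -> None:
        if len(meta) == 0:
            return
        allowed = {
            "design": {k.value for k in CrossKind},
            "maternal_population": {POP1, POP2},
            "sex": set(SEXES),
            "stage": set(STAGES) | {"NA"},
            "f1_parent_sex": {"F", "M", "NA"},
            "recurrent_population": {POP1, POP2, "NA"},
        }
        for col, values in allowed.items():
            bad = ~meta[col].isin(values)
            if bad.any():
                i = int(np.nonzero(bad.to_numpy())[0][0])
                raise DataError(
                    f"row {i}: invalid {col} {meta[col].iloc[i]!r}"
                )
        # one design per cross
        key_cols = ["cross_id", "design", "f1_parent_sex", "recurrent_population"]
        uniq = meta[key_cols].drop_duplicates()
        dup = uniq["cross_id"].duplicated()
        if dup.any():
            cross = uniq["cross_id"][dup].iloc[0]
            raise DataError(f"cross {cross!r} has inconsistent design metadata")

    @property
    def n_individuals(self) -> int:
        return self.calls.shape[0]

    def design_of(self, row: int) -> CrossDesign:
        r = self.meta.iloc[row]
        return CrossDesign(
            kind=CrossKind(r["design"]),
            f1_parent_sex=r["f1_parent_sex"],
            recurrent_population=r["recurrent_population"],
        )

    def subset(self, stratum: StratumSpec) -> "GenotypeTable":
        mask = resolve_stratum(self, stratum)
        return GenotypeTable(self.panel, self.meta.loc[mask], self.calls[mask])

    def equals(self, other: "GenotypeTable") -> bool:
        if self.panel != other.panel or not np.array_equal(self.calls, other.calls):
            return False
        a, b = self.meta, other.meta
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if c == "temperature_C":
                x = a[c].astype(float).to_numpy()
                y = b[c].astype(float).to_numpy()
                if not np.array_equal(np.isnan(x), np.isnan(y)):
                    return False
                if not np.array_equal(x[~np.isnan(x)], y[~np.isnan(y)]):
                    return False
            elif not a[c].astype(str).equals(b[c].astype(str)):
                return False
        return True


def marginal_counts(
    table: GenotypeTable, marker: str, stratum: StratumSpec = None
) -> GenotypeCounts:
    """Three-class genotype counts (plus missing) at one marker in a stratum.

    The four counts always sum to the stratum size.
    """
    j = table.panel.index_of(marker)
    mask = resolve_stratum(table, stratum)
    col = table.calls[mask, j]
    n0 = int(np.sum(col == HOM_P1))
    n1 = int(np.sum(col == HET))
    n2 = int(np.sum(col == HOM_P2))
    nm = int(np.sum(col == MISSING))
    return GenotypeCounts(n=(n0, n1, n2), n_missing=nm)


def default_panel() -> MarkerPanel:
    """The 25-marker, 12-chromosome fixture panel.

    Chromosome marker counts (1,3,5,3,2,2,1,4,1,1,1,1) and the letter-suffixed
    marker names follow the motivating study's marker labels; map positions
    are arbitrary (evenly spaced at 20 cM within each chromosome) since true
    positions are not part of the analysis contract.
    """
    counts = {
        "1": 1, "2": 3, "3": 5, "4": 3, "5": 2, "6": 2,
        "7": 1, "8": 4, "9": 1, "10": 1, "11": 1, "12": 1,
    }
    markers: List[MarkerDef] = []
    for chrom, k in counts.items():
        for i in range(k):
            suffix = chr(ord("a") + i) if k > 1 else ""
            name = f"{chrom}{suffix}"
            if chrom == "10":
                name = "10a"  # study labels the single chr-10 marker "10a"
            markers.append(MarkerDef(name, chrom, 20.0 * i))
    return MarkerPanel(markers)
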