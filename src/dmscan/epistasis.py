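"""Two- and three-locus nonindependence tests for hybrid incompatibilities.

A Dobzhansky-Muller incompatibility removes particular *combinations* of
genotypes at two or more loci.  Because hybrid crosses also show strong
single-locus distortion, a joint-genotype test must absorb the lower-order
deviations before asking about interaction:

* two loci: the expected 3x3 table is the outer product of the *observed*
  (distorted) marginals divided by n — exactly the textbook independence
  chi-square, which by construction conditions away any purely single-locus
  selection;
* three loci: the no-three-way-interaction expected table is obtained by
  iterative proportional fitting (IPF) to all three observed two-way margins
  — the maximum-entropy table with the observed pairwise structure — and the
  chi-square measures only what pairwise structure cannot explain.

Only marker tuples on pairwise distinct chromosomes are enumerated by
default: physical linkage makes intra-chromosomal nonindependence expected,
not epistatic.  Multiple testing is handled by Bonferroni over the
enumerated family (276 pairs / 1780 triples for the default 25-marker,
12-chromosome panel).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError, DegenerateStatisticError
from .markers import GenotypeTable, MarkerPanel, MISSING, StratumSpec, resolve_stratum
from .results import TestResult

EXPECTED_CELL_FLOOR = 1e-12
SPARSE_CELL_WARN = 1.0  # Cochran-style guidance threshold


@dataclass(frozen=True)
class JointCounts2:
    """Complete-case 3x3 joint genotype counts for a marker pair."""

    counts: np.ndarray  # (3, 3) int
    n: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3) or np.any(c < 0) or int(c.sum()) != self.n:
            raise DataError("invalid 3x3 joint counts")


@dataclass(frozen=True)
class JointCounts3:
    """Complete-case 3x3x3 joint genotype counts for a marker triple."""

    counts: np.ndarray  # (3, 3, 3) int
    n: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (3, 3, 3) or np.any(c < 0) or int(c.sum()) != self.n:
            raise DataError("invalid 3x3x3 joint counts")


@dataclass(frozen=True)
class TestEnumeration:
    """The family of inter-chromosomal marker tuples tested together."""

    order: int
    tuples: Tuple[Tuple[str, ...], ...]
    n_tests: int


def joint_counts(
    table: GenotypeTable,
    markers: Sequence[str],
    stratum: StratumSpec = None,
) -> Union[JointCounts2, JointCounts3]:
    """Complete-case joint genotype counts at 2 or 3 markers.

    Individuals missing at *any* listed marker are excluded here but still
    contribute to single-marker marginal scans.
    """
    markers = tuple(markers)
    if len(markers) not in (2, 3):
        raise DataError(f"joint counts need 2 or 3 markers, got {len(markers)}")
    if len(set(markers)) != len(markers):
        raise DataError(f"duplicate markers in {markers}")
    idx = [table.panel.index_of(m) for m in markers]
    mask = resolve_stratum(table, stratum)
    cols = table.calls[np.ix_(mask, idx)]
    complete = np.all(cols != MISSING, axis=1)
    cols = cols[complete]
    k = len(markers)
    counts = np.zeros((3,) * k, dtype=int)
    np.add.at(counts, tuple(cols[:, j] for j in range(k)), 1)
    n = int(counts.sum())
    return JointCounts2(counts, n) if k == 2 else JointCounts3(counts, n)


def _collapse_axes(counts: np.ndarray) -> Tuple[np.ndarray, List[int]]:
    """Drop genotype classes empty on each axis; error if an axis degenerates."""
    c = np.asarray(counts, dtype=float)
    sizes = []
    for ax in range(c.ndim):
        other = tuple(a for a in range(c.ndim) if a != ax)
        keep = c.sum(axis=other) > 0
        if keep.sum() < 2:
            raise DegenerateStatisticError(
                f"locus {ax + 1} has a single non-empty genotype class"
            )
        c = np.compress(keep, c, axis=ax)
        sizes.append(int(keep.sum()))
    return c, sizes


def two_locus_test(joint: JointCounts2) -> TestResult:
    """Independence chi-square on the joint table with observed marginals.

    E_ij = row_i * col_j / n uses the observed (possibly heavily distorted)
    single-locus marginals, so purely single-locus viability selection at
    either or both loci leaves the statistic calibrated.  Empty genotype
    classes are collapsed first; df = (rows-1)*(cols-1), i.e. 4 for a full
    3x3 table.
    """
    if joint.n < 1:
        raise DegenerateStatisticError("empty joint table")
    c, (r, k) = _collapse_axes(joint.counts)
    n = c.sum()
    exp = np.outer(c.sum(axis=1), c.sum(axis=0)) / n
    chi2 = float(((c - exp) ** 2 / exp).sum())
    df = (r - 1) * (k - 1)
    return TestResult(
        statistic=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        method="two_locus_chi2",
        n_used=int(n),
    )


def ipf_fit_no_three_way(
    joint: JointCounts3, tol: float = 1e-10, max_iter: int = 500
) -> np.ndarray:
    """No-three-way-interaction expected table by iterative proportional fitting.

    Cycles scaling updates over the three two-way margins of the observed
    table until every fitted margin matches its observed counterpart within
    ``tol``.  The fixed point is the unique maximum-entropy (log-linear,
    all-pairwise-terms) table with those margins.  Cells whose observed
    two-way margins are all zero stay zero.
    """
    if tol <= 0:
        raise ConfigError("tol must be positive")
    obs = np.asarray(joint.counts, dtype=float)
    if joint.n < 1:
        raise DegenerateStatisticError("empty joint table")
    margins = [obs.sum(axis=2), obs.sum(axis=1), obs.sum(axis=0)]  # AB, AC, BC
    sum_axes = [2, 1, 0]
    fit = np.ones_like(obs)
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(max_iter):
            for tgt, ax in zip(margins, sum_axes):
                cur = fit.sum(axis=ax)
                ratio = np.where(cur > 0, tgt / np.where(cur > 0, cur, 1.0), 0.0)
                fit = fit * np.expand_dims(ratio, axis=ax)
            disc = max(
                float(np.abs(fit.sum(axis=ax) - tgt).max())
                for tgt, ax in zip(margins, sum_axes)
            )
            if disc < tol:
                return fit
    raise DegenerateStatisticError(
        f"IPF did not converge in {max_iter} iterations "
        f"(margin discrepancy {disc:.3g})"
    )


def three_locus_test(
    joint: JointCounts3,
    df_policy: str = "paper_12",
    tol: float = 1e-10,
    max_iter: int = 500,
) -> TestResult:
    """Three-locus interaction chi-square against the IPF pairwise-null.

    ``df_policy``:

    * ``"paper_12"`` (default): 12 df for a full 3x3x3 table, matching the
      convention of the motivating study's printed thresholds;
    * ``"loglinear_8"``: (3-1)^3 = 8 df, the saturated-minus-pairwise
      parameter count of the log-linear model.

    Empty genotype classes are collapsed first (both policies then fall back
    to the log-linear (a-1)(b-1)(c-1) count for the reduced table); expected
    cells below a floor of 1e-12 are structural zeros, excluded from the sum
    with one df removed each.
    """
    if df_policy not in ("paper_12", "loglinear_8"):
        raise ConfigError(f"unknown df_policy {df_policy!r}")
    c, (a, b, d) = _collapse_axes(joint.counts)
    sub = JointCounts3.__new__(JointCounts3)  # bypass 3x3x3 shape check
    object.__setattr__(sub, "counts", c.astype(int))
    object.__setattr__(sub, "n", int(c.sum()))
    exp = ipf_fit_no_three_way(sub, tol=tol, max_iter=max_iter)
    keep = exp > EXPECTED_CELL_FLOOR
    n_excluded = int((~keep).sum())
    chi2 = float(((c[keep] - exp[keep]) ** 2 / exp[keep]).sum())
    if (a, b, d) == (3, 3, 3) and df_policy == "paper_12":
        base_df = 12
    else:
        base_df = (a - 1) * (b - 1) * (d - 1)
    df = max(base_df - n_excluded, 1)
    return TestResult(
        statistic=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        method=f"three_locus_chi2_{df_policy}",
        n_used=int(c.sum()),
    )


def _tuple_statistic(
    table: GenotypeTable,
    markers: Sequence[str],
    stratum: StratumSpec,
    df_policy: str,
) -> TestResult:
    jc = joint_counts(table, markers, stratum)
    if isinstance(jc, JointCounts2):
        return two_locus_test(jc)
    return three_locus_test(jc, df_policy=df_policy)


def permutation_p(
    table: GenotypeTable,
    markers: Sequence[str],
    stratum: StratumSpec = None,
    n_perm: int = 999,
    seed: Optional[int] = None,
    df_policy: str = "paper_12",
) -> TestResult:
    """Permutation p-value for a two- or three-locus chi-square.

    One marker's genotype column is shuffled within the stratum, preserving
    every single-locus marginal while breaking the joint structure;
    p = (1 + #{permuted chi2 >= observed}) / (1 + n_perm).  Permutations on
    which the statistic is degenerate are counted as exceedances
    (conservative).  A seed is required for reproducibility.
    """
    if n_perm < 1:
        raise ConfigError("n_perm must be >= 1")
    if seed is None:
        raise ConfigError("permutation_p requires a seed")
    observed = _tuple_statistic(table, markers, stratum, df_policy)
    rng = np.random.default_rng(seed)
    mask = resolve_stratum(table, stratum)
    rows = np.nonzero(mask)[0]
    j0 = table.panel.index_of(markers[0])
    calls = table.calls.copy()
    base_col = calls[rows, j0].copy()
    shadow = GenotypeTable(table.panel, table.meta, calls)
    exceed = 0
    for _ in range(n_perm):
        calls[rows, j0] = base_col[rng.permutation(len(rows))]
        try:
            stat = _tuple_statistic(shadow, markers, stratum, df_policy).statistic
        except DegenerateStatisticError:
            exceed += 1
            continue
        if stat >= observed.statistic - 1e-12:
            exceed += 1
    return TestResult(
        statistic=observed.statistic,
        df=observed.df,
        p_value=(1 + exceed) / (1 + n_perm),
        method=f"permutation[{observed.method}]",
        n_used=observed.n_used,
    )


def enumerate_tests(
    panel: MarkerPanel, order: int, policy: str = "inter_chromosomal_only"
) -> TestEnumeration:
    """All marker pairs/triples eligible for interaction testing.

    Under the default policy, only tuples whose markers lie on pairwise
    distinct chromosomes are tested.  For the study's 25-marker panel this
    yields 276 pairs and 1780 triples — the Bonferroni denominators.
    """
    if order not in (2, 3):
        raise ConfigError(f"order must be 2 or 3, got {order}")
    if policy not in ("inter_chromosomal_only", "all"):
        raise ConfigError(f"unknown enumeration policy {policy!r}")
    tuples = []
    for combo in combinations(panel.markers, order):
        if policy == "inter_chromosomal_only":
            if len({m.chromosome for m in combo}) != order:
                continue
        tuples.append(tuple(m.marker_id for m in combo))
    return TestEnumeration(order=order, tuples=tuple(tuples), n_tests=len(tuples))


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance threshold controlling family-wise error."""
    if n_tests < 1:
        raise ConfigError(f"n_tests must be >= 1, got {n_tests}")
    if not (0.0 < family_alpha < 1.0):
        raise ConfigError(f"family_alpha must be in (0, 1), got {family_alpha}")
    return family_alpha / n_tests


def chi2_upper_quantile(p: float, df: int) -> float:
    """x such that P(Chi2_df >= x) = p."""
    if not (0.0 < p < 1.0):
        raise ConfigError(f"p must be in (0, 1), got {p}")
    if df < 1:
        raise ConfigError(f"df must be >= 1, got {df}")
    return float(stats.chi2.isf(p, df))


def chi2_upper_tail(x: float, df: int) -> float:
    """P(Chi2_df >= x)."""
    if x < 0:
        raise ConfigError(f"x must be >= 0, got {x}")
    if df < 1:
        raise ConfigError(f"df must be >= 1, got {df}")
    return float(stats.chi2.sf(x, df))


INTERACTION_COLUMNS = [
    "stratum", "locus1", "locus2", "locus3", "n_complete", "chi2", "df", "p",
    "p_perm", "alpha_bonf", "n_tests", "significant_bonf", "significant_p001",
    "error",
]

RELAXED_P = 0.001  # secondary reporting threshold (P < 0.001 convention)


def interaction_scan(
    table: GenotypeTable,
    order: int,
    strata: Optional[Dict[str, StratumSpec]] = None,
    *,
    policy: str = "inter_chromosomal_only",
    df_policy: str = "paper_12",
    family_alpha: float = 0.05,
    n_perm: int = 0,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Interaction chi-squares for every enumerated tuple, per stratum.

    Rows are ranked within stratum by chi-square descending (ties broken by
    tuple lexicographic order).  Each row carries both the Bonferroni
    decision at ``family_alpha`` / n_tests and the relaxed p < 0.001 flag.
    Degenerate tuples are flagged rows, not aborts.
    """
    if strata is None:
        strata = {"all": None}
    enum = enumerate_tests(table.panel, order, policy)
    if enum.n_tests == 0:
        return pd.DataFrame(columns=INTERACTION_COLUMNS)
    alpha = bonferroni_alpha(family_alpha, enum.n_tests)
    if n_perm > 0 and seed is None:
        raise ConfigError("permutation p-values require a seed")
    frames = []
    for s_idx, (name, spec) in enumerate(strata.items()):
        rows: List[dict] = []
        for t_idx, tup in enumerate(enum.tuples):
            row = dict.fromkeys(INTERACTION_COLUMNS, np.nan)
            row.update(
                stratum=name,
                locus1=tup[0], locus2=tup[1],
                locus3=tup[2] if order == 3 else "",
                alpha_bonf=alpha, n_tests=enum.n_tests,
                significant_bonf=0, significant_p001=0, error="",
            )
            try:
                jc = joint_counts(table, tup, spec)
                row["n_complete"] = jc.n
                res = (
                    two_locus_test(jc)
                    if order == 2
                    else three_locus_test(jc, df_policy=df_policy)
                )
                row.update(
                    chi2=res.statistic, df=res.df, p=res.p_value,
                    significant_bonf=int(res.p_value < alpha),
                    significant_p001=int(res.p_value < RELAXED_P),
                )
                if n_perm > 0:
                    perm = permutation_p(
                        table, tup, spec, n_perm=n_perm,
                        seed=seed + 1009 * s_idx + t_idx,
                        df_policy=df_policy,
                    )
                    row["p_perm"] = perm.p_value
            except (DataError, DegenerateStatisticError) as exc:
                row["error"] = str(exc)
            rows.append(row)
        frame = pd.DataFrame(rows, columns=INTERACTION_COLUMNS)
        frame = frame.sort_values(
            by=["chi2", "locus1", "locus2", "locus3"],
            ascending=[False, True, True, True],
            na_position="last",
            kind="mergesort",
        ).reset_index(drop=True)
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)
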