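"""Single-locus segregation statistics.

Distortion of offspring genotype frequencies away from the Mendelian
expectation of the cross (1:2:1 in an F2 intercross, 1:1 in a backcross) is
the first-line signal of viability selection on hybrid genotypes.  This
module provides:

* :func:`gof_test` — Pearson chi-square goodness of fit to arbitrary class
  proportions, with structural zeros (the impossible homozygote class of a
  backcross) excluded rather than treated as observed zeros;
* :func:`exact_multinomial_test` — a small-sample exact alternative that
  sums the probabilities of all outcomes no more probable than the observed
  one;
* :func:`relative_viability` — homozygote survival relative to the
  heterozygote class, w = 2*n_hom/n_het, with delta-method standard errors;
* :func:`heterogeneity_test` — a groups x classes contingency chi-square for
  comparing genotype ratios between strata (reciprocal crosses, sexes,
  temperatures, developmental stages);
* :func:`single_locus_scan` — the per-marker, per-stratum sweep with
  Bonferroni bookkeeping.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, DegenerateStatisticError
from .markers import GenotypeTable, StratumSpec, marginal_counts, resolve_stratum
from .results import GenotypeCounts, RelativeViability, TestResult


def _normalize_ratio(expected_ratio: Sequence[float]) -> np.ndarray:
    p = np.asarray(expected_ratio, dtype=float)
    if p.ndim != 1 or np.any(p < 0) or not np.all(np.isfinite(p)):
        raise DataError(f"invalid expected ratio {expected_ratio!r}")
    s = p.sum()
    if s <= 0:
        raise DataError("expected ratio sums to zero")
    return p / s


def gof_test(counts: GenotypeCounts, expected_ratio: Sequence[float]) -> TestResult:
    """Pearson chi-square goodness of fit of genotype counts to a ratio.

    Classes with expected proportion zero are structural (impossible under
    the cross design): an observed count there is an error, and they do not
    contribute to the statistic or the degrees of freedom.  df = (number of
    possible classes) - 1.  The expected ratio may be given unnormalized
    (e.g. (1, 2, 1)).
    """
    p = _normalize_ratio(expected_ratio)
    obs = np.asarray(counts.n, dtype=float)
    if obs.shape != p.shape:
        raise DataError(
            f"{len(obs)} observed classes vs {len(p)} expected proportions"
        )
    structural = p == 0
    if np.any(obs[structural] > 0):
        bad = int(np.nonzero(obs * structural)[0][0])
        raise DataError(
            f"observed count {int(obs[bad])} in class {bad}, which is "
            "impossible under the cross design (expected proportion 0)"
        )
    obs = obs[~structural]
    p = p[~structural]
    n = obs.sum()
    if n == 0:
        raise DegenerateStatisticError("no scored individuals")
    if len(obs) < 2:
        raise DegenerateStatisticError("fewer than two possible classes")
    exp = n * p
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    df = len(obs) - 1
    return TestResult(
        statistic=chi2,
        df=df,
        p_value=float(stats.chi2.sf(chi2, df)),
        method="pearson_gof",
        n_used=int(n),
    )


def _compositions(n: int, k: int):
    """All ordered count vectors of length k summing to n."""
    if k == 1:
        yield (n,)
        return
    for first in range(n + 1):
        for rest in _compositions(n - first, k - 1):
            yield (first,) + rest


def exact_multinomial_test(
    counts: GenotypeCounts,
    expected_ratio: Sequence[float],
    cap: int = 200,
) -> TestResult:
    """Exact multinomial test by full enumeration.

    The p-value sums the probabilities of every outcome vector whose
    multinomial probability does not exceed the observed one (with a small
    relative tolerance for floating-point ties).  The statistic field carries
    -2*log of the observed probability; df is reported as the sentinel 0
    because no chi-square reference is involved.  N above ``cap`` raises,
    pointing to :func:`gof_test`.
    """
    p = _normalize_ratio(expected_ratio)
    obs = np.asarray(counts.n, dtype=int)
    if obs.shape != p.shape:
        raise DataError(
            f"{len(obs)} observed classes vs {len(p)} expected proportions"
        )
    structural = p == 0
    if np.any(obs[structural] > 0):
        raise DataError("observed count in a zero-expectation class")
    obs = obs[~structural]
    p = p[~structural]
    n = int(obs.sum())
    if n == 0:
        raise DegenerateStatisticError("no scored individuals")
    if n > cap:
        raise DataError(
            f"N={n} exceeds the exact-test cap ({cap}); use gof_test"
        )
    dist = stats.multinomial(n, p)
    p_obs = float(dist.pmf(obs))
    tol = 1e-9
    p_val = 0.0
    for outcome in _compositions(n, len(p)):
        prob = float(dist.pmf(outcome))
        if prob <= p_obs * (1 + tol):
            p_val += prob
    p_val = min(p_val, 1.0)
    stat = -2.0 * math.log(p_obs) if p_obs > 0 else float("inf")
    return TestResult(
        statistic=stat,
        df=0,
        p_value=p_val,
        method="exact_multinomial",
        n_used=n,
    )


def relative_viability(counts: GenotypeCounts) -> RelativeViability:
    """Relative viability of each homozygote class vs the heterozygotes.

    Under the expected 1 : 2 homozygote : heterozygote ratio,
    w = 2*n_hom/n_het is 1 for an undistorted class and 0 exactly when no
    homozygotes were observed.  SE(w) = w*sqrt(1/n_hom + 1/n_het) by the
    delta method on the count ratio; undefined (None) when n_hom = 0.
    Requires at least one heterozygote (the reference class).
    """
    n0, n1, n2 = counts.n
    if n1 == 0:
        raise DegenerateStatisticError(
            "no heterozygotes: relative viability reference class is empty"
        )

    def one(n_hom: int) -> Tuple[float, Optional[float]]:
        w = 2.0 * n_hom / n1
        if n_hom == 0:
            return 0.0, None
        return w, w * math.sqrt(1.0 / n_hom + 1.0 / n1)

    w1, se1 = one(n0)
    w2, se2 = one(n2)
    return RelativeViability(w_hom_p1=w1, w_hom_p2=w2, se_p1=se1, se_p2=se2)


def heterogeneity_test(
    counts_by_group: Sequence[GenotypeCounts],
    df: Optional[int] = None,
) -> TestResult:
    """Pearson contingency chi-square comparing genotype ratios across groups.

    Classes empty in every group (e.g. the impossible homozygote class of a
    backcross) are collapsed before the statistic; df is the textbook
    (groups-1)*(classes-1) after collapse unless overridden.
    """
    if len(counts_by_group) < 2:
        raise DataError("heterogeneity test needs at least two groups")
    tab = np.asarray([g.n for g in counts_by_group], dtype=float)
    if np.any(tab.sum(axis=1) == 0):
        raise DegenerateStatisticError("a group has no scored individuals")
    tab = tab[:, tab.sum(axis=0) > 0]
    if tab.shape[1] < 2:
        raise DegenerateStatisticError(
            "fewer than two genotype classes present across groups"
        )
    n = tab.sum()
    exp = np.outer(tab.sum(axis=1), tab.sum(axis=0)) / n
    chi2 = float(((tab - exp) ** 2 / exp).sum())
    use_df = df if df is not None else (tab.shape[0] - 1) * (tab.shape[1] - 1)
    if use_df < 1:
        raise DataError(f"invalid df {use_df}")
    return TestResult(
        statistic=chi2,
        df=use_df,
        p_value=float(stats.chi2.sf(chi2, use_df)),
        method="heterogeneity_chi2",
        n_used=int(n),
    )


SCAN_COLUMNS = [
    "marker_id", "chromosome", "stratum", "n0", "n1", "n2", "n_missing",
    "w_P1", "se_P1", "w_P2", "se_P2", "chi2", "df", "p",
    "bonferroni_alpha", "significant", "method", "error",
]


def _stratum_expected_ratio(
    table: GenotypeTable, mask: np.ndarray
) -> Tuple[float, float, float]:
    """Derive the Mendelian expectation shared by all individuals in a stratum."""
    rows = np.nonzero(mask)[0]
    ratios = {table.design_of(int(i)).expected_ratio() for i in rows}
    if len(ratios) != 1:
        raise DataError(
            "stratum mixes cross designs with different Mendelian "
            "expectations; pass expected_ratio explicitly"
        )
    return ratios.pop()


def single_locus_scan(
    table: GenotypeTable,
    strata: Optional[Dict[str, StratumSpec]] = None,
    *,
    expected_ratio: Optional[Sequence[float]] = None,
    family_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-marker goodness-of-fit and relative-viability sweep.

    One row per (marker, stratum).  The Bonferroni threshold divides
    ``family_alpha`` by the number of markers (so 25 markers at 0.05 flag at
    p < 0.002).  Per-marker statistical failures (all-missing columns, empty
    reference classes) are recorded in the ``error`` column, never raised.
    """
    from .epistasis import bonferroni_alpha  # local import to avoid a cycle

    if strata is None:
        strata = {"all": None}
    alpha = bonferroni_alpha(family_alpha, table.panel.n_markers)
    rows: List[dict] = []
    for name, spec in strata.items():
        mask = resolve_stratum(table, spec)
        ratio = expected_ratio
        derive_err = None
        if ratio is None and mask.any():
            try:
                ratio = _stratum_expected_ratio(table, mask)
            except DataError as exc:
                derive_err = str(exc)
        for m in table.panel.markers:
            counts = marginal_counts(table, m.marker_id, mask)
            row = dict.fromkeys(SCAN_COLUMNS, np.nan)
            row.update(
                marker_id=m.marker_id,
                chromosome=m.chromosome,
                stratum=name,
                n0=counts.n[0], n1=counts.n[1], n2=counts.n[2],
                n_missing=counts.n_missing,
                bonferroni_alpha=alpha,
                significant=0,
                method="pearson_gof",
                error="",
            )
            if derive_err is not None:
                row["error"] = derive_err
                rows.append(row)
                continue
            try:
                res = gof_test(counts, ratio)
                row.update(
                    chi2=res.statistic, df=res.df, p=res.p_value,
                    significant=int(res.p_value < alpha),
                )
            except (DataError, DegenerateStatisticError) as exc:
                row["error"] = str(exc)
            try:
                rv = relative_viability(counts)
                row.update(
                    w_P1=rv.w_hom_p1, se_P1=rv.se_p1,
                    w_P2=rv.w_hom_p2, se_P2=rv.se_p2,
                )
            except DegenerateStatisticError as exc:
                if not row["error"]:
                    row["error"] = str(exc)
            rows.append(row)
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)
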