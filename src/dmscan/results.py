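"""Shared result containers for the statistics modules."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple


@dataclass(frozen=True)
class GenotypeCounts:
    """Marginal genotype class counts at one marker.

    ``n`` is ordered (HOM_P1, HET, HOM_P2); ``n_missing`` counts unscored
    individuals in the same stratum.
    """

    n: Tuple[int, int, int]
    n_missing: int = 0

    def __post_init__(self) -> None:
        if len(self.n) != 3 or any(x < 0 for x in self.n) or self.n_missing < 0:
            raise ValueError(f"invalid genotype counts {self.n}, {self.n_missing}")

    @property
    def total(self) -> int:
        """Non-missing total."""
        return int(sum(self.n))

    @property
    def stratum_size(self) -> int:
        return self.total + self.n_missing

    def __add__(self, other: "GenotypeCounts") -> "GenotypeCounts":
        return GenotypeCounts(
            n=tuple(a + b for a, b in zip(self.n, other.n)),
            n_missing=self.n_missing + other.n_missing,
        )


@dataclass(frozen=True)
class TestResult:
    """One test statistic with its reference distribution and p-value.

    ``df`` is 0 (a sentinel, not a real degrees-of-freedom count) for exact
    tests that have no chi-square reference distribution.
    """

    statistic: float
    df: int
    p_value: float
    method: str
    n_used: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")
        if self.statistic < 0:
            raise ValueError(f"negative statistic {self.statistic}")


@dataclass(frozen=True)
class RelativeViability:
    """Homozygote survival relative to the heterozygote class.

    Under Mendelian 1:2:1 segregation each homozygote class is expected at
    half the heterozygote frequency, so w = 2*n_hom/n_het equals 1 for an
    undistorted marker.  Standard errors are delta-method; they are undefined
    (None) when the homozygote count is 0.
    """

    w_hom_p1: float
    w_hom_p2: float
    se_p1: Optional[float]
    se_p2: Optional[float]
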