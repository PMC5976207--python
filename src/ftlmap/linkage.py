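"""Tetrad-based genetic linkage: Perkins map distance, SE, and comparisons.

The Perkins estimator corrects tetrad data for double crossovers:

    X = 100 · (T/2 + 3·NPD) / n   cM,   n = PD + T + NPD.

It equals 100 times the mean of a per-tetrad score s ∈ {0 (PD), 1/2 (T),
3 (NPD)}, so its sampling variance follows from the multinomial delta method:

    SE(X) = 100 · sqrt((E[s²] − E[s]²) / n).

Two conditions are compared with a normal Z on the estimates (primary) or a
chi-square test on the (PD | T | NPD) contingency table (cross-check).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import NamedTuple

import numpy as np
from scipy import stats

from .classify import ClassCounts

__all__ = [
    "MapDistanceResult",
    "DistanceComparison",
    "UndefinedDistanceError",
    "perkins_distance",
    "perkins_se",
    "compare_distances",
    "counts_chi2",
]

#: per-tetrad crossover score by class (PD, T, NPD)
_SCORES = (Fraction(0), Fraction(1, 2), Fraction(3))


class UndefinedDistanceError(ValueError):
    """Raised when a map distance is requested for an empty count table."""


@dataclass(frozen=True)
class MapDistanceResult:
    """Perkins genetic distance (cM) with its delta-method standard error."""

    X: float
    SE: float
    n: int
    counts: ClassCounts

    @property
    def variance(self) -> float:
        return self.SE**2


class DistanceComparison(NamedTuple):
    z: float
    p: float


def _check_nonempty(counts: ClassCounts) -> None:
    if counts.n == 0:
        raise UndefinedDistanceError(
            f"map distance undefined: no classified tetrads in "
            f"{counts.interval or 'interval'} ({counts.condition or 'condition'})"
        )


def perkins_distance(counts: ClassCounts) -> MapDistanceResult:
    """Perkins map distance X = 100·(T/2 + 3·NPD)/n, exact until the final float.

    OTHER tetrads are ignored (they are outside the PD/T/NPD multinomial).
    """
    _check_nonempty(counts)
    x = 100 * (Fraction(counts.T, 2) + 3 * counts.NPD) / counts.n
    return MapDistanceResult(
        X=float(x), SE=perkins_se(counts), n=counts.n, counts=counts
    )


def perkins_se(counts: ClassCounts) -> float:
    """Delta-method SE of the Perkins distance, in cM.

    Zero iff all classified tetrads fall in a single class.
    """
    _check_nonempty(counts)
    n = counts.n
    ks = (counts.PD, counts.T, counts.NPD)
    e_s = sum(k * s for k, s in zip(ks, _SCORES)) / n
    e_s2 = sum(k * s * s for k, s in zip(ks, _SCORES)) / n
    var_score = e_s2 - e_s * e_s
    return 100.0 * math.sqrt(float(var_score) / n)


def compare_distances(
    result_a: MapDistanceResult, result_b: MapDistanceResult
) -> DistanceComparison:
    """Normal Z test of two independent Perkins distances.

    Z = (X_A − X_B) / sqrt(SE_A² + SE_B²), two-sided p against the standard
    normal.  Degenerate zero-SE inputs give Z = 0 (equal X) or ±inf.
    """
    diff = result_a.X - result_b.X
    denom = math.hypot(result_a.SE, result_b.SE)
    if denom == 0.0:
        z = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        z = diff / denom
    p = 1.0 if z == 0.0 else float(2.0 * stats.norm.sf(abs(z)))
    return DistanceComparison(z=z, p=p)


def counts_chi2(counts_a: ClassCounts, counts_b: ClassCounts) -> tuple[float, float, int]:
    """Chi-square homogeneity test on the (PD | T | NPD) class counts.

    Cross-check for :func:`compare_distances`; all-zero classes are dropped
    from the 2×k table.  Returns (chi2, p, dof).
    """
    table = np.array(
        [
            [counts_a.PD, counts_a.T, counts_a.NPD],
            [counts_b.PD, counts_b.T, counts_b.NPD],
        ]
    )
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return 0.0, 1.0, 0
    res = stats.chi2_contingency(table)
    return float(res.statistic), float(res.pvalue), int(res.dof)
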