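"""Crossover interference from conditioned map distances.

Interference is quantified by comparing the genetic distance of a test
interval among tetrads *without* a crossover in the adjacent interval (X_wo)
to the distance among tetrads *with* one (X_wi):

    R = X_wo / X_wi

Positive interference suppresses crossovers next to an existing one, so
X_wi < X_wo and R > 1; R ≈ 1 means no interference.  The ratio variance uses
the standard first-order (delta-method) expansion for a ratio of independent
estimates, with the covariance term set to zero (the two partitions are
disjoint tetrad sets):

    Var(R) = R² · (Var(X_wo)/X_wo² + Var(X_wi)/X_wi²)

Two conditions (e.g. growth temperatures) are compared with

    Z = |R₁ − R₂| / sqrt(Var(R₁) + Var(R₂)),  p = 2·(1 − Φ(Z)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from scipy import stats

from .classify import ClassCounts
from .linkage import perkins_distance

__all__ = [
    "InterferenceResult",
    "InterferenceComparison",
    "UndefinedRatioError",
    "interference_ratio",
    "compare_interference",
]


class UndefinedRatioError(ValueError):
    """Raised when the interference ratio is undefined (X_wi = 0 or an
    empty partition)."""


@dataclass(frozen=True)
class InterferenceResult:
    """Conditioned distances and interference ratio for one condition."""

    X_wo: float
    X_wi: float
    Var_wo: float
    Var_wi: float
    R: float
    Var_R: float
    n_wo: int
    n_wi: int


class InterferenceComparison(NamedTuple):
    z: float
    p: float


def interference_ratio(
    counts_wo: ClassCounts, counts_wi: ClassCounts
) -> InterferenceResult:
    """Interference ratio R = X_wo / X_wi with its delta-method variance.

    Both partitions must be non-empty and the with-crossover distance must be
    positive, otherwise :class:`UndefinedRatioError` is raised (never a
    silent NaN).
    """
    if counts_wo.n == 0 or counts_wi.n == 0:
        raise UndefinedRatioError(
            f"interference ratio undefined: empty partition "
            f"(n_wo={counts_wo.n}, n_wi={counts_wi.n})"
        )
    res_wo = perkins_distance(counts_wo)
    res_wi = perkins_distance(counts_wi)
    if res_wi.X == 0.0:
        raise UndefinedRatioError(
            "interference ratio undefined: zero map distance in the "
            "with-crossover partition"
        )
    r = res_wo.X / res_wi.X
    var_r = r * r * (
        res_wo.variance / res_wo.X**2 + res_wi.variance / res_wi.X**2
    ) if res_wo.X > 0 else (
        # X_wo = 0: first-order term from the wo distance alone vanishes with
        # R; keep the wi contribution of the expansion evaluated at R = 0.
        res_wo.variance / res_wi.X**2
    )
    return InterferenceResult(
        X_wo=res_wo.X,
        X_wi=res_wi.X,
        Var_wo=res_wo.variance,
        Var_wi=res_wi.variance,
        R=r,
        Var_R=var_r,
        n_wo=res_wo.n,
        n_wi=res_wi.n,
    )


def compare_interference(
    result_a: InterferenceResult, result_b: InterferenceResult
) -> InterferenceComparison:
    """Z test of two interference ratios: Z = |R_a − R_b| / sqrt(Var_a + Var_b).

    Two-sided p from the standard normal.  Requires finite variances.
    """
    for res in (result_a, result_b):
        if not math.isfinite(res.Var_R):
            raise ValueError("interference comparison requires finite Var_R")
    denom = math.sqrt(result_a.Var_R + result_b.Var_R)
    diff = abs(result_a.R - result_b.R)
    if denom == 0.0:
        z = 0.0 if diff == 0.0 else math.inf
    else:
        z = diff / denom
    p = 1.0 if z == 0.0 else float(2.0 * stats.norm.sf(z))
    return InterferenceComparison(z=z, p=p)
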