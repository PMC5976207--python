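"""Tetrad classification: grain phenotypes → PD/T/NPD class counts.

For a pair of coupling-phase markers A, B a true tetrad segregates each
channel 2:2, so the grain multiset determines the class:

* ``{AB, AB, --, --}`` — parental ditype (PD), no crossover between A and B
  on any scored chromatid pair;
* ``{AB, A-, -B, --}`` — tetratype (T), a single crossover (or odd
  recombination pattern) between the markers;
* ``{A-, A-, -B, -B}`` — non-parental ditype (NPD), a four-strand double
  crossover;
* anything else — OTHER: impossible under a coupling heterozygote tetrad
  (e.g. 3:1 channel segregation from transgene silencing or an aborted
  grain); logged and excluded from every linkage statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np

from .synthetic import MarkerMap, Tetrad, TetradDataset

__all__ = [
    "IntervalClass",
    "ClassCounts",
    "classify_interval",
    "tabulate",
    "partition_by_adjacent",
]

logger = logging.getLogger(__name__)


class IntervalClass(Enum):
    PD = "PD"
    T = "T"
    NPD = "NPD"
    OTHER = "OTHER"


@dataclass(frozen=True)
class ClassCounts:
    """PD/T/NPD(/OTHER) tallies for one marker interval in one condition.

    ``n = PD + T + NPD`` is the multinomial denominator of every linkage
    statistic; OTHER tetrads are tracked but never enter ``n``.
    """

    PD: int = 0
    T: int = 0
    NPD: int = 0
    OTHER: int = 0
    interval: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        for name in ("PD", "T", "NPD", "OTHER"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} count must be >= 0")

    @property
    def n(self) -> int:
        return self.PD + self.T + self.NPD

    @property
    def total(self) -> int:
        return self.n + self.OTHER

    def __add__(self, other: "ClassCounts") -> "ClassCounts":
        return ClassCounts(
            PD=self.PD + other.PD,
            T=self.T + other.T,
            NPD=self.NPD + other.NPD,
            OTHER=self.OTHER + other.OTHER,
            interval=self.interval or other.interval,
            condition=self.condition or other.condition,
        )


def _class_from_pattern(n_ab: int, n_a: int, n_b: int, n_none: int) -> IntervalClass:
    pattern = (n_ab, n_a, n_b, n_none)
    if pattern == (2, 0, 0, 2):
        return IntervalClass.PD
    if pattern == (1, 1, 1, 1):
        return IntervalClass.T
    if pattern == (0, 2, 2, 0):
        return IntervalClass.NPD
    return IntervalClass.OTHER


def classify_interval(
    tetrad: Tetrad,
    marker_pair: Sequence[str],
    marker_map: MarkerMap | None = None,
) -> IntervalClass:
    """Classify one tetrad for the interval between two channels.

    ``marker_pair`` is a pair of channel labels.  The result is invariant to
    the order of grains within the tetrad.  If a marker map is supplied, the
    channels are validated against it; unknown labels raise ``KeyError``.
    """
    if len(marker_pair) != 2:
        raise ValueError("marker_pair must name exactly two channels")
    a, b = marker_pair
    if a == b:
        raise ValueError("marker_pair channels must differ")
    if marker_map is not None:
        marker_map.channel_index(a)
        marker_map.channel_index(b)
    n_ab = n_a = n_b = n_none = 0
    for grain in tetrad.grains:
        has_a, has_b = a in grain, b in grain
        if has_a and has_b:
            n_ab += 1
        elif has_a:
            n_a += 1
        elif has_b:
            n_b += 1
        else:
            n_none += 1
    return _class_from_pattern(n_ab, n_a, n_b, n_none)


# Vectorised path ------------------------------------------------------------

_CLASS_CODES = (IntervalClass.PD, IntervalClass.T, IntervalClass.NPD, IntervalClass.OTHER)


def _classify_alleles(alleles_pair: np.ndarray) -> np.ndarray:
    """Class codes (0=PD, 1=T, 2=NPD, 3=OTHER) from an (n, 4, 2) allele block."""
    a = alleles_pair[:, :, 0].astype(bool)
    b = alleles_pair[:, :, 1].astype(bool)
    n_ab = (a & b).sum(axis=1)
    n_a = (a & ~b).sum(axis=1)
    n_b = (~a & b).sum(axis=1)
    n_none = (~a & ~b).sum(axis=1)
    codes = np.full(alleles_pair.shape[0], 3, dtype=np.int8)
    codes[(n_ab == 2) & (n_a == 0) & (n_b == 0) & (n_none == 2)] = 0
    codes[(n_ab == 1) & (n_a == 1) & (n_b == 1) & (n_none == 1)] = 1
    codes[(n_ab == 0) & (n_a == 2) & (n_b == 2) & (n_none == 0)] = 2
    return codes


def _pair_codes(dataset, marker_pair: Sequence[str]) -> np.ndarray:
    """Class codes for every tetrad in ``dataset`` for one channel pair."""
    if isinstance(dataset, TetradDataset):
        ia = dataset.marker_map.channel_index(marker_pair[0])
        ib = dataset.marker_map.channel_index(marker_pair[1])
        return _classify_alleles(dataset.alleles[:, :, (ia, ib)])
    classes = [classify_interval(t, marker_pair) for t in dataset]
    lut = {cls: code for code, cls in enumerate(_CLASS_CODES)}
    return np.array([lut[c] for c in classes], dtype=np.int8)


def _counts_from_codes(
    codes: np.ndarray, interval: str = "", condition: str = ""
) -> ClassCounts:
    tallies = np.bincount(codes, minlength=4)
    return ClassCounts(
        PD=int(tallies[0]),
        T=int(tallies[1]),
        NPD=int(tallies[2]),
        OTHER=int(tallies[3]),
        interval=interval,
        condition=condition,
    )


def _group_labels(dataset, group_by) -> list[str]:
    if callable(group_by):
        return [str(group_by(t)) for t in dataset]
    keys = [group_by] if isinstance(group_by, str) else list(group_by)
    if isinstance(dataset, TetradDataset):
        label = "/".join(str(getattr(dataset, k)) for k in keys)
        return [label] * len(dataset)
    return ["/".join(str(getattr(t, k)) for k in keys) for t in dataset]


def tabulate(
    dataset,
    marker_pair: Sequence[str],
    group_by=None,
    interval: str = "",
) -> ClassCounts | dict[str, ClassCounts]:
    """Tally PD/T/NPD/OTHER for one channel pair, optionally per condition.

    ``dataset`` is a :class:`TetradDataset` (vectorised path) or any iterable
    of :class:`Tetrad`.  ``group_by`` may be ``None`` (one pooled table), a
    tetrad attribute name or sequence of names (``"temperature"``,
    ``("genotype", "temperature")``), or a callable ``tetrad -> label``.
    Grouping partitions the totals exactly.
    """
    interval = interval or "-".join(marker_pair)
    if group_by is None:
        codes = _pair_codes(dataset, marker_pair)
        counts = _counts_from_codes(codes, interval=interval)
        if counts.OTHER:
            logger.info(
                "%s: excluded %d OTHER tetrads (non-Mendelian channel pattern)",
                interval,
                counts.OTHER,
            )
        return counts
    if isinstance(dataset, TetradDataset) and not callable(group_by):
        # homogeneous labels: single group
        label = _group_labels(dataset, group_by)[0] if len(dataset) else ""
        counts = tabulate(dataset, marker_pair, interval=interval)
        return {label: ClassCounts(
            PD=counts.PD, T=counts.T, NPD=counts.NPD, OTHER=counts.OTHER,
            interval=interval, condition=label,
        )} if len(dataset) else {}
    tetrads = list(dataset)
    codes = _pair_codes(tetrads, marker_pair)
    labels = _group_labels(tetrads, group_by)
    out: dict[str, ClassCounts] = {}
    for label in dict.fromkeys(labels):
        mask = np.array([l == label for l in labels])
        out[label] = _counts_from_codes(codes[mask], interval=interval, condition=label)
    return out


def partition_by_adjacent(
    dataset,
    test_pair: Sequence[str],
    conditioning_pair: Sequence[str],
) -> tuple[ClassCounts, ClassCounts]:
    """Split tetrads on crossover presence in an adjacent interval.

    Returns ``(counts_wo, counts_wi)`` for the *test* interval: ``wi`` holds
    tetrads whose conditioning-interval class is T or NPD (a crossover is
    present — NPD being a double crossover), ``wo`` those classified PD.
    Tetrads whose conditioning interval is OTHER are unclassifiable and
    excluded from both partitions (logged).  The pairs must share exactly one
    marker (adjacent intervals of a three-marker map).
    """
    if len(test_pair) != 2 or len(conditioning_pair) != 2:
        raise ValueError("marker pairs must each name two channels")
    shared = set(test_pair) & set(conditioning_pair)
    if len(shared) != 1:
        raise ValueError(
            "test and conditioning intervals must be adjacent "
            "(share exactly one marker)"
        )
    if isinstance(dataset, TetradDataset) and len(dataset.marker_map.markers) < 3:
        raise ValueError("adjacent-interval partition requires a three-marker map")
    tetrads = dataset if isinstance(dataset, TetradDataset) else list(dataset)
    cond_codes = _pair_codes(tetrads, conditioning_pair)
    test_codes = _pair_codes(tetrads, test_pair)
    interval = "-".join(test_pair)
    usable = cond_codes != 3
    n_other = int((~usable).sum())
    if n_other:
        logger.info(
            "adjacent partition: excluded %d tetrads with OTHER conditioning class",
            n_other,
        )
    wi_mask = usable & ((cond_codes == 1) | (cond_codes == 2))
    wo_mask = usable & (cond_codes == 0)
    counts_wo = _counts_from_codes(test_codes[wo_mask], interval=interval, condition="wo")
    counts_wi = _counts_from_codes(test_codes[wi_mask], interval=interval, condition="wi")
    return counts_wo, counts_wi
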