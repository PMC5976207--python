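"""Simulation of meioses, pollen tetrads, cytological foci, and qPCR plates.

The generative model is the two-pathway picture of plant meiotic crossovers:

* **Type I (interfering) crossovers** are placed along the bivalent by a
  stationary gamma-renewal process on the genetic scale.  The gamma shape
  ``nu`` controls interference strength (``nu = 1`` collapses to a homogeneous
  Poisson process, i.e. no interference); the intensity is calibrated so that
  the expected chiasma count on a ``X`` cM stretch is ``rate_factor * X / 50``.
* **Type II (non-interfering) crossovers** follow a homogeneous Poisson
  process with an analogous intensity.

Each chiasma involves one randomly chosen chromatid from each homolog (no
chromatid interference); the four spores of a tetrad are the four chromatids.
A spore expresses a fluorescent channel iff its chromatid carries the
transgene-bearing parental allele at that marker (coupling configuration).

DSB-marking foci (γH2AX, RAD51) are Poisson around a homeostatic mean that is
deliberately independent of the Type I rate factor; MLH1 foci count the
genome-wide Type I events of the same meiocyte plus a small Poisson
background.  qPCR plates are generated as CT = baseline − log2(expression)
with technical and biological noise, the endogenous control untouched by
treatment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Marker",
    "MarkerMap",
    "SimConfig",
    "Tetrad",
    "TetradDataset",
    "FociRecord",
    "QpcrRecord",
    "place_type1_events",
    "place_type2_events",
    "resolve_tetrad",
    "simulate_tetrad_dataset",
    "simulate_foci_dataset",
    "simulate_pollen_viability",
    "simulate_qpcr_plate",
    "scenario_config",
    "I3A_MAP",
    "I1A_MAP",
    "I5CD_MAP",
    "TEMPERATURE_TYPE1_FACTOR",
    "VIABLE_POLLEN_MEAN",
    "QPCR_BASELINE_CT",
    "SALT_TREATMENT_LOG2FC",
    "FOCI_ANTIBODIES",
]

# ---------------------------------------------------------------------------
# Study-condition constants
# ---------------------------------------------------------------------------

#: Type I intensity multiplier per growth temperature.  The 28°C value is
#: calibrated from the WT MLH1 foci means (9.7 at 20°C vs 11.8 at 28°C, with a
#: 0.5 background): (11.8 - 0.5) / (9.7 - 0.5) ≈ 1.228.
TEMPERATURE_TYPE1_FACTOR: dict[str, float] = {"20C": 1.0, "28C": 1.228}

#: Mean viable pollen grains per anther by growth temperature.
VIABLE_POLLEN_MEAN: dict[str, float] = {"20C": 665.7, "28C": 294.5}

#: Baseline CT (cycles) per assayed gene at reference expression.
QPCR_BASELINE_CT: dict[str, float] = {"TUB4": 22.0, "BHLH122": 28.0, "AKR4C9": 26.0}

#: log2 fold-change of each salt-stress biomarker per NaCl treatment, relative
#: to the 0 mM control (TUB4, the endogenous control, is unaffected).
SALT_TREATMENT_LOG2FC: dict[str, dict[str, float]] = {
    "BHLH122": {"100mM": math.log2(1.2), "200mM": math.log2(8.2)},
    "AKR4C9": {"100mM": math.log2(1.6), "200mM": math.log2(10.5)},
}

FOCI_ANTIBODIES = ("MLH1", "RAD51", "gH2AX")

#: Map-distance calibration: expected bivalent chiasma count on an X cM
#: interval is X / 50 (so the single-spore recombination fraction matches the
#: map distance in the small-distance limit: each chiasma hits 2 of 4
#: chromatids).
_CM_PER_CHIASMA = 50.0


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Marker:
    """A fluorescent transgene marker at a fixed genetic position."""

    name: str
    channel: str
    position_cM: float


@dataclass(frozen=True)
class MarkerMap:
    """Ordered coupling-phase markers on one chromosome.

    All markers sit on the same parental homolog (coupling), so a grain
    expresses a channel iff its chromatid carries the transgene parent's
    allele at that marker.
    """

    markers: tuple[Marker, ...]

    def __post_init__(self) -> None:
        if len(self.markers) < 2:
            raise ValueError("MarkerMap requires at least 2 markers")
        positions = [m.position_cM for m in self.markers]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("marker positions must be strictly increasing")
        channels = [m.channel for m in self.markers]
        if len(set(channels)) != len(channels):
            raise ValueError("channel labels must be unique")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("marker names must be unique")

    @classmethod
    def from_tuples(cls, markers: Iterable[tuple[str, str, float]]) -> "MarkerMap":
        return cls(tuple(Marker(*m) for m in markers))

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(m.channel for m in self.markers)

    @property
    def positions(self) -> np.ndarray:
        return np.array([m.position_cM for m in self.markers], dtype=float)

    @property
    def span_cM(self) -> float:
        return self.markers[-1].position_cM - self.markers[0].position_cM

    def channel_index(self, channel: str) -> int:
        try:
            return self.channels.index(channel)
        except ValueError:
            raise KeyError(f"unknown channel label: {channel!r}") from None


# Representative FTL interval maps (positions in cM on their chromosome;
# interval widths are typical published FTL interval sizes, used as simulator
# defaults — the analysis itself never assumes them).
I3A_MAP = MarkerMap.from_tuples([("FTL-I3a-L", "G", 0.0), ("FTL-I3a-R", "R", 4.8)])
I1A_MAP = MarkerMap.from_tuples([("FTL-I1a-L", "C", 0.0), ("FTL-I1a-R", "Y", 7.0)])
I5CD_MAP = MarkerMap.from_tuples(
    [("FTL1963", "C", 0.0), ("FTL1143", "Y", 6.0), ("FTL2450", "R", 13.0)]
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated experiment (a genotype × condition cell).

    ``type1_rate_factor`` carries the temperature effect on the interfering
    pathway; ``type1_active``/``type2_active`` are the msh4/mus81 switches;
    ``type2_scale`` models fancm-like Type II hyper-activity; ``dsb_mean`` is
    homeostatic (independent of the Type I factor by construction);
    ``interference_shape`` is the gamma shape ν (ν = 1 ⇒ no interference).
    """

    n_meioses: int = 1000
    type1_rate_factor: float = 1.0
    type1_active: bool = True
    type2_active: bool = True
    type2_scale: float = 1.0
    interference_shape: float = 3.0
    type1_fraction: float = 0.85
    dsb_mean: float = 200.0
    dsb_scale_spo11: float = 0.1
    spo11: bool = False
    genome_length_cM: float = 541.2
    n_chromosomes: int = 5
    mlh1_background: float = 0.5
    rad51_efficiency: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_meioses < 0:
            raise ValueError("n_meioses must be >= 0")
        for name in (
            "type1_rate_factor",
            "type2_scale",
            "dsb_mean",
            "dsb_scale_spo11",
            "genome_length_cM",
            "mlh1_background",
            "rad51_efficiency",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.type1_fraction <= 1.0:
            raise ValueError("type1_fraction must be in [0, 1]")
        if self.interference_shape < 1.0:
            raise ValueError("interference_shape (nu) must be >= 1")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be >= 1")

    @property
    def type1_intensity(self) -> float:
        """Effective Type I chiasma intensity multiplier (0 when inactive)."""
        if not self.type1_active:
            return 0.0
        return self.type1_fraction * self.type1_rate_factor

    @property
    def type2_intensity(self) -> float:
        if not self.type2_active:
            return 0.0
        return (1.0 - self.type1_fraction) * self.type2_scale

    @property
    def dsb_scale(self) -> float:
        return self.dsb_scale_spo11 if self.spo11 else 1.0


def scenario_config(
    genotype: str = "WT",
    temperature: str = "20C",
    n_meioses: int = 1000,
    seed: int = 0,
    **overrides,
) -> SimConfig:
    """Build a :class:`SimConfig` for a named genotype × temperature scenario.

    Genotypes: ``WT``, ``msh4`` (Type I off), ``mus81`` (Type II off),
    ``fancm`` (Type II intensity ×10), ``spo11`` (DSBs scaled to 10%, both
    crossover pathways off — spo11 meioses have essentially no chiasmata).
    """
    genotype_key = genotype.lower()
    kwargs: dict = dict(n_meioses=n_meioses, seed=seed)
    try:
        kwargs["type1_rate_factor"] = TEMPERATURE_TYPE1_FACTOR[temperature]
    except KeyError:
        raise ValueError(
            f"unknown temperature label {temperature!r}; "
            f"known: {sorted(TEMPERATURE_TYPE1_FACTOR)}"
        ) from None
    if genotype_key == "wt":
        pass
    elif genotype_key == "msh4":
        kwargs["type1_active"] = False
    elif genotype_key == "mus81":
        kwargs["type2_active"] = False
    elif genotype_key == "fancm":
        kwargs["type2_scale"] = 10.0
    elif genotype_key in ("spo11", "spo11-1-1"):
        kwargs.update(spo11=True, type1_active=False, type2_active=False)
    else:
        raise ValueError(f"unknown genotype label {genotype!r}")
    kwargs.update(overrides)
    return SimConfig(**kwargs)


@dataclass(frozen=True)
class Tetrad:
    """The four spores of one meiosis, each a set of expressed channels."""

    grains: tuple[frozenset[str], ...]
    genotype: str = "WT"
    temperature: str = "20C"
    tetrad_id: int = 0

    def __post_init__(self) -> None:
        if len(self.grains) != 4:
            raise ValueError("a tetrad has exactly 4 grains")


@dataclass(frozen=True)
class FociRecord:
    """One immunostained meiocyte: a focus count for one antibody."""

    cell_id: int
    genotype: str
    temperature: str
    antibody: str
    count: int

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("focus count must be >= 0")


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR well: CT cycles for a sample × gene technical replicate."""

    sample_id: str
    treatment: str
    gene: str
    ct: float
    tech_rep: int

    def __post_init__(self) -> None:
        if self.ct <= 0:
            raise ValueError("CT must be positive")


class TetradDataset(Sequence):
    """A simulated tetrad collection with a fast array backbone.

    Behaves as a sequence of :class:`Tetrad`; the per-grain allele matrix
    (``n × 4 × n_markers`` of {0, 1}, 1 = transgene-parent allele) is exposed
    as ``.alleles`` so that tabulation over large simulations stays
    vectorised.
    """

    def __init__(
        self,
        alleles: np.ndarray,
        marker_map: MarkerMap,
        genotype: str = "WT",
        temperature: str = "20C",
    ) -> None:
        alleles = np.asarray(alleles, dtype=np.uint8)
        if alleles.ndim != 3 or alleles.shape[1] != 4:
            raise ValueError("alleles must have shape (n, 4, n_markers)")
        if alleles.shape[2] != len(marker_map.markers):
            raise ValueError("alleles marker axis does not match marker map")
        self.alleles = alleles
        self.marker_map = marker_map
        self.genotype = genotype
        self.temperature = temperature

    def __len__(self) -> int:
        return self.alleles.shape[0]

    def __getitem__(self, index):
        if isinstance(index, slice):
            return TetradDataset(
                self.alleles[index], self.marker_map, self.genotype, self.temperature
            )
        channels = self.marker_map.channels
        row = self.alleles[index]
        grains = tuple(
            frozenset(ch for ch, a in zip(channels, grain) if a) for grain in row
        )
        return Tetrad(
            grains=grains,
            genotype=self.genotype,
            temperature=self.temperature,
            tetrad_id=int(index) if index >= 0 else len(self) + int(index),
        )

    def __iter__(self) -> Iterator[Tetrad]:
        for i in range(len(self)):
            yield self[i]


# ---------------------------------------------------------------------------
# Crossover event placement
# ---------------------------------------------------------------------------


def place_type1_events(
    interval_length_cM: float,
    nu: float,
    rate_factor: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Positions of interfering (Type I) chiasmata on ``[0, L]``.

    Stationary gamma-renewal process on the genetic scale: interarrival
    distances are Gamma(ν, θ) with mean ν·θ = 50 / rate_factor cM, so the
    expected event count on X cM is rate_factor · X / 50.  Stationarity is
    obtained by drawing the first event from the equilibrium forward-
    recurrence distribution (a uniform fraction of a length-biased
    interarrival, which for a gamma is Gamma(ν + 1, θ)).
    """
    if interval_length_cM < 0:
        raise ValueError("interval_length_cM must be >= 0")
    if nu < 1:
        raise ValueError("nu must be >= 1")
    if rate_factor < 0:
        raise ValueError("rate_factor must be >= 0")
    if rate_factor == 0 or interval_length_cM == 0:
        return np.empty(0, dtype=float)
    theta = _CM_PER_CHIASMA / (rate_factor * nu)
    positions: list[float] = []
    x = rng.uniform() * rng.gamma(nu + 1.0, theta)
    while x <= interval_length_cM:
        positions.append(x)
        x += rng.gamma(nu, theta)
    return np.array(positions, dtype=float)


def place_type2_events(
    interval_length_cM: float,
    rate_factor: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Positions of non-interfering (Type II) chiasmata: homogeneous Poisson."""
    if interval_length_cM < 0:
        raise ValueError("interval_length_cM must be >= 0")
    if rate_factor < 0:
        raise ValueError("rate_factor must be >= 0")
    if rate_factor == 0 or interval_length_cM == 0:
        return np.empty(0, dtype=float)
    count = rng.poisson(rate_factor * interval_length_cM / _CM_PER_CHIASMA)
    return np.sort(rng.uniform(0.0, interval_length_cM, size=count))


# ---------------------------------------------------------------------------
# Bivalent resolution
# ---------------------------------------------------------------------------


def _resolve_alleles_single(
    chiasma_positions: np.ndarray,
    chromatid_1: np.ndarray,
    chromatid_2: np.ndarray,
    marker_positions: np.ndarray,
) -> np.ndarray:
    """Allele matrix (4 × n_markers) for one meiosis.

    Each chiasma joins one *original* chromatid from each homolog axis
    (chromatids 0,1 carry the transgene parent's alleles, 2,3 the other
    parent's) and exchanges their distal continuations.  Sweeping left to
    right, each spore strand tracks which original chromatid it currently
    follows; a chiasma swaps the followers of its two chromatids.  This keeps
    every isolated crossover phenotypically visible (a single chiasma in an
    interval always yields a tetratype) and makes disjoint intervals
    independent when the underlying process is Poisson.
    """
    # follower[k] = spore strand currently reading original chromatid k
    follower = np.arange(4)
    out = np.empty((4, marker_positions.size), dtype=np.uint8)
    order = np.argsort(chiasma_positions, kind="stable")
    pos_sorted = chiasma_positions[order]
    c1_sorted = chromatid_1[order]
    c2_sorted = chromatid_2[order]
    e = 0
    for j, mpos in enumerate(marker_positions):
        while e < pos_sorted.size and pos_sorted[e] < mpos:
            a, b = c1_sorted[e], c2_sorted[e]
            follower[a], follower[b] = follower[b], follower[a]
            e += 1
        alleles = np.zeros(4, dtype=np.uint8)
        alleles[follower[0]] = 1
        alleles[follower[1]] = 1
        out[:, j] = alleles
    return out


def resolve_tetrad(
    chiasma_positions,
    marker_map: MarkerMap,
    rng: np.random.Generator,
    genotype: str = "WT",
    temperature: str = "20C",
    tetrad_id: int = 0,
) -> Tetrad:
    """Resolve chiasmata on a four-chromatid bivalent into one tetrad.

    Each chiasma involves one uniformly chosen chromatid from each homolog
    (no chromatid interference).  ``chiasma_positions`` are in the marker
    map's cM coordinates.  With zero chiasmata two grains carry all channels
    and two carry none (parental ditype everywhere).
    """
    positions = np.asarray(chiasma_positions, dtype=float)
    if positions.ndim != 1:
        raise ValueError("chiasma_positions must be one-dimensional")
    k = positions.size
    c1 = rng.integers(0, 2, size=k)
    c2 = rng.integers(2, 4, size=k)
    alleles = _resolve_alleles_single(positions, c1, c2, marker_map.positions)
    channels = marker_map.channels
    grains = tuple(
        frozenset(ch for ch, a in zip(channels, alleles[g]) if a) for g in range(4)
    )
    return Tetrad(grains, genotype=genotype, temperature=temperature, tetrad_id=tetrad_id)


# ---------------------------------------------------------------------------
# Vectorised dataset simulation
# ---------------------------------------------------------------------------


def _renewal_event_table(
    n: int, length: float, nu: float, intensity: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Stationary gamma-renewal events for n independent meioses at once.

    Returns (meiosis_index, position) flat arrays.
    """
    if intensity == 0 or length == 0 or n == 0:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=float)
    theta = _CM_PER_CHIASMA / (intensity * nu)
    pos = rng.uniform(size=n) * rng.gamma(nu + 1.0, theta, size=n)
    idx_all: list[np.ndarray] = []
    pos_all: list[np.ndarray] = []
    active = np.arange(n)
    while active.size:
        inside = pos[active] <= length
        hit = active[inside]
        if hit.size:
            idx_all.append(hit)
            pos_all.append(pos[hit])
            pos[hit] += rng.gamma(nu, theta, size=hit.size)
        active = hit
    if not idx_all:
        return np.empty(0, dtype=np.intp), np.empty(0, dtype=float)
    return np.concatenate(idx_all), np.concatenate(pos_all)


def _renewal_counts(
    n: int, length: float, nu: float, intensity: float, rng: np.random.Generator
) -> np.ndarray:
    """Event counts only, for n meioses (used for genome-wide MLH1 foci)."""
    counts = np.zeros(n, dtype=np.int64)
    if intensity == 0 or length == 0 or n == 0:
        return counts
    theta = _CM_PER_CHIASMA / (intensity * nu)
    pos = rng.uniform(size=n) * rng.gamma(nu + 1.0, theta, size=n)
    active = np.arange(n)
    while active.size:
        inside = pos[active] <= length
        hit = active[inside]
        counts[hit] += 1
        if hit.size:
            pos[hit] += rng.gamma(nu, theta, size=hit.size)
        active = hit
    return counts


def _simulate_alleles(
    config: SimConfig, marker_map: MarkerMap, rng: np.random.Generator
) -> np.ndarray:
    """Allele matrix (n × 4 × n_markers) for a whole simulated dataset.

    Events are placed on the marker span only: the process is stationary, and
    exchanges outside the span merely permute chromatid labels, which leaves
    every tetrad class invariant.
    """
    n = config.n_meioses
    length = marker_map.span_cM
    first = marker_map.markers[0].position_cM
    rel_markers = marker_map.positions - first

    i1, p1 = _renewal_event_table(
        n, length, config.interference_shape, config.type1_intensity, rng
    )
    # Type II: Poisson counts, uniform positions.
    lam2 = config.type2_intensity * length / _CM_PER_CHIASMA
    if lam2 > 0:
        k2 = rng.poisson(lam2, size=n)
        i2 = np.repeat(np.arange(n), k2)
        p2 = rng.uniform(0.0, length, size=int(k2.sum()))
    else:
        i2 = np.empty(0, dtype=np.intp)
        p2 = np.empty(0, dtype=float)

    idx = np.concatenate([i1, i2])
    pos = np.concatenate([p1, p2])
    c1 = rng.integers(0, 2, size=idx.size)
    c2 = rng.integers(2, 4, size=idx.size)

    alleles = np.empty((n, 4, rel_markers.size), dtype=np.uint8)
    # follower[:, k] = spore strand currently reading original chromatid k
    follower = np.tile(np.arange(4, dtype=np.intp), (n, 1))

    def _record(j: int) -> None:
        a = np.zeros((n, 4), dtype=np.uint8)
        a[rows, follower[:, 0]] = 1
        a[rows, follower[:, 1]] = 1
        alleles[:, :, j] = a

    rows = np.arange(n)
    if idx.size == 0:
        for j in range(rel_markers.size):
            _record(j)
        return alleles

    # Pad events into an (n, K) grid sorted by position within each meiosis,
    # then sweep markers applying pending swaps rank by rank (each meiosis
    # appears at most once per rank, so the fancy-indexed swap is safe).
    order = np.lexsort((pos, idx))
    idx, pos, c1, c2 = idx[order], pos[order], c1[order], c2[order]
    counts = np.bincount(idx, minlength=n)
    K = int(counts.max())
    # rank of each event within its meiosis (0-based), vectorised
    starts = np.cumsum(counts) - counts
    rank = np.arange(idx.size) - np.repeat(starts, counts)
    E_pos = np.full((n, K), np.inf)
    E_c1 = np.zeros((n, K), dtype=np.intp)
    E_c2 = np.zeros((n, K), dtype=np.intp)
    E_pos[idx, rank] = pos
    E_c1[idx, rank] = c1
    E_c2[idx, rank] = c2

    applied = np.zeros((n, K), dtype=bool)
    for j, mpos in enumerate(rel_markers):
        for r in range(K):
            pending = (~applied[:, r]) & (E_pos[:, r] < mpos)
            if pending.any():
                sel = rows[pending]
                a = E_c1[sel, r]
                b = E_c2[sel, r]
                tmp = follower[sel, a].copy()
                follower[sel, a] = follower[sel, b]
                follower[sel, b] = tmp
                applied[sel, r] = True
        _record(j)
    return alleles


def simulate_tetrad_dataset(
    config: SimConfig,
    marker_map: MarkerMap,
    genotype: str = "WT",
    temperature: str = "20C",
    rng: np.random.Generator | None = None,
) -> TetradDataset:
    """Simulate ``config.n_meioses`` tetrads on ``marker_map``.

    Superposes Type I (gamma-renewal) and Type II (Poisson) chiasmata and
    resolves each meiosis on a four-chromatid bivalent.  Reproducible:
    identical config (seed included) gives bit-identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    alleles = _simulate_alleles(config, marker_map, rng)
    return TetradDataset(alleles, marker_map, genotype=genotype, temperature=temperature)


# ---------------------------------------------------------------------------
# Cytology: foci and pollen viability
# ---------------------------------------------------------------------------


def _normalize_antibody(antibody: str) -> str:
    key = antibody.strip().replace("γ", "g").replace("-", "").upper()
    if key in ("MLH1",):
        return "MLH1"
    if key in ("RAD51",):
        return "RAD51"
    if key in ("GH2AX", "H2AX"):
        return "gH2AX"
    raise ValueError(f"unknown antibody {antibody!r}; known: {FOCI_ANTIBODIES}")


def simulate_foci_dataset(
    config: SimConfig,
    n_cells: int,
    antibody: str,
    rng: np.random.Generator,
    genotype: str = "WT",
    temperature: str = "20C",
) -> list[FociRecord]:
    """Per-cell focus counts for one antibody under one condition.

    γH2AX and RAD51 counts are Poisson around the homeostatic DSB mean
    (``dsb_mean · dsb_scale``, RAD51 additionally scaled by its detection
    efficiency) and are independent of ``type1_rate_factor`` by construction.
    MLH1 counts are the meiocyte's genome-wide Type I crossover count (the
    same renewal process that drives the tetrads, run over all chromosomes)
    plus a small Poisson background.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    ab = _normalize_antibody(antibody)
    if ab == "MLH1":
        per_chrom = config.genome_length_cM / config.n_chromosomes
        counts = np.zeros(n_cells, dtype=np.int64)
        for _ in range(config.n_chromosomes):
            counts += _renewal_counts(
                n_cells, per_chrom, config.interference_shape, config.type1_intensity, rng
            )
        counts += rng.poisson(config.mlh1_background, size=n_cells)
    else:
        lam = config.dsb_mean * config.dsb_scale
        if ab == "RAD51":
            lam *= config.rad51_efficiency
        counts = rng.poisson(lam, size=n_cells)
    return [
        FociRecord(
            cell_id=i,
            genotype=genotype,
            temperature=temperature,
            antibody=ab,
            count=int(c),
        )
        for i, c in enumerate(counts)
    ]


def simulate_pollen_viability(
    n_anthers: int,
    mean_viable: float,
    rng: np.random.Generator,
    dispersion: float = 16.0,
) -> np.ndarray:
    """Viable pollen grains per anther: gamma-Poisson (negative binomial).

    ``dispersion`` is the gamma shape of the per-anther rate (CV = 1/√shape ≈
    0.25 by default), giving the anther-to-anther spread real viability counts
    show on top of Poisson noise.
    """
    if n_anthers < 0:
        raise ValueError("n_anthers must be >= 0")
    if mean_viable < 0:
        raise ValueError("mean_viable must be >= 0")
    if dispersion <= 0:
        raise ValueError("dispersion must be > 0")
    lam = rng.gamma(dispersion, mean_viable / dispersion, size=n_anthers)
    return rng.poisson(lam)


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------


def simulate_qpcr_plate(
    treatment_effects: dict[str, dict[str, float]],
    n_biological: int,
    n_technical: int,
    rng: np.random.Generator,
    baselines: dict[str, float] | None = None,
    control_gene: str = "TUB4",
    treatments: Sequence[str] = ("0mM", "100mM", "200mM"),
    sigma_technical: float = 0.15,
    sigma_biological: float = 0.25,
) -> list[QpcrRecord]:
    """Simulate CT values for a comparative-CT experiment.

    ``treatment_effects[gene][treatment]`` is the log2 fold-change of that
    gene under that treatment relative to the first (reference) treatment;
    missing entries mean no effect.  The endogenous control gene must carry no
    effects.  CT = baseline − (effect + biological noise) + technical noise,
    so expression doubling lowers CT by one cycle.
    """
    if n_biological < 1 or n_technical < 1:
        raise ValueError("n_biological and n_technical must be >= 1")
    if baselines is None:
        baselines = QPCR_BASELINE_CT
    genes = list(baselines)
    if control_gene not in genes:
        raise ValueError(f"control gene {control_gene!r} missing from baselines")
    if treatment_effects.get(control_gene):
        raise ValueError("endogenous control gene must have no treatment effects")
    records: list[QpcrRecord] = []
    for treatment in treatments:
        for b in range(n_biological):
            sample_id = f"{treatment}-rep{b + 1}"
            for gene in genes:
                effect = treatment_effects.get(gene, {}).get(treatment, 0.0)
                log2_expr = effect + rng.normal(0.0, sigma_biological)
                ct_true = baselines[gene] - log2_expr
                for t in range(n_technical):
                    ct = ct_true + rng.normal(0.0, sigma_technical)
                    records.append(
                        QpcrRecord(
                            sample_id=sample_id,
                            treatment=treatment,
                            gene=gene,
                            ct=float(ct),
                            tech_rep=t + 1,
                        )
                    )
    return records
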