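import numpy as np
import pytest

from ftlmap import MarkerMap, SimConfig, Tetrad


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_marker_map():
    return MarkerMap.from_tuples([("mA", "A", 0.0), ("mB", "B", 10.0)])


@pytest.fixture
def three_marker_map():
    """Adjacent 15 cM intervals: wide enough for conditioned distances."""
    return MarkerMap.from_tuples(
        [("m1", "C", 0.0), ("m2", "Y", 15.0), ("m3", "R", 30.0)]
    )


def make_tetrad(*grains, genotype="WT", temperature="20C", tetrad_id=0):
    return Tetrad(
        grains=tuple(frozenset(g) for g in grains),
        genotype=genotype,
        temperature=temperature,
        tetrad_id=tetrad_id,
    )


@pytest.fixture
def poisson_config():
    """No-interference config for closed-form oracles."""

    def _make(n, seed=0, **kw):
        kw.setdefault("interference_shape", 1.0)
        return SimConfig(n_meioses=n, seed=seed, **kw)

    return _make
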