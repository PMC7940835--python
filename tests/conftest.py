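import numpy as np
import pytest

from conmap.markers import MarkerData
from conmap.io import PopulationDataset
from conmap.simulate import SimConfig, make_truth, simulate_connected


def make_marker(name, female_gt, male_gt, calls):
    return MarkerData(name=name, female_gt=female_gt, male_gt=male_gt,
                      calls=np.asarray(calls, dtype=np.int8))


def make_dataset(markers, population_id="pop1", female_id="F", male_id="M"):
    n = markers[0].n_progeny
    return PopulationDataset(population_id, female_id, male_id,
                             [f"i{j}" for j in range(n)], list(markers))


@pytest.fixture
def pair_factory():
    """Simulate a single marker pair with known r, phases and cross types."""

    def _make(t1, t2, r, n=200, seed=0):
        types = {"B3.7": ("ab", "ab"), "D1.10": ("ab", "aa"),
                 "D2.15": ("aa", "ab")}
        rng = np.random.default_rng(seed)
        f1, ma1 = types[t1]
        f2, ma2 = types[t2]
        hm = np.empty((n, 2), int)
        hp = np.empty((n, 2), int)
        hm[:, 0] = rng.integers(0, 2, n)
        hm[:, 1] = hm[:, 0] ^ (rng.random(n) < r)
        hp[:, 0] = rng.integers(0, 2, n)
        hp[:, 1] = hp[:, 0] ^ (rng.random(n) < r)
        of = [int(rng.integers(0, 2)) if f == "ab" else 0 for f in (f1, f2)]
        om = [int(rng.integers(0, 2)) if m == "ab" else 0 for m in (ma1, ma2)]
        calls = np.zeros((n, 2), np.int8)
        for t, (fh, mh) in enumerate([(f1 == "ab", ma1 == "ab"),
                                      (f2 == "ab", ma2 == "ab")]):
            calls[:, t] = ((fh & (hm[:, t] != of[t])).astype(int)
                           + (mh & (hp[:, t] != om[t])).astype(int))
        m1 = make_marker("m1", f1, ma1, calls[:, 0])
        m2 = make_marker("m2", f2, ma2, calls[:, 1])
        return m1, m2

    return _make


@pytest.fixture
def connected_sim():
    """Small pair of connected populations with known truth."""

    def _make(n_markers=8, seed=0, **overrides):
        kwargs = dict(n1=100, n2=120, epsilon=0.0, missing_rate=0.0,
                      seed=seed)
        kwargs.update(overrides)
        cfg = SimConfig(**kwargs)
        truth = make_truth(n_markers, cfg, rf_range=(0.05, 0.2))
        ds1, ds2 = simulate_connected(truth, cfg)
        return truth, ds1, ds2

    return _make
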