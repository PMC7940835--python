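"""Multipoint HMM: likelihood identities, EM properties, phasing."""

import numpy as np
import pytest

from conmap.markers import MISSING
from conmap.twopoint import rf_twopoint
from conmap.hmm import (
    em_fit, em_fit_joint, hmm_loglik, hmm_loglik_joint,
    phase_search, phase_search_joint,
    _emissions, _forward, _backward_loglik, _e_step,
)

from conftest import make_marker, make_dataset


def _phasing_for_pair(m1, m2, phase):
    """Orientation vectors for a 2-marker order under a named pair phase."""
    def vec(het1, het2, p):
        o = np.array([-1, -1])
        if het1:
            o[0] = 0
        if het2:
            o[1] = 0 if p in (None, "C") else 1
        return o
    return {
        "female": vec(m1.female_het, m2.female_het, phase.female),
        "male": vec(m1.male_het, m2.male_het, phase.male),
    }


@pytest.mark.parametrize("t1,t2", [
    ("B3.7", "B3.7"), ("D1.10", "D1.10"), ("D2.15", "D2.15"),
    ("B3.7", "D1.10"), ("B3.7", "D2.15"),
])
def test_two_marker_hmm_equals_twopoint_likelihood(pair_factory, t1, t2):
    """With no error modelling, the 2-marker forward likelihood reproduces
    the two-point multinomial log-likelihood at every phase and r."""
    m1, m2 = pair_factory(t1, t2, 0.18, n=150, seed=21)
    ds = make_dataset([m1, m2])
    res = rf_twopoint(m1, m2)
    for phase, (r_hat, ll) in res.per_phase.items():
        phasing = _phasing_for_pair(m1, m2, phase)
        lh = hmm_loglik(["m1", "m2"], [max(r_hat, 1e-7)], phasing, ds,
                        epsilon=0.0)
        assert lh == pytest.approx(ll, abs=1e-9)


def test_unlinked_rf_factorizes_into_single_locus_likelihoods(connected_sim):
    truth, ds1, _ = connected_sim(n_markers=4, seed=3)
    order = truth.marker_names
    phasing, _ = phase_search(order, ds1, epsilon=0.05)
    eps = 0.05
    ll = hmm_loglik(order, [0.5] * 3, phasing, ds1, epsilon=eps)
    single = 0.0
    for j, nm in enumerate(order):
        single += hmm_loglik([nm], [], {
            "female": phasing["female"][j:j + 1],
            "male": phasing["male"][j:j + 1]}, ds1, epsilon=eps)
    assert ll == pytest.approx(single, rel=1e-10)


def test_all_missing_progeny_contributes_zero():
    m1 = make_marker("a", "ab", "aa", [0, 1, MISSING])
    m2 = make_marker("b", "ab", "aa", [0, 1, MISSING])
    m1b = make_marker("a", "ab", "aa", [0, 1])
    m2b = make_marker("b", "ab", "aa", [0, 1])
    ph = {"female": np.array([0, 0]), "male": np.array([-1, -1])}
    ll3 = hmm_loglik(["a", "b"], [0.1], ph, make_dataset([m1, m2]))
    ll2 = hmm_loglik(["a", "b"], [0.1], ph, make_dataset([m1b, m2b]))
    assert ll3 == pytest.approx(ll2, abs=1e-12)


def test_forward_and_backward_recursions_agree(connected_sim):
    truth, ds1, _ = connected_sim(n_markers=6, seed=9,
                                  epsilon=0.05, missing_rate=0.1)
    order = truth.marker_names
    phasing, rf0 = phase_search(order, ds1)
    markers = [ds1.marker(nm) for nm in order]
    emis = _emissions(markers, phasing["female"], phasing["male"], 0.05)
    rf = np.clip(rf0, 1e-6, 0.49)
    ll_f = _forward(emis, rf)[2]
    ll_b = _backward_loglik(emis, rf)
    assert ll_f == pytest.approx(ll_b, abs=1e-10 * abs(ll_f))


def test_posterior_expected_recombinations_bounded(connected_sim):
    truth, ds1, _ = connected_sim(n_markers=5, seed=4)
    order = truth.marker_names
    phasing, rf0 = phase_search(order, ds1)
    markers = [ds1.marker(nm) for nm in order]
    emis = _emissions(markers, phasing["female"], phasing["male"], 0.02)
    _, e_mat, e_pat = _e_step(emis, np.clip(rf0, 1e-6, 0.49))
    n = ds1.n_progeny
    assert np.all(e_mat >= 0) and np.all(e_mat <= n)
    assert np.all(e_pat >= 0) and np.all(e_pat <= n)


def test_em_loglik_non_decreasing(connected_sim):
    """EM ascent property checked across random instances by re-running the
    E-step likelihood along the iterate path."""
    for seed in range(10):
        truth, ds1, _ = connected_sim(n_markers=6, seed=seed + 50,
                                      epsilon=0.05, missing_rate=0.1)
        order = truth.marker_names
        phasing, rf0 = phase_search(order, ds1)
        markers = [ds1.marker(nm) for nm in order]
        emis = _emissions(markers, phasing["female"], phasing["male"], 0.05)
        rf = np.clip(rf0, 1e-6, 0.49)
        prev = -np.inf
        for _ in range(30):
            ll, e_mat, e_pat = _e_step(emis, rf)
            assert ll >= prev - 1e-8
            prev = ll
            rf = np.clip((e_mat + e_pat) / (2 * ds1.n_progeny), 1e-7, 0.49999)


def test_complete_noiseless_testcross_em_matches_count_ratio(connected_sim):
    """With complete, error-free maternal-testcross data, the EM estimate per
    interval equals the observed recombinant fraction exactly."""
    from conmap.markers import JointCrossType
    truth, ds1, _ = connected_sim(
        n_markers=5, seed=3,
        joint_proportions={JointCrossType.D1_10_D1_10: 1.0})
    gm = em_fit(truth.marker_names, ds1, epsilon=0.0)
    # independent closed form: maternal homolog per call, phase from truth
    names = truth.marker_names
    for j in range(4):
        c1 = ds1.marker(names[j]).calls
        c2 = ds1.marker(names[j + 1]).calls
        o1, o2 = truth.female_phase[j], truth.female_phase[j + 1]
        h1 = np.where(c1 == 1, 1 - o1, o1)
        h2 = np.where(c2 == 1, 1 - o2, o2)
        observed = float(np.mean(h1 != h2))
        assert gm.rf[j] == pytest.approx(observed, abs=1e-6)


def test_em_two_markers_reproduces_twopoint(pair_factory):
    m1, m2 = pair_factory("D1.10", "D1.10", 0.12, n=200, seed=31)
    ds = make_dataset([m1, m2])
    tp = rf_twopoint(m1, m2)
    gm = em_fit(["m1", "m2"], ds, epsilon=0.0)
    assert gm.rf[0] == pytest.approx(tp.r_best, abs=1e-4)


def test_positions_are_cumulative_kosambi(connected_sim):
    from conmap.markers import kosambi
    truth, ds1, _ = connected_sim(n_markers=5, seed=8)
    gm = em_fit(truth.marker_names, ds1)
    pos = gm.positions_cm
    assert pos[0] == 0.0
    assert np.all(np.diff(pos) >= 0)
    np.testing.assert_allclose(np.diff(pos), kosambi(gm.rf), rtol=1e-12)


class TestJointFit:
    def test_empty_population_degenerates_to_single(self, connected_sim):
        from conmap.io import PopulationDataset
        truth, ds1, ds2 = connected_sim(n_markers=4, seed=13)
        empty_ds = PopulationDataset(
            "pop2", ds2.female_id, ds2.male_id, [],
            [make_marker(m.name, m.female_gt, m.male_gt, [])
             for m in ds2.markers])
        gm_single = em_fit(truth.marker_names, ds1)
        gm_joint = em_fit_joint(truth.marker_names, ds1, empty_ds)
        np.testing.assert_allclose(gm_joint.rf, gm_single.rf, atol=1e-9)

    def test_duplicated_dataset_same_rf_double_loglik(self, connected_sim):
        truth, ds1, _ = connected_sim(n_markers=5, seed=17)
        gm1 = em_fit(truth.marker_names, ds1)
        gmj = em_fit_joint(truth.marker_names, ds1, ds1)
        np.testing.assert_allclose(gmj.rf, gm1.rf, atol=1e-4)
        assert gmj.loglik == pytest.approx(2 * gm1.loglik, rel=1e-4)

    def test_joint_loglik_additivity_at_fixed_rf(self, connected_sim):
        truth, ds1, ds2 = connected_sim(n_markers=5, seed=19,
                                        epsilon=0.05, missing_rate=0.1)
        order = truth.marker_names
        gmj = em_fit_joint(order, ds1, ds2)
        ph = gmj.phasing
        joint_ll = hmm_loglik_joint(order, gmj.rf, ph, ds1, ds2)
        ll1 = hmm_loglik(order, gmj.rf,
                         {"female": ph["female"], "male": ph["male1"]}, ds1)
        ll2 = hmm_loglik(order, gmj.rf,
                         {"female": ph["female"], "male": ph["male2"]}, ds2)
        assert joint_ll == pytest.approx(ll1 + ll2, rel=1e-12)
        assert gmj.loglik == pytest.approx(joint_ll, rel=1e-9)

    def test_marker_absent_from_one_population_errors(self, connected_sim):
        truth, ds1, ds2 = connected_sim(n_markers=4, seed=23)
        sub2 = ds2.subset(truth.marker_names[:-1])
        with pytest.raises(ValueError, match="absent"):
            em_fit_joint(truth.marker_names, ds1, sub2)


class TestPhaseSearch:
    def _canon(self, v, het):
        v = np.asarray(v).copy()
        idx = np.nonzero(het)[0]
        if len(idx) and v[idx[0]] == 1:
            v[het] = 1 - v[het]
        return v

    def test_recovers_true_phasing(self, connected_sim):
        truth, ds1, ds2 = connected_sim(n_markers=10, seed=29,
                                        n1=200, n2=200)
        ph, _ = phase_search_joint(truth.marker_names, ds1, ds2)
        fh = truth.female_phase >= 0
        m1h = truth.male1_phase >= 0
        m2h = truth.male2_phase >= 0
        np.testing.assert_array_equal(
            ph["female"], self._canon(truth.female_phase, fh))
        np.testing.assert_array_equal(
            ph["male1"], self._canon(truth.male1_phase, m1h))
        np.testing.assert_array_equal(
            ph["male2"], self._canon(truth.male2_phase, m2h))

    def test_whole_parent_mirror_leaves_loglik_unchanged(self, connected_sim):
        truth, ds1, _ = connected_sim(n_markers=5, seed=31)
        order = truth.marker_names
        ph, rf0 = phase_search(order, ds1)
        rf = np.clip(rf0, 1e-6, 0.49)
        ll = hmm_loglik(order, rf, ph, ds1)
        flipped = dict(ph)
        het = ph["female"] >= 0
        flipped["female"] = np.where(het, 1 - ph["female"], -1)
        assert hmm_loglik(order, rf, flipped, ds1) == pytest.approx(
            ll, rel=1e-12)

    def test_homozygous_parent_phase_is_null(self, connected_sim):
        from conmap.markers import JointCrossType
        truth, ds1, _ = connected_sim(
            n_markers=4, seed=37,
            joint_proportions={JointCrossType.D2_15_D2_15: 1.0})
        ph, _ = phase_search(truth.marker_names, ds1)
        assert np.all(ph["female"] == -1)
        assert np.all(ph["male"] >= 0)
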