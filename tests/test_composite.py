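"""Composite-map construction: framework, conflicts, scaled insertion."""

import numpy as np
import pytest

from conmap.markers import kosambi_inverse
from conmap.hmm import GeneticMap, em_fit, em_fit_joint
from conmap.composite import (
    CompositeMap, build_framework, conflict_set, resolve_conflicts,
    insert_unique, build_composite, match_groups, _lcs,
)
from conmap.simulate import SimConfig, make_truth, simulate_connected


def _sim(n_markers=8, seed=0, spacing=(8.0, 14.0), **overrides):
    kwargs = dict(n1=160, n2=184, epsilon=0.0, missing_rate=0.0, seed=seed)
    kwargs.update(overrides)
    cfg = SimConfig(**kwargs)
    rng = np.random.default_rng(seed + 3000)
    truth = make_truth(n_markers, cfg, rng=np.random.default_rng(seed + 4000))
    truth.rf = kosambi_inverse(rng.uniform(*spacing, n_markers - 1))
    ds1, ds2 = simulate_connected(truth, cfg)
    return truth, ds1, ds2


def _map_for(order, ds, **kw):
    return em_fit(list(order), ds, **kw)


class TestLCS:
    def test_conflict_set_for_local_swap(self):
        # ABCD vs ABDC: the LCS keeps three markers, one conflicts
        cs = conflict_set(list("abcd"), list("abdc"))
        assert len(cs) == 1
        assert cs[0] in {"c", "d"}
        # lexicographic tie-break keeps the smaller name in the LCS
        assert cs == ["d"]

    def test_identical_orders_have_no_conflicts(self):
        assert conflict_set(list("abcde"), list("abcde")) == []

    def test_mirrored_order_is_not_a_conflict(self):
        assert conflict_set(list("abcde"), list("edcba")) == []

    def test_lcs_is_a_common_subsequence(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = [f"m{i}" for i in range(8)]
            b = list(rng.permutation(a))
            s = _lcs(a, b)

            def is_subseq(s, seq):
                it = iter(seq)
                return all(x in it for x in s)

            assert is_subseq(s, a) and is_subseq(s, b)


class TestFramework:
    def test_identical_restricted_orders_pass_through(self):
        truth, ds1, ds2 = _sim(n_markers=6, seed=1)
        order = truth.marker_names
        m1 = _map_for(order, ds1)
        m2 = _map_for(order, ds2)
        fw = build_framework(m1, m2, ds1, ds2)
        assert fw.marker_names == order
        ref = em_fit_joint(order, ds1, ds2)
        np.testing.assert_allclose(fw.rf, ref.rf, atol=1e-9)

    def test_perturbed_map_loses_to_correct_order(self):
        truth, ds1, ds2 = _sim(n_markers=7, seed=2)
        order = list(truth.marker_names)
        bad = list(order)
        bad[2], bad[5] = bad[5], bad[2]
        m1 = _map_for(order, ds1)
        m2 = _map_for(bad, ds2)
        fw = build_framework(m1, m2, ds1, ds2)
        assert fw.marker_names == order

    def test_too_few_shared_markers_raises(self):
        truth, ds1, ds2 = _sim(n_markers=4, seed=3)
        names = truth.marker_names
        m1 = _map_for(names[:2], ds1)
        m2 = _map_for(names[2:], ds2)
        with pytest.raises(ValueError, match="shared"):
            build_framework(m1, m2, ds1, ds2)


class TestResolveConflicts:
    def test_swapped_pair_resolved_to_joint_argmax(self):
        truth, ds1, ds2 = _sim(n_markers=6, seed=4, n1=200, n2=200)
        order = list(truth.marker_names)
        bad = list(order)
        bad[2], bad[3] = bad[3], bad[2]
        m1 = _map_for(order, ds1)
        m2 = _map_for(bad, ds2)
        fw = build_framework(m1, m2, ds1, ds2)
        resolved = resolve_conflicts(fw, m1, m2, ds1, ds2)
        assert resolved.loglik >= fw.loglik - 1e-9
        assert (resolved.marker_names == order
                or resolved.marker_names == order[::-1])

    def test_exhaustive_position_oracle_on_four_markers(self):
        """The re-inserted conflict marker lands at the position an
        exhaustive search over all insertion points selects."""
        import itertools
        truth, ds1, ds2 = _sim(n_markers=4, seed=5, n1=200, n2=200)
        order = list(truth.marker_names)
        bad = [order[0], order[1], order[3], order[2]]
        m1 = _map_for(order, ds1)
        m2 = _map_for(bad, ds2)
        fw = build_framework(m1, m2, ds1, ds2)
        resolved = resolve_conflicts(fw, m1, m2, ds1, ds2)
        conflicts = conflict_set(
            [n for n in m1.marker_names],
            [n for n in m2.marker_names])
        (cmarker,) = conflicts
        reduced = [n for n in fw.marker_names if n != cmarker]
        best_ll, best_order = -np.inf, None
        for pos in range(len(reduced) + 1):
            cand = reduced[:pos] + [cmarker] + reduced[pos:]
            ll = em_fit_joint(cand, ds1, ds2).loglik
            if ll > best_ll:
                best_ll, best_order = ll, cand
        # ripple may refine further, so the resolved likelihood must be at
        # least the exhaustive-insertion optimum
        assert resolved.loglik >= best_ll - 1e-6

    def test_identical_orders_have_empty_conflict_set(self):
        # identical restricted orders: nothing is re-placed; the closing
        # joint ripple may still refine locally but never loses likelihood
        truth, ds1, ds2 = _sim(n_markers=5, seed=6)
        order = truth.marker_names
        m1 = _map_for(order, ds1)
        m2 = _map_for(order, ds2)
        assert conflict_set(order, order) == []
        fw = build_framework(m1, m2, ds1, ds2)
        resolved = resolve_conflicts(fw, m1, m2, ds1, ds2)
        assert resolved.loglik >= fw.loglik - 1e-9
        assert set(resolved.marker_names) == set(order)


def _toy_map(names, positions, female=None):
    """GeneticMap with prescribed positions (via rf inversion)."""
    rf = kosambi_inverse(np.diff(positions))
    k = len(names)
    phasing = {"female": np.zeros(k, int), "male": np.zeros(k, int)}
    return GeneticMap(list(names), rf, phasing, 0.0)


class TestInsertUnique:
    def test_interval_scaling_halves_offset(self):
        # composite interval 10 cM vs individual 20 cM: a unique marker
        # 5 cM from the left flank lands 2.5 cM from it
        fw = _toy_map(["A", "B"], [0.0, 10.0])
        ind = _toy_map(["A", "u", "B"], [0.0, 5.0, 20.0])
        other = _toy_map(["A", "B"], [0.0, 9.0])
        cm = insert_unique(fw, ind, other)
        (ins,) = cm.inserted
        assert ins.name == "u"
        assert ins.position_cm == pytest.approx(2.5, abs=1e-9)
        assert ins.scaling_factor == pytest.approx(0.5, abs=1e-9)
        assert ins.scope == "interval"

    def test_terminal_scaling(self):
        # terminal factor = composite length / individual length = 0.8;
        # a marker 10 cM beyond the last common marker lands 8 cM beyond
        fw = _toy_map(["A", "B"], [0.0, 16.0])
        ind = _toy_map(["A", "B", "u"], [0.0, 20.0, 30.0])
        other = _toy_map(["A", "B"], [0.0, 16.0])
        cm = insert_unique(fw, ind, other)
        (ins,) = cm.inserted
        assert ins.scope == "terminal"
        assert ins.scaling_factor == pytest.approx(16.0 / 30.0, abs=1e-9)
        assert ins.position_cm == pytest.approx(16.0 + 10.0 * 16.0 / 30.0,
                                                abs=1e-9)

    def test_markers_from_both_populations_merge_by_position(self):
        fw = _toy_map(["A", "B"], [0.0, 10.0])
        ind1 = _toy_map(["A", "u1", "B"], [0.0, 8.0, 20.0])   # -> 4.0
        ind2 = _toy_map(["A", "u2", "B"], [0.0, 5.0, 20.0])   # -> 2.5
        cm = insert_unique(fw, ind1, ind2)
        names = [nm for nm, _, _ in cm.full_order]
        assert names == ["A", "u2", "u1", "B"]

    def test_scaling_invariant_to_uniform_rescale(self):
        fw = _toy_map(["A", "B", "C"], [0.0, 10.0, 30.0])
        ind = _toy_map(["A", "u", "B", "C"], [0.0, 6.0, 15.0, 45.0])
        ind_scaled = _toy_map(["A", "u", "B", "C"], [0.0, 4.0, 10.0, 30.0])
        p1 = insert_unique(fw, ind, fw).inserted[0].position_cm
        p2 = insert_unique(fw, ind_scaled, fw).inserted[0].position_cm
        assert p1 == pytest.approx(p2, abs=1e-9)

    def test_positions_preserve_flanking_order(self):
        truth, ds1, ds2 = _sim(n_markers=10, seed=7, unique_fraction=0.4)
        shared = truth.names_in("pop1")
        shared = [nm for nm in shared if nm in truth.names_in("pop2")]
        m1 = _map_for(truth.names_in("pop1"), ds1)
        m2 = _map_for(truth.names_in("pop2"), ds2)
        fw = em_fit_joint(shared, ds1, ds2)
        cm = insert_unique(fw, m1, m2)
        # every source-map marker appears exactly once in the merged order
        names = [nm for nm, _, _ in cm.full_order]
        assert sorted(names) == sorted(set(m1.marker_names)
                                       | set(m2.marker_names))
        positions = [p for _, p, _ in cm.full_order]
        assert positions == sorted(positions)
        assert positions[0] == 0.0


class TestBuildComposite:
    def test_end_to_end_places_all_markers(self):
        truth, ds1, ds2 = _sim(n_markers=10, seed=8, unique_fraction=0.3,
                               n1=200, n2=200)
        maps1 = [_map_for(truth.names_in("pop1"), ds1)]
        maps2 = [_map_for(truth.names_in("pop2"), ds2)]
        result = build_composite(ds1, ds2, maps1, maps2)
        assert len(result.composite_groups) == 1
        cm = result.composite_groups[0]
        all_names = set(maps1[0].marker_names) | set(maps2[0].marker_names)
        assert {nm for nm, _, _ in cm.full_order} == all_names
        shared = [nm for nm, p in zip(truth.marker_names, truth.presence)
                  if p == "shared"]
        assert set(cm.framework.marker_names) == set(shared)
        prov = {nm: pv for nm, _, pv in cm.full_order}
        for nm, pres in zip(truth.marker_names, truth.presence):
            expected = "shared" if pres == "shared" else f"{pres}-only"
            assert prov[nm] == expected
        # summary densities: composite spacing below each individual map's
        summ = result.summary().iloc[0]
        dens1 = maps1[0].length_cm / (maps1[0].n_markers - 1)
        dens2 = maps2[0].length_cm / (maps2[0].n_markers - 1)
        assert summ.marker_density < max(dens1, dens2)

    def test_deterministic_rerun(self):
        truth, ds1, ds2 = _sim(n_markers=8, seed=9, unique_fraction=0.25)
        maps1 = [_map_for(truth.names_in("pop1"), ds1)]
        maps2 = [_map_for(truth.names_in("pop2"), ds2)]
        r1 = build_composite(ds1, ds2, maps1, maps2)
        r2 = build_composite(ds1, ds2, maps1, maps2)
        assert r1.map_table().equals(r2.map_table())

    def test_match_groups_pairs_by_overlap(self):
        truth, ds1, ds2 = _sim(n_markers=12, seed=10)
        names = truth.marker_names
        g1a = _map_for(names[:6], ds1)
        g1b = _map_for(names[6:], ds1)
        g2a = _map_for(names[:6], ds2)
        g2b = _map_for(names[6:], ds2)
        pairs = match_groups([g1a, g1b], [g2b, g2a])
        assert len(pairs) == 2
        matched = {(id(a), id(b)) for a, b, _ in pairs}
        assert (id(g1a), id(g2a)) in matched
        assert (id(g1b), id(g2b)) in matched
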