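"""Multipoint likelihood and EM re-estimation on a fixed marker order.

The hidden state of a progeny at a marker is the pair (maternal homolog,
paternal homolog) it inherited, four states in all with a uniform 1/4 prior
at the first position.  The transition between consecutive markers is the
tensor product of the 2x2 matrix [[1-r, r], [r, 1-r]] for each parent with
the *same* r per interval (integrated-map assumption: a single recombination
fraction shared by the two parents, and — in the joint two-population fit —
by both crosses).

Emissions implement a symmetric genotyping-error model: the genotype class
implied by the state, the marker's parental phasing, and its cross type is
observed with probability 1 - epsilon; each of the other c - 1 observable
classes with epsilon / (c - 1) (c = 3 for B3.7 markers, 2 for testcross
types).  A missing call emits 1 for every state, so uninformative progeny
contribute nothing.

EM: the E-step runs forward-backward per progeny (and, in the joint fit, per
population, since meioses of different populations are independent); the
M-step pools expected maternal plus paternal recombination events over all
available meioses: r_j = E[recombinations in interval j] / (2 N_total).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .markers import MISSING, MarkerData, kosambi
from .io import PopulationDataset
from .twopoint import rf_twopoint, TwoPointResult, PhaseAssignment

__all__ = ["GeneticMap", "hmm_loglik", "hmm_loglik_joint", "em_fit",
           "em_fit_joint", "phase_search", "phase_search_joint"]

_RF_LO, _RF_HI = 1e-7, 0.49999

# state s = 2*hm + hp
_HM = np.array([0, 0, 1, 1])
_HP = np.array([0, 1, 0, 1])
_RM = (_HM[:, None] != _HM[None, :]).astype(float)
_RP = (_HP[:, None] != _HP[None, :]).astype(float)


def _trans(r: float) -> np.ndarray:
    # tensor product of [[1-r, r], [r, 1-r]] with itself, written out
    a = (1.0 - r) * (1.0 - r)
    b = (1.0 - r) * r
    c = r * r
    return np.array([[a, b, b, c],
                     [b, a, c, b],
                     [b, c, a, b],
                     [c, b, b, a]])


@dataclass
class GeneticMap:
    """An ordered linkage group with per-interval recombination fractions.

    ``phasing`` maps a parent label (``"female"``/``"male"`` for a single
    population, ``"female"``/``"male1"``/``"male2"`` for a joint map) to an
    orientation vector: entry j is the homolog (0 or 1) carrying the
    reference allele at marker j, or -1 where that parent is homozygous
    (phase undefined).  Positions are cumulative Kosambi distances.
    """

    marker_names: list[str]
    rf: np.ndarray
    phasing: dict[str, np.ndarray]
    loglik: float
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self) -> None:
        self.rf = np.asarray(self.rf, dtype=float)
        if self.rf.size != max(len(self.marker_names) - 1, 0):
            raise ValueError("rf vector must have n_markers - 1 entries")

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def positions_cm(self) -> np.ndarray:
        if self.rf.size == 0:
            return np.zeros(self.n_markers)
        return np.concatenate([[0.0], np.cumsum(kosambi(self.rf))])

    @property
    def length_cm(self) -> float:
        p = self.positions_cm
        return float(p[-1]) if p.size else 0.0

    def reversed(self) -> "GeneticMap":
        return GeneticMap(
            marker_names=list(reversed(self.marker_names)),
            rf=self.rf[::-1].copy(),
            phasing={k: v[::-1].copy() for k, v in self.phasing.items()},
            loglik=self.loglik, converged=self.converged, n_iter=self.n_iter,
        )


def _state_classes(m: MarkerData, of: int, om: int) -> np.ndarray:
    """Genotype class implied by each hidden state given the phasing."""
    a_f = np.where(_HM != of, 1, 0) if m.female_het else np.zeros(4, int)
    a_m = np.where(_HP != om, 1, 0) if m.male_het else np.zeros(4, int)
    return a_f + a_m


def _marker_emission(m: MarkerData, of: int, om: int,
                     epsilon: float) -> np.ndarray:
    """(N, 4) emission probabilities for one marker."""
    cls = _state_classes(m, of, om)
    n_cls = len(m.cross_type.observable_classes)
    lut = np.ones((4, 4))  # obs call (0..2) x state; row 3 = missing
    for v in range(3):
        lut[v] = np.where(cls == v, 1.0 - epsilon,
                          epsilon / (n_cls - 1))
    calls = np.where(m.calls == MISSING, 3, m.calls).astype(int)
    return lut[calls]


def _emissions(markers: list[MarkerData], of: np.ndarray, om: np.ndarray,
               epsilon: float) -> np.ndarray:
    return np.stack([
        _marker_emission(m, int(of[j]), int(om[j]), epsilon)
        for j, m in enumerate(markers)
    ])


def _forward(emis: np.ndarray, rf: np.ndarray):
    """Scaled forward pass; returns (alphas, scales, loglik)."""
    k, n, _ = emis.shape
    alphas = np.empty_like(emis)
    scales = np.empty((k, n))
    a = emis[0] * 0.25
    s = np.maximum(a.sum(axis=1), 1e-300)
    alphas[0] = a / s[:, None]
    scales[0] = s
    for j in range(1, k):
        a = (alphas[j - 1] @ _trans(rf[j - 1])) * emis[j]
        s = np.maximum(a.sum(axis=1), 1e-300)
        alphas[j] = a / s[:, None]
        scales[j] = s
    return alphas, scales, float(np.log(scales).sum())


def _backward_loglik(emis: np.ndarray, rf: np.ndarray) -> float:
    """Total log-likelihood via the backward recursion (cross-check)."""
    k, n, _ = emis.shape
    b = np.ones((n, 4))
    ll = np.zeros(n)
    for j in range(k - 2, -1, -1):
        b = (_trans(rf[j]) @ (emis[j + 1] * b).T).T
        s = np.maximum(b.sum(axis=1), 1e-300)
        b /= s[:, None]
        ll += np.log(s)
    final = np.maximum((0.25 * emis[0] * b).sum(axis=1), 1e-300)
    return float((ll + np.log(final)).sum())


def _e_step(emis: np.ndarray, rf: np.ndarray):
    """Forward-backward; returns (loglik, E[mat rec], E[pat rec]) per interval."""
    k, n, _ = emis.shape
    alphas, scales, ll = _forward(emis, rf)
    e_mat = np.zeros(max(k - 1, 0))
    e_pat = np.zeros(max(k - 1, 0))
    beta = np.ones((n, 4))
    for j in range(k - 2, -1, -1):
        t = _trans(rf[j])
        eb = emis[j + 1] * beta
        xi = alphas[j][:, :, None] * t[None, :, :] * eb[:, None, :]
        z = np.maximum(xi.sum(axis=(1, 2)), 1e-300)
        xi /= z[:, None, None]
        e_mat[j] = float((xi * _RM).sum())
        e_pat[j] = float((xi * _RP).sum())
        beta = (t @ eb.T).T / scales[j + 1][:, None]
    return ll, e_mat, e_pat


def _prepare(order, dataset: PopulationDataset,
             phasing: dict[str, np.ndarray], epsilon: float):
    markers = [dataset.marker(nm) for nm in order]
    return _emissions(markers, phasing["female"],
                      phasing[_male_key(phasing)], epsilon)


def _male_key(phasing: dict) -> str:
    return "male" if "male" in phasing else "male1"


def hmm_loglik(order, rf, phasing, dataset: PopulationDataset,
               epsilon: float = 0.05) -> float:
    """Multipoint log-likelihood of ``dataset`` under a fixed order/rf/phasing."""
    rf = np.asarray(rf, dtype=float)
    if rf.size != len(order) - 1:
        raise ValueError("rf vector must have len(order) - 1 entries")
    if np.any(rf < 0) or np.any(rf > 0.5):
        raise ValueError("recombination fractions must lie in [0, 0.5]")
    emis = _prepare(order, dataset, phasing, epsilon)
    _, _, ll = _forward(emis, rf)
    return ll


def hmm_loglik_joint(order, rf, phasing, ds1: PopulationDataset,
                     ds2: PopulationDataset, epsilon: float = 0.05) -> float:
    """Summed multipoint log-likelihood of two populations at a shared rf."""
    rf = np.asarray(rf, dtype=float)
    mk1 = [ds1.marker(nm) for nm in order]
    mk2 = [ds2.marker(nm) for nm in order]
    emis1 = _emissions(mk1, phasing["female"], phasing["male1"], epsilon)
    emis2 = _emissions(mk2, phasing["female"], phasing["male2"], epsilon)
    return _forward(emis1, rf)[2] + _forward(emis2, rf)[2]


def _phase_candidates(m: MarkerData, parent: str, seen: bool) -> list[int]:
    het = m.female_het if parent == "female" else m.male_het
    if not het:
        return [-1]
    # canonical anchoring: the parent's first heterozygous marker is fixed
    return [0] if not seen else [0, 1]


def _chain_r(tp: TwoPointResult, prev_m: MarkerData, cur_m: MarkerData,
             of_prev: int, om_prev: int, cf: int, cm: int,
             joint_male2: tuple | None = None) -> float:
    """Two-point r-hat under the pair phase implied by candidate orientations."""
    pf = pm = pm2 = None
    if prev_m.female_het and cur_m.female_het:
        pf = "C" if of_prev == cf else "R"
    if prev_m.male_het and cur_m.male_het:
        pm = "C" if om_prev == cm else "R"
    if joint_male2 is not None:
        prev2, cur2, om2_prev, cm2 = joint_male2
        if prev2.male_het and cur2.male_het:
            pm2 = "C" if om2_prev == cm2 else "R"
        key = PhaseAssignment(pf, pm, pm2)
    else:
        key = PhaseAssignment(pf, pm)
    r = tp.per_phase.get(key, (tp.r_best, 0.0))[0]
    if r >= 0.49:
        # an uninformative or unlinked adjacent pair must not wipe out the
        # forward message: score with a moderate linked distance instead
        # (r = 0.5 makes the transition fully mixing and the choice blind)
        r = 0.15
    return float(min(max(r, _RF_LO), _RF_HI))


def _flip_combos(n_parents: int) -> list[tuple[int, ...]]:
    """Non-identity subsets of parents to flip at one marker."""
    out = []
    for mask in range(1, 2 ** n_parents):
        out.append(tuple(i for i in range(n_parents) if mask >> i & 1))
    return out


def _polish_orientations(marker_sets, orient_sets, epsilon, chain_fns,
                         max_sweeps: int = 5):
    """Local hill-climb over per-marker orientation flips.

    The greedy left-to-right pass cannot break likelihood ties that the
    prefix alone leaves unresolved — notably, for a pair with both parents
    heterozygous at both loci, assigning the recombination to the female
    versus the male chain gives identical two-point likelihoods.  Here each
    marker's informative-parent orientations are flipped in every
    combination and re-scored with a full forward pass (interval r values
    re-chained from the two-point tables under the implied phases); flips
    are accepted greedily while the total log-likelihood improves.

    ``marker_sets``/``orient_sets`` hold one entry per population (a shared
    female orientation array is aliased across populations).  ``chain_fns``
    maps an orientation state to the chained rf vector per population.
    """
    emis_cache = [
        _emissions(markers, orient_sets[p][0], orient_sets[p][1], epsilon)
        for p, markers in enumerate(marker_sets)]

    def refresh(j: int) -> None:
        for p, markers in enumerate(marker_sets):
            emis_cache[p][j] = _marker_emission(
                markers[j], int(orient_sets[p][0][j]),
                int(orient_sets[p][1][j]), epsilon)

    def total_ll():
        ll = 0.0
        rfs = []
        for p in range(len(marker_sets)):
            rf = chain_fns[p]()
            rfs.append(rf)
            ll += _forward(emis_cache[p], rf)[2]
        return ll, rfs

    k = len(marker_sets[0])
    # parents: 0 = female (shared), then one male per population
    best_ll, _ = total_ll()
    for _ in range(max_sweeps):
        improved = False
        for j in range(k):
            informative = []
            if any(orient_sets[p][0][j] >= 0 for p in range(len(marker_sets))):
                informative.append(("f", None))
            for p in range(len(marker_sets)):
                if orient_sets[p][1][j] >= 0:
                    informative.append(("m", p))
            if not informative:
                continue
            for combo in _flip_combos(len(informative)):
                flipped = [informative[i] for i in combo]
                _apply_flips(orient_sets, j, flipped)
                refresh(j)
                ll, _ = total_ll()
                if ll > best_ll + 1e-9:
                    best_ll = ll
                    improved = True
                else:
                    _apply_flips(orient_sets, j, flipped)  # revert
                    refresh(j)
        if not improved:
            break
    return best_ll


def _apply_flips(orient_sets, j: int, flips) -> None:
    for kind, p in flips:
        if kind == "f":
            # the female orientation array is shared (aliased) between
            # populations: flip each distinct array exactly once
            seen: set[int] = set()
            for q in range(len(orient_sets)):
                arr = orient_sets[q][0]
                if id(arr) in seen:
                    continue
                seen.add(id(arr))
                if arr[j] >= 0:
                    arr[j] ^= 1
        else:
            orient_sets[p][1][j] ^= 1


def _recanonicalize(orient: np.ndarray) -> None:
    """Flip a whole parent so its first heterozygous marker has orientation 0
    (the likelihood is invariant under the whole-parent mirror)."""
    het = orient >= 0
    idx = np.nonzero(het)[0]
    if idx.size and orient[idx[0]] == 1:
        orient[het] = 1 - orient[het]


def phase_search(order, dataset: PopulationDataset, epsilon: float = 0.05,
                 tp_cache: dict | None = None):
    """Sequential maximum-likelihood phasing of one population.

    Markers are added left to right; for each new marker every orientation of
    each informative parent is scored by the forward likelihood of the prefix
    (interval r taken from the two-point estimate at the implied pair phase)
    and the argmax kept.  A local flip-polish pass then breaks the phase
    ties the prefix could not resolve.  Returns ``(phasing, chained rf)``.
    """
    markers = [dataset.marker(nm) for nm in order]
    k = len(markers)
    of = np.full(k, -1, dtype=int)
    om = np.full(k, -1, dtype=int)
    f_seen = m_seen = False
    if markers[0].female_het:
        of[0] = 0
        f_seen = True
    if markers[0].male_het:
        om[0] = 0
        m_seen = True
    alpha = _marker_emission(markers[0], int(of[0]), int(om[0]),
                             epsilon) * 0.25
    alpha /= np.maximum(alpha.sum(axis=1), 1e-300)[:, None]
    tps = []
    for j in range(1, k):
        prev_m, cur_m = markers[j - 1], markers[j]
        tp = _pair_lookup(tp_cache, prev_m, cur_m)
        tps.append(tp)
        best = None
        for cf in _phase_candidates(cur_m, "female", f_seen):
            for cm in _phase_candidates(cur_m, "male", m_seen):
                r = _chain_r(tp, prev_m, cur_m, int(of[j - 1]),
                             int(om[j - 1]), cf, cm)
                e = _marker_emission(cur_m, cf, cm, epsilon)
                a = (alpha @ _trans(r)) * e
                score = float(np.log(np.maximum(a.sum(axis=1),
                                                1e-300)).sum())
                if best is None or score > best[0] + 1e-12:
                    best = (score, cf, cm, r, a)
        _, cf, cm, r, a = best
        of[j], om[j] = cf, cm
        alpha = a / np.maximum(a.sum(axis=1), 1e-300)[:, None]
        f_seen = f_seen or cur_m.female_het
        m_seen = m_seen or cur_m.male_het

    def chain() -> np.ndarray:
        return np.array([
            _chain_r(tps[j - 1], markers[j - 1], markers[j],
                     int(of[j - 1]), int(om[j - 1]), int(of[j]), int(om[j]))
            for j in range(1, k)])

    if k > 2:
        _polish_orientations([markers], [(of, om)], epsilon, [chain])
        _recanonicalize(of)
        _recanonicalize(om)
    init_rf = chain() if k > 1 else np.empty(0)
    return {"female": of, "male": om}, init_rf


def _pair_lookup(tp_cache, m1: MarkerData, m2: MarkerData) -> TwoPointResult:
    if tp_cache is not None and (m1.name, m2.name) in tp_cache:
        return tp_cache[(m1.name, m2.name)]
    return rf_twopoint(m1, m2)


def phase_search_joint(order, ds1: PopulationDataset, ds2: PopulationDataset,
                       epsilon: float = 0.05):
    """Joint sequential phasing: shared female orientation, per-cross males."""
    mk1 = [ds1.marker(nm) for nm in order]
    mk2 = [ds2.marker(nm) for nm in order]
    k = len(order)
    of = np.full(k, -1, dtype=int)
    om1 = np.full(k, -1, dtype=int)
    om2 = np.full(k, -1, dtype=int)
    f_seen = m1_seen = m2_seen = False
    if mk1[0].female_het:
        of[0] = 0
        f_seen = True
    if mk1[0].male_het:
        om1[0] = 0
        m1_seen = True
    if mk2[0].male_het:
        om2[0] = 0
        m2_seen = True
    a1 = _marker_emission(mk1[0], int(of[0]), int(om1[0]), epsilon) * 0.25
    a1 /= np.maximum(a1.sum(axis=1), 1e-300)[:, None]
    a2 = _marker_emission(mk2[0], int(of[0]), int(om2[0]), epsilon) * 0.25
    a2 /= np.maximum(a2.sum(axis=1), 1e-300)[:, None]
    tps1, tps2 = [], []
    for j in range(1, k):
        tp1 = rf_twopoint(mk1[j - 1], mk1[j])
        tp2 = rf_twopoint(mk2[j - 1], mk2[j])
        tps1.append(tp1)
        tps2.append(tp2)
        best = None
        for cf in _phase_candidates(mk1[j], "female", f_seen):
            for cm1 in _phase_candidates(mk1[j], "male", m1_seen):
                r1 = _chain_r(tp1, mk1[j - 1], mk1[j], int(of[j - 1]),
                              int(om1[j - 1]), cf, cm1)
                e1 = _marker_emission(mk1[j], cf, cm1, epsilon)
                c1 = (a1 @ _trans(r1)) * e1
                s1 = float(np.log(np.maximum(c1.sum(axis=1),
                                             1e-300)).sum())
                for cm2 in _phase_candidates(mk2[j], "male", m2_seen):
                    r2 = _chain_r(tp2, mk2[j - 1], mk2[j], int(of[j - 1]),
                                  int(om2[j - 1]), cf, cm2)
                    e2 = _marker_emission(mk2[j], cf, cm2, epsilon)
                    c2 = (a2 @ _trans(r2)) * e2
                    s2 = float(np.log(np.maximum(c2.sum(axis=1),
                                                 1e-300)).sum())
                    n1 = mk1[j].calls.size
                    n2 = mk2[j].calls.size
                    r_pool = (r1 * n1 + r2 * n2) / (n1 + n2)
                    if best is None or s1 + s2 > best[0] + 1e-12:
                        best = (s1 + s2, cf, cm1, cm2, r_pool, c1, c2)
        _, cf, cm1, cm2, r_pool, c1, c2 = best
        of[j], om1[j], om2[j] = cf, cm1, cm2
        a1 = c1 / np.maximum(c1.sum(axis=1), 1e-300)[:, None]
        a2 = c2 / np.maximum(c2.sum(axis=1), 1e-300)[:, None]
        f_seen = f_seen or mk1[j].female_het
        m1_seen = m1_seen or mk1[j].male_het
        m2_seen = m2_seen or mk2[j].male_het

    def chain1() -> np.ndarray:
        return np.array([
            _chain_r(tps1[j - 1], mk1[j - 1], mk1[j], int(of[j - 1]),
                     int(om1[j - 1]), int(of[j]), int(om1[j]))
            for j in range(1, k)])

    def chain2() -> np.ndarray:
        return np.array([
            _chain_r(tps2[j - 1], mk2[j - 1], mk2[j], int(of[j - 1]),
                     int(om2[j - 1]), int(of[j]), int(om2[j]))
            for j in range(1, k)])

    if k > 2:
        _polish_orientations([mk1, mk2], [(of, om1), (of, om2)], epsilon,
                             [chain1, chain2])
        _recanonicalize(of)
        _recanonicalize(om1)
        _recanonicalize(om2)
    if k > 1:
        n1, n2 = mk1[0].calls.size, mk2[0].calls.size
        init_rf = (chain1() * n1 + chain2() * n2) / max(n1 + n2, 1)
    else:
        init_rf = np.empty(0)
    return {"female": of, "male1": om1, "male2": om2}, init_rf


def em_fit(order, dataset: PopulationDataset, epsilon: float = 0.05,
           init_rf=None, max_iter: int = 100, tol: float = 1e-6,
           phasing: dict | None = None, tp_cache: dict | None = None
           ) -> GeneticMap:
    """Fit per-interval recombination fractions by EM on a fixed order.

    Initial rf come from chained two-point estimates found during phasing
    (fallback 0.1 where a pair is uninformative).  The log-likelihood is
    non-decreasing across iterations; convergence is declared when its
    relative change drops below ``tol``.
    """
    order = list(order)
    if phasing is None:
        phasing, chained = phase_search(order, dataset, epsilon, tp_cache)
        if init_rf is None:
            init_rf = chained
    if init_rf is None:
        init_rf = np.full(max(len(order) - 1, 0), 0.1)
    rf = np.clip(np.where(np.asarray(init_rf, float) >= 0.5 - 1e-4, 0.1,
                          np.asarray(init_rf, float)), _RF_LO, _RF_HI)
    emis = _prepare(order, dataset, phasing, epsilon)
    n = dataset.n_progeny
    if len(order) < 2:
        _, _, ll = _forward(emis, rf)
        return GeneticMap(order, rf, phasing, ll)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, e_mat, e_pat = _e_step(emis, rf)
        rf_new = np.clip((e_mat + e_pat) / (2.0 * n), _RF_LO, _RF_HI)
        moved = float(np.max(np.abs(rf_new - rf)))
        rf = rf_new
        if (np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev)
                and moved <= 10 * tol):
            converged = True
            break
        ll_prev = ll
    _, _, ll_final = _forward(emis, rf)
    return GeneticMap(order, rf, phasing, ll_final,
                      converged=converged, n_iter=it)


def em_fit_joint(order, ds1: PopulationDataset, ds2: PopulationDataset,
                 epsilon: float = 0.05, init_rf=None, max_iter: int = 100,
                 tol: float = 1e-6, phasing: dict | None = None
                 ) -> GeneticMap:
    """Joint EM over two connected populations with a shared rf vector.

    The E-step runs on each population separately (meioses are independent
    between crosses and the male phasings are population-specific, while the
    shared female parent imposes one common female phasing); the M-step pools
    expected recombination events over both populations:
    r_j = sum of expected maternal+paternal recombinations / (2 (N1 + N2)).
    """
    order = list(order)
    missing1 = [nm for nm in order if nm not in ds1]
    missing2 = [nm for nm in order if nm not in ds2]
    if missing1 or missing2:
        raise ValueError(
            f"joint fit requires all markers in both populations; absent: "
            f"pop1 {missing1[:3]}, pop2 {missing2[:3]}")
    if ds2.n_progeny == 0:
        return em_fit(order, ds1, epsilon, init_rf, max_iter, tol)
    if ds1.n_progeny == 0:
        return em_fit(order, ds2, epsilon, init_rf, max_iter, tol)

    if phasing is None:
        phasing, chained = phase_search_joint(order, ds1, ds2, epsilon)
        if init_rf is None:
            init_rf = chained
    if init_rf is None:
        init_rf = np.full(max(len(order) - 1, 0), 0.1)
    rf = np.clip(np.where(np.asarray(init_rf, float) >= 0.5 - 1e-4, 0.1,
                          np.asarray(init_rf, float)), _RF_LO, _RF_HI)
    mk1 = [ds1.marker(nm) for nm in order]
    mk2 = [ds2.marker(nm) for nm in order]
    emis1 = _emissions(mk1, phasing["female"], phasing["male1"], epsilon)
    emis2 = _emissions(mk2, phasing["female"], phasing["male2"], epsilon)
    n_total = ds1.n_progeny + ds2.n_progeny
    if len(order) < 2:
        ll = _forward(emis1, rf)[2] + _forward(emis2, rf)[2]
        return GeneticMap(order, rf, phasing, ll)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll1, em1, ep1 = _e_step(emis1, rf)
        ll2, em2, ep2 = _e_step(emis2, rf)
        ll = ll1 + ll2
        rf_new = np.clip((em1 + ep1 + em2 + ep2) / (2.0 * n_total),
                         _RF_LO, _RF_HI)
        moved = float(np.max(np.abs(rf_new - rf)))
        rf = rf_new
        if (np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * abs(ll_prev)
                and moved <= 10 * tol):
            converged = True
            break
        ll_prev = ll
    ll_final = _forward(emis1, rf)[2] + _forward(emis2, rf)[2]
    return GeneticMap(order, rf, phasing, ll_final,
                      converged=converged, n_iter=it)
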