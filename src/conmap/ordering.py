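"""Linkage-group formation and marker-order search.

Groups are connected components of the graph whose edges join marker pairs
with two-point LOD >= ``lod_min`` and r-hat <= ``rf_max``.  Ordering follows
the classical seeded strategy: an exhaustive search over permutations of a
small, informative, well-spaced seed subset (mirror orders deduplicated),
sequential insertion of the remaining markers at their best gap when the
placement is unambiguous, and a sliding-window ripple that accepts any local
permutation improving the multipoint log-likelihood.  All objectives are
multipoint log-likelihoods from the HMM, single-population or joint.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .markers import CrossType, kosambi
from .io import PopulationDataset
from .twopoint import TwoPointResult
from .hmm import GeneticMap, em_fit, em_fit_joint

__all__ = ["LinkageGroup", "OrderSearchState", "group_markers",
           "order_seq", "try_insert", "ripple", "rf_heat_matrix", "Fitter"]

_LN10 = math.log(10.0)


@dataclass
class LinkageGroup:
    group_id: int
    marker_names: list[str]
    order: list[str] | None = None

    @property
    def size(self) -> int:
        return len(self.marker_names)


@dataclass
class OrderSearchState:
    """Framework order plus markers left aside with the reason.

    ``flags`` records markers that looked suspect (terminal gap or group
    inflation) but were kept because no better position could be found.
    """

    framework: list[str]
    unplaced: dict[str, str] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)


def group_markers(
    tp_matrix: dict[tuple[str, str], TwoPointResult],
    marker_names: list[str] | None = None,
    lod_min: float = 7.5,
    rf_max: float = 0.35,
) -> list[LinkageGroup]:
    """Partition markers into linkage groups by thresholded connectivity.

    An edge joins (i, j) iff LOD >= ``lod_min`` and r-hat <= ``rf_max``;
    groups are the connected components, largest first (singletons included
    as size-1 groups at the end).
    """
    if marker_names is None:
        marker_names = sorted({n for pair in tp_matrix for n in pair})
    g = nx.Graph()
    g.add_nodes_from(marker_names)
    seen = set()
    for (a, b), res in tp_matrix.items():
        if (b, a) in seen:
            continue
        seen.add((a, b))
        if res.lod >= lod_min and res.r_best <= rf_max:
            g.add_edge(a, b)
    comps = sorted(
        (sorted(c) for c in nx.connected_components(g)),
        key=lambda c: (-len(c), c[0]),
    )
    return [LinkageGroup(i + 1, list(c)) for i, c in enumerate(comps)]


class Fitter:
    """Multipoint-likelihood scorer over a fixed dataset (or joint pair).

    Order search evaluates many candidate orders; scoring fits use a reduced
    EM iteration budget (the ranking of orders stabilizes quickly), while
    ``full=True`` fits run to convergence.  Fits are cached by order.
    """

    def __init__(self, datasets, epsilon: float = 0.05,
                 score_iters: int = 20, tp_cache: dict | None = None):
        self.joint = isinstance(datasets, (tuple, list))
        self.datasets = tuple(datasets) if self.joint else (datasets,)
        self.epsilon = epsilon
        self.score_iters = score_iters
        self.tp_cache = tp_cache
        self._cache: dict[tuple, GeneticMap] = {}

    def fit(self, order, full: bool = False) -> GeneticMap:
        key = (tuple(order), full)
        if key in self._cache:
            return self._cache[key]
        kwargs = dict(epsilon=self.epsilon,
                      max_iter=100 if full else self.score_iters,
                      tol=1e-6 if full else 1e-4)
        if self.joint:
            gm = em_fit_joint(order, *self.datasets, **kwargs)
        else:
            gm = em_fit(order, self.datasets[0], tp_cache=self.tp_cache,
                        **kwargs)
        self._cache[key] = gm
        return gm

    def loglik(self, order) -> float:
        return self.fit(order).loglik

    def rank(self, name: str) -> tuple:
        """Informativeness key: B3.7 first, then least missing, then name."""
        ds = self.datasets[0]
        m = ds.marker(name)
        ct_rank = 0 if m.cross_type is CrossType.B3_7 else 1
        miss = m.missing_fraction
        if self.joint and name in self.datasets[1]:
            m2 = self.datasets[1].marker(name)
            miss = 0.5 * (miss + m2.missing_fraction)
        return (ct_rank, miss, name)


def _mirror_dedup(perms):
    for p in perms:
        if p <= p[::-1]:
            yield p


def _pair_r(tp_matrix, a: str, b: str) -> float:
    """Spread distance for seed selection: 0 for uninformative pairs so the
    seed prefers mutually informative markers over blind combinations."""
    res = tp_matrix.get((a, b)) if tp_matrix else None
    if res is None or res.n_informative_meioses == 0:
        return 0.0
    return res.r_best


def _select_seed(names: list[str], fitter: Fitter, seed_size: int,
                 tp_matrix) -> list[str]:
    """Informative, well-spaced seed.

    Starting from the top-ranked marker, markers are added greedily with
    cross-type informativeness as the primary key (a fully informative
    marker anchors both parents' chains) and maximin r-hat spread to the
    current seed as the secondary key, then missingness and name.  Keeping
    informativeness primary also makes seed choices consistent between two
    connected populations, which the composite framework depends on.
    """
    ranked = sorted(names, key=fitter.rank)
    seed = [ranked[0]]
    while len(seed) < min(seed_size, len(names)):
        best = None
        for nm in ranked:
            if nm in seed:
                continue
            spread = min(_pair_r(tp_matrix, nm, s) for s in seed)
            rank = fitter.rank(nm)
            key = (rank[0], -spread) + rank[1:]
            if best is None or key < best[0]:
                best = (key, nm)
        seed.append(best[1])
    return seed


def order_seq(
    group: LinkageGroup | list[str],
    datasets,
    seed_size: int = 6,
    epsilon: float = 0.05,
    ambiguity_lod: float = 3.0,
    tp_matrix: dict | None = None,
    score_iters: int = 20,
    suspect_gap_cm: float = 15.0,
    touchdown: bool = True,
) -> tuple[OrderSearchState, GeneticMap]:
    """Order a linkage group: exhaustive seed search plus sequential insertion.

    All ``seed_size!/2`` mirror-deduplicated permutations of the seed subset
    are scored by multipoint log-likelihood; the best seed order is extended
    with :func:`try_insert` for every remaining marker (most informative
    first).  With ``touchdown`` (the conventional final integration round),
    markers still ambiguous after the regular passes are retried once at a
    threshold one log10 unit lower.  Framework markers creating terminal
    gaps larger than ``suspect_gap_cm`` or inflating the group by more than
    that amount are pulled out and re-tried.  Returns the search state and
    the converged map of the framework.
    """
    names = group.marker_names if isinstance(group, LinkageGroup) else list(group)
    fitter = Fitter(datasets, epsilon=epsilon, score_iters=score_iters,
                    tp_cache=tp_matrix)
    if len(names) < 3:
        order = sorted(names, key=fitter.rank)
        state = OrderSearchState(framework=order)
        return state, fitter.fit(order, full=True)

    seed = _select_seed(names, fitter, seed_size, tp_matrix)
    best_order, best_ll = None, -np.inf
    for perm in _mirror_dedup(itertools.permutations(sorted(seed))):
        ll = fitter.loglik(list(perm))
        if ll > best_ll + 1e-9:
            best_order, best_ll = list(perm), ll
    state = OrderSearchState(framework=best_order)

    remaining = sorted((n for n in names if n not in seed), key=fitter.rank)
    for nm in remaining:
        try_insert(state, nm, fitter, ambiguity_lod=ambiguity_lod)
    # previously ambiguous markers are retried: every placement adds an
    # anchor, so a marker ambiguous against a sparse framework may place
    # unambiguously against a denser one
    for _ in range(3):
        retry = sorted(state.unplaced, key=fitter.rank)
        placed_any = False
        for nm in retry:
            try_insert(state, nm, fitter, ambiguity_lod=ambiguity_lod)
            placed_any = placed_any or nm not in state.unplaced
        if not placed_any:
            break
    if touchdown and state.unplaced:
        lowered = max(ambiguity_lod - 1.0, 1.0)
        for _ in range(2):
            retry = sorted(state.unplaced, key=fitter.rank)
            placed_any = False
            for nm in retry:
                try_insert(state, nm, fitter, ambiguity_lod=lowered)
                placed_any = placed_any or nm not in state.unplaced
            if not placed_any:
                break

    _prune_suspect(state, fitter, ambiguity_lod, suspect_gap_cm)
    final = fitter.fit(state.framework, full=True)
    return state, final


def try_insert(
    state: OrderSearchState,
    marker_name: str,
    fitter: Fitter,
    ambiguity_lod: float = 3.0,
) -> OrderSearchState:
    """Score ``marker_name`` at every gap of the framework.

    The marker is placed at the argmax position iff it beats the runner-up
    by at least ``ambiguity_lod`` log10-likelihood units; otherwise it is
    recorded as ambiguous.
    """
    fw = state.framework
    if len(fw) < 2:
        raise ValueError("framework must hold at least two markers")
    scores = []
    for pos in range(len(fw) + 1):
        cand = fw[:pos] + [marker_name] + fw[pos:]
        scores.append((fitter.loglik(cand), pos))
    scores.sort(key=lambda t: (-t[0], t[1]))
    best_ll, best_pos = scores[0]
    runner_ll = scores[1][0]
    if (best_ll - runner_ll) / _LN10 >= ambiguity_lod:
        state.framework = fw[:best_pos] + [marker_name] + fw[best_pos:]
        state.unplaced.pop(marker_name, None)
    else:
        state.unplaced[marker_name] = "ambiguous"
    return state


def _prune_suspect(state: OrderSearchState, fitter: Fitter,
                   ambiguity_lod: float, gap_cm: float) -> None:
    """Pull out framework markers at suspect positions and re-try them.

    A marker is suspect when it sits beyond a terminal gap larger than
    ``gap_cm`` or when removing it shrinks the group by more than ``gap_cm``.
    """
    if len(state.framework) < 4:
        return
    gm = fitter.fit(state.framework)
    gaps = kosambi(gm.rf)
    suspects: dict[str, str] = {}
    if gaps[0] > gap_cm:
        suspects[state.framework[0]] = "terminal-gap"
    if gaps[-1] > gap_cm:
        suspects[state.framework[-1]] = "terminal-gap"
    base_len = gm.length_cm
    # interior markers only: removing a terminal marker always shrinks the
    # map by its whole terminal gap, which is genuine length, not inflation
    for nm in state.framework[1:-1]:
        if nm in suspects or len(state.framework) - len(suspects) < 4:
            continue
        reduced = [x for x in state.framework if x != nm]
        if base_len - fitter.fit(reduced).length_cm > gap_cm:
            suspects[nm] = "inflating"
    for nm, reason in suspects.items():
        original = state.framework.index(nm)
        state.framework = [x for x in state.framework if x != nm]
        if len(state.framework) >= 2:
            try_insert(state, nm, fitter, ambiguity_lod)
        if nm not in state.framework:
            # no unambiguous alternative: keep the marker where it was,
            # flagged for inspection, rather than losing it
            state.framework.insert(original, nm)
            state.unplaced.pop(nm, None)
            state.flags[nm] = reason


def ripple(
    gm: GeneticMap,
    datasets,
    window: int = 4,
    epsilon: float = 0.05,
    min_improve: float = 1e-6,
    max_sweeps: int = 10,
    score_iters: int = 20,
    fitter: Fitter | None = None,
) -> GeneticMap:
    """Sliding-window verification of local orders.

    Every permutation of each ``window``-sized slice is scored; an order is
    adopted as soon as it improves the multipoint log-likelihood by more than
    ``min_improve``, and sweeps repeat until a full pass yields no
    improvement (monotone, hence terminating).  Pass a tuple of datasets for
    the joint two-population objective.
    """
    if fitter is None:
        fitter = Fitter(datasets, epsilon=epsilon, score_iters=score_iters)
    order = list(gm.marker_names)
    w = min(window, len(order))
    if w < 2:
        return gm
    best_ll = fitter.loglik(order)
    for _ in range(max_sweeps):
        improved = False
        for start in range(len(order) - w + 1):
            segment = order[start:start + w]
            for perm in itertools.permutations(segment):
                if list(perm) == segment:
                    continue
                cand = order[:start] + list(perm) + order[start + w:]
                ll = fitter.loglik(cand)
                if ll > best_ll + min_improve:
                    order, best_ll = cand, ll
                    improved = True
        if not improved:
            break
    out = fitter.fit(order, full=True)
    if out.loglik < gm.loglik - 1e-9 and order == list(gm.marker_names):
        return gm
    return out


def rf_heat_matrix(
    order: list[str] | GeneticMap,
    tp_matrix: dict[tuple[str, str], TwoPointResult],
    plot_path=None,
) -> pd.DataFrame:
    """Pairwise r-hat (lower triangle) and LOD (upper triangle) in map order."""
    names = order.marker_names if isinstance(order, GeneticMap) else list(order)
    k = len(names)
    mat = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i + 1, k):
            res = tp_matrix.get((names[i], names[j]))
            if res is None:
                continue
            mat[j, i] = res.r_best
            mat[i, j] = res.lod
    df = pd.DataFrame(mat, index=names, columns=names)
    if plot_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(6, 5))
        rf_only = np.where(np.tril(np.ones((k, k)), -1) > 0, mat, np.nan)
        im = ax.imshow(rf_only, cmap="RdYlBu", vmin=0, vmax=0.5)
        fig.colorbar(im, ax=ax, label="recombination fraction")
        ax.set_xticks(range(k), names, rotation=90, fontsize=6)
        ax.set_yticks(range(k), names, fontsize=6)
        fig.tight_layout()
        fig.savefig(plot_path, dpi=120)
        plt.close(fig)
    return df
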