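"""Two-point recombination-fraction and LOD estimation.

For a pair of markers in an outcrossing F1 population, each progeny genotype
pair arises from one maternal and one paternal gamete.  Conditional on the
linkage phase of each heterozygous parent, the probability of every gamete
configuration is a function of a single recombination fraction r (shared by
the two parents under the integrated-map assumption).  The likelihood is the
multinomial over observed joint genotype classes; it is maximized here by an
EM on the gamete-configuration mixture — expected recombination events among
the informative meioses divided by their number — which reduces to the
closed-form count ratio whenever the configuration-to-class map is invertible
(testcross-type pairs) and handles the mixed B3.7 classes otherwise.

A parent is *informative* for a pair only if it is heterozygous at both
markers; the phase of any other parent is undefined and reported as ``None``.
For two populations connected by a shared female parent, the joint estimator
maximizes the summed log-likelihood of both populations over a single shared
r, enumerating up to eight joint phase assignments (shared female phase times
one male phase per cross).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .markers import MISSING, MarkerData, PhaseAssignment

__all__ = ["TwoPointResult", "rf_twopoint", "rf_twopoint_joint",
           "twopoint_matrix", "twopoint_matrix_joint"]

_LN10 = math.log(10.0)

# The four gamete configurations (homolog at locus 1, homolog at locus 2)
# and whether each represents a recombination event.
_GAM = np.array([(g1, g2) for g1 in (0, 1) for g2 in (0, 1)], dtype=int)
_REC4 = (_GAM[:, 0] != _GAM[:, 1]).astype(float)
_REC_M16 = np.repeat(_REC4, 4)
_REC_P16 = np.tile(_REC4, 4)

_EM_TOL = 1e-8
_EM_MAX_ITER = 200


def _alleles(het: tuple[bool, bool], orient: tuple[int, int]) -> np.ndarray:
    """Allele (0='a', 1='b') transmitted at each locus for each gamete config.

    A heterozygous parent carries 'a' on homolog ``orient[t]`` at locus t; a
    homozygous parent transmits 'a' from either homolog.
    """
    out = np.zeros((4, 2), dtype=int)
    for t in range(2):
        if het[t]:
            out[:, t] = (_GAM[:, t] != orient[t]).astype(int)
    return out


def _pair_cells(m_het, m_orient, p_het, p_orient) -> np.ndarray:
    """Observable joint-class index (3*c1 + c2) for all 16 gamete configs."""
    am = _alleles(m_het, m_orient)
    ap = _alleles(p_het, p_orient)
    c1 = am[:, None, 0] + ap[None, :, 0]
    c2 = am[:, None, 1] + ap[None, :, 1]
    return (3 * c1 + c2).ravel()


def _gamete_probs(r: float) -> np.ndarray:
    return np.where(_REC4 == 1.0, r / 2.0, (1.0 - r) / 2.0)


def _cell_probs(r: float, cells: np.ndarray) -> np.ndarray:
    w = _gamete_probs(r)
    p16 = np.outer(w, w).ravel()
    return np.bincount(cells, weights=p16, minlength=9)


def _loglik(r: float, counts: np.ndarray, cells: np.ndarray) -> float:
    p = _cell_probs(r, cells)
    nz = counts > 0
    if np.any(p[nz] <= 0):
        return -np.inf
    return float(np.sum(counts[nz] * np.log(p[nz])))


_COARSE_RS = np.linspace(0.0, 0.5, 51)


def _loglik_vec(rs: np.ndarray, counts: np.ndarray,
                cells: np.ndarray) -> np.ndarray:
    """Log-likelihood at each r of ``rs`` (vectorized over the grid)."""
    w0 = (1.0 - rs) / 2.0
    w1 = rs / 2.0
    wm = np.where(_REC4[:, None] == 1.0, w1[None, :], w0[None, :])
    p = np.zeros((9, rs.size))
    for gm in range(4):
        for gp in range(4):
            p[cells[4 * gm + gp]] += wm[gm] * wm[gp]
    nz = counts > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = np.sum(counts[nz, None] * np.log(p[nz]), axis=0)
    ll[~np.isfinite(ll)] = -np.inf
    return ll


def _refine_r(r: float, ll: float, ll_vec_fn) -> tuple[float, float]:
    """Two rounds of local grid refinement around r (windows 5e-3, 1e-4).

    EM converges geometrically slowly on nearly flat likelihoods; this
    finishing step pins the maximizer to ~2e-6 resolution.
    """
    for half, step in ((5e-3, 1e-4), (1e-4, 2e-6)):
        lo = max(0.0, r - half)
        hi = min(0.5, r + half)
        rs = np.clip(np.arange(lo, hi + step / 2, step), 0.0, 0.5)
        lls = ll_vec_fn(rs)
        i = int(np.argmax(lls))
        if lls[i] > ll:
            r, ll = float(rs[i]), float(lls[i])
    return r, ll


def _maximize_rf(counts, cells, inf_f, inf_m) -> tuple[float, float]:
    """EM from r0 = 0.25 with grid safeguards.

    The per-phase likelihood is a low-degree polynomial in r and can carry
    an interior stationary point distinct from the constrained maximum
    (which may sit at the r = 0.5 boundary); EM alone stalls there.  A
    51-point grid locates the global basin, EM restarts from the best grid
    point when that beats the first run, and a local refinement finishes
    the flat tail of the climb.
    """
    r = _em_rf(counts, cells, inf_f, inf_m)
    ll = _loglik(r, counts, cells)
    grid_ll = _loglik_vec(_COARSE_RS, counts, cells)
    i = int(np.argmax(grid_ll))
    if grid_ll[i] > ll + 1e-12:
        r0 = float(np.clip(_COARSE_RS[i], 1e-6, 0.5 - 1e-6))
        r2 = _em_rf(counts, cells, inf_f, inf_m, r0=r0)
        ll2 = _loglik(r2, counts, cells)
        if ll2 > ll:
            r, ll = r2, ll2
        if grid_ll[i] > ll:
            r, ll = float(_COARSE_RS[i]), float(grid_ll[i])
    return _refine_r(r, ll, lambda rs: _loglik_vec(rs, counts, cells))


def _em_rf(counts: np.ndarray, cells: np.ndarray,
           inf_m: bool, inf_p: bool, r0: float = 0.25) -> float:
    """EM for r on the 16-configuration mixture.

    The E-step computes the posterior expected number of recombination events
    among informative meioses given the observed class counts; the M-step
    divides by the number of informative meioses.  One step gives the closed
    form when classes identify configurations uniquely.  Only informative
    parents' events are counted: a non-informative parent's posterior expected
    events equal the prior r and must enter neither numerator nor denominator.
    """
    n = float(counts.sum())
    denom = n * (int(inf_m) + int(inf_p))
    rec16 = _REC_M16 * float(inf_m) + _REC_P16 * float(inf_p)
    r = r0
    for _ in range(_EM_MAX_ITER):
        w = _gamete_probs(r)
        p16 = np.outer(w, w).ravel()
        p_cell = np.bincount(cells, weights=p16, minlength=9)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(p_cell > 0, counts / p_cell, 0.0)
        post = p16 * ratio[cells]
        erec = float(post @ rec16)
        r_new = min(max(erec / denom, 1e-9), 0.5)
        if abs(r_new - r) < _EM_TOL:
            r = r_new
            break
        r = r_new
    return r


@dataclass
class TwoPointResult:
    """Per-phase recombination-fraction estimates for one marker pair.

    ``per_phase`` maps each distinguishable :class:`PhaseAssignment` to its
    maximized ``(r_hat, log-likelihood)``; ``lod`` compares the best phase
    against independence (r = 0.5) on the log10 scale.
    """

    pair: tuple[str, str]
    per_phase: dict[PhaseAssignment, tuple[float, float]]
    best_phase: PhaseAssignment
    r_best: float
    lod: float
    n_used: int
    n_informative_meioses: int = 0
    joint: bool = False

    @property
    def loglik_best(self) -> float:
        return self.per_phase[self.best_phase][1]


def _counts9(m1: MarkerData, m2: MarkerData) -> tuple[np.ndarray, int]:
    mask = (m1.calls != MISSING) & (m2.calls != MISSING)
    c1 = m1.calls[mask].astype(int)
    c2 = m2.calls[mask].astype(int)
    counts = np.bincount(3 * c1 + c2, minlength=9).astype(float)
    return counts, int(mask.sum())


def _orient_for_phase(phase: str | None) -> tuple[int, int]:
    # coupling: 'a' alleles on the same homolog at both loci
    return (0, 0) if phase in (None, "C") else (0, 1)


def rf_twopoint(m1: MarkerData, m2: MarkerData) -> TwoPointResult:
    """Maximum-likelihood two-point analysis of one marker pair.

    Progeny missing either call are excluded pairwise.  Raises ``ValueError``
    with fewer than two jointly non-missing progeny.  Pairs with no parent
    heterozygous at both markers carry no linkage information and are
    reported at r = 0.5 with LOD 0.
    """
    counts, n_used = _counts9(m1, m2)
    if n_used < 2:
        raise ValueError(
            f"pair ({m1.name}, {m2.name}): only {n_used} jointly "
            "non-missing progeny"
        )
    f_het = (m1.female_het, m2.female_het)
    m_het = (m1.male_het, m2.male_het)
    inf_f = all(f_het)
    inf_m = all(m_het)
    n_inf = int(inf_f) + int(inf_m)

    female_phases = ("C", "R") if inf_f else (None,)
    male_phases = ("C", "R") if inf_m else (None,)

    per_phase: dict[PhaseAssignment, tuple[float, float]] = {}
    cells_any = None
    for pf in female_phases:
        for pm in male_phases:
            cells = _pair_cells(f_het, _orient_for_phase(pf),
                                m_het, _orient_for_phase(pm))
            cells_any = cells
            if n_inf == 0:
                per_phase[PhaseAssignment(pf, pm)] = (
                    0.5, _loglik(0.5, counts, cells))
                continue
            per_phase[PhaseAssignment(pf, pm)] = _maximize_rf(
                counts, cells, inf_f, inf_m)

    best_phase = max(per_phase, key=lambda k: (per_phase[k][1],
                                               _phase_rank(k)))
    r_best, ll_best = per_phase[best_phase]
    ll_half = _loglik(0.5, counts, cells_any)
    if r_best >= 0.5 - 1e-6:
        r_best = 0.5
    lod = max((ll_best - ll_half) / _LN10, 0.0)
    if r_best == 0.5:
        lod = 0.0
    return TwoPointResult(
        pair=(m1.name, m2.name), per_phase=per_phase, best_phase=best_phase,
        r_best=r_best, lod=lod, n_used=n_used,
        n_informative_meioses=n_used * n_inf,
    )


def _phase_rank(p: PhaseAssignment) -> tuple:
    order = {None: 0, "C": 1, "R": 2}
    return (-order[p.female], -order[p.male], -order[p.male2])


def rf_twopoint_joint(
    m1_pop1: MarkerData, m2_pop1: MarkerData,
    m1_pop2: MarkerData, m2_pop2: MarkerData,
) -> TwoPointResult:
    """Joint two-point analysis over two populations sharing the female parent.

    A single recombination fraction is assumed homogeneous between
    populations; for each distinguishable joint phase (shared female phase,
    one male phase per cross — up to eight), the summed log-likelihood of both
    populations is maximized over r by pooling expected recombination events
    from both crosses.
    """
    if (m1_pop1.name != m1_pop2.name) or (m2_pop1.name != m2_pop2.name):
        raise ValueError("joint estimation requires the same two markers "
                         "in both populations")
    if (m1_pop1.female_gt != m1_pop2.female_gt
            or m2_pop1.female_gt != m2_pop2.female_gt):
        raise ValueError("female parental genotypes differ between "
                         "populations; the female parent must be shared")

    counts1, n1 = _counts9(m1_pop1, m2_pop1)
    counts2, n2 = _counts9(m1_pop2, m2_pop2)
    if n2 == 0:
        res = rf_twopoint(m1_pop1, m2_pop1)
        res.joint = True
        return res
    if n1 == 0:
        res = rf_twopoint(m1_pop2, m2_pop2)
        res.joint = True
        return res

    f_het = (m1_pop1.female_het, m2_pop1.female_het)
    m1_het = (m1_pop1.male_het, m2_pop1.male_het)
    m2_het = (m1_pop2.male_het, m2_pop2.male_het)
    inf_f = all(f_het)
    inf_m1 = all(m1_het)
    inf_m2 = all(m2_het)

    female_phases = ("C", "R") if inf_f else (None,)
    male1_phases = ("C", "R") if inf_m1 else (None,)
    male2_phases = ("C", "R") if inf_m2 else (None,)

    per_phase: dict[PhaseAssignment, tuple[float, float]] = {}
    cells_any = None
    for pf in female_phases:
        of = _orient_for_phase(pf)
        for pm1 in male1_phases:
            cells1 = _pair_cells(f_het, of, m1_het, _orient_for_phase(pm1))
            for pm2 in male2_phases:
                cells2 = _pair_cells(f_het, of, m2_het,
                                     _orient_for_phase(pm2))
                cells_any = (cells1, cells2)
                r = _em_rf_joint(
                    counts1, cells1, inf_f, inf_m1,
                    counts2, cells2, inf_f, inf_m2)
                ll = (_loglik(r, counts1, cells1)
                      + _loglik(r, counts2, cells2))
                grid_ll = (_loglik_vec(_COARSE_RS, counts1, cells1)
                           + _loglik_vec(_COARSE_RS, counts2, cells2))
                i = int(np.argmax(grid_ll))
                if grid_ll[i] > ll + 1e-12:
                    r0 = float(np.clip(_COARSE_RS[i], 1e-6, 0.5 - 1e-6))
                    r2 = _em_rf_joint(counts1, cells1, inf_f, inf_m1,
                                      counts2, cells2, inf_f, inf_m2, r0=r0)
                    ll2 = (_loglik(r2, counts1, cells1)
                           + _loglik(r2, counts2, cells2))
                    if ll2 > ll:
                        r, ll = r2, ll2
                    if grid_ll[i] > ll:
                        r, ll = float(_COARSE_RS[i]), float(grid_ll[i])
                r, ll = _refine_r(
                    r, ll,
                    lambda rs: (_loglik_vec(rs, counts1, cells1)
                                + _loglik_vec(rs, counts2, cells2)))
                per_phase[PhaseAssignment(pf, pm1, pm2)] = (r, ll)

    best_phase = max(per_phase, key=lambda k: (per_phase[k][1],
                                               _phase_rank(k)))
    r_best, ll_best = per_phase[best_phase]
    ll_half = (_loglik(0.5, counts1, cells_any[0])
               + _loglik(0.5, counts2, cells_any[1]))
    if r_best >= 0.5 - 1e-6:
        r_best = 0.5
    lod = max((ll_best - ll_half) / _LN10, 0.0)
    if r_best == 0.5:
        lod = 0.0
    n_inf_meioses = (n1 * (int(inf_f) + int(inf_m1))
                     + n2 * (int(inf_f) + int(inf_m2)))
    return TwoPointResult(
        pair=(m1_pop1.name, m2_pop1.name), per_phase=per_phase,
        best_phase=best_phase, r_best=r_best, lod=lod, n_used=n1 + n2,
        n_informative_meioses=n_inf_meioses, joint=True,
    )


def _em_rf_joint(counts1, cells1, inf_f1, inf_m1,
                 counts2, cells2, inf_f2, inf_m2,
                 r0: float = 0.25) -> float:
    denom = (counts1.sum() * (int(inf_f1) + int(inf_m1))
             + counts2.sum() * (int(inf_f2) + int(inf_m2)))
    if denom == 0:
        return 0.5
    rec1 = _REC_M16 * float(inf_f1) + _REC_P16 * float(inf_m1)
    rec2 = _REC_M16 * float(inf_f2) + _REC_P16 * float(inf_m2)
    r = r0
    for _ in range(_EM_MAX_ITER):
        erec = 0.0
        w = _gamete_probs(r)
        p16 = np.outer(w, w).ravel()
        for counts, cells, rec16 in ((counts1, cells1, rec1),
                                     (counts2, cells2, rec2)):
            if not rec16.any():
                continue
            p_cell = np.bincount(cells, weights=p16, minlength=9)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(p_cell > 0, counts / p_cell, 0.0)
            erec += float((p16 * ratio[cells]) @ rec16)
        r_new = min(max(erec / denom, 1e-9), 0.5)
        if abs(r_new - r) < _EM_TOL:
            return r_new
        r = r_new
    return r


def twopoint_matrix(dataset) -> dict[tuple[str, str], TwoPointResult]:
    """All-pairs two-point results keyed by both orderings of the names."""
    out: dict[tuple[str, str], TwoPointResult] = {}
    markers = dataset.markers
    for i in range(len(markers)):
        for j in range(i + 1, len(markers)):
            res = rf_twopoint(markers[i], markers[j])
            out[(markers[i].name, markers[j].name)] = res
            out[(markers[j].name, markers[i].name)] = res
    return out


def twopoint_matrix_joint(
    ds1, ds2, names: list[str] | None = None
) -> dict[tuple[str, str], TwoPointResult]:
    """Joint two-point results for markers shared by both datasets."""
    if names is None:
        names = [n for n in ds1.marker_names if n in ds2]
    out: dict[tuple[str, str], TwoPointResult] = {}
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            res = rf_twopoint_joint(ds1.marker(a), ds1.marker(b),
                                    ds2.marker(a), ds2.marker(b))
            out[(a, b)] = res
            out[(b, a)] = res
    return out
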