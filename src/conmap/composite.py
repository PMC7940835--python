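"""Composite map construction from two connected populations.

The composite map pools the meioses of two F1 crosses that share their
female parent.  Markers mapped in both populations form a *framework* whose
recombination fractions are re-estimated jointly (per-population E-step,
pooled M-step); the initial framework order is whichever individual map's
restricted order has the higher joint likelihood, markers with ordering
conflicts between the individual maps are re-placed at their joint-likelihood
argmax position, and a joint ripple verifies local orders.  Markers unique to
one population cannot contribute to a multipopulation recombination fraction;
they are inserted at scaled positions: the distance to the flanking common
marker on their own map is multiplied by the ratio of composite to individual
interval length (interval scaling factor), or by the ratio of total group
lengths for markers beyond the outermost common marker (terminal factor).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PopulationDataset
from .hmm import GeneticMap, em_fit_joint
from .ordering import Fitter, ripple

log = logging.getLogger(__name__)

__all__ = ["CompositeMap", "InsertedMarker", "build_framework",
           "resolve_conflicts", "insert_unique", "build_composite",
           "CompositeResult"]


@dataclass
class InsertedMarker:
    name: str
    source_population: str          # 'pop1' | 'pop2'
    position_cm: float
    scaling_factor: float
    scope: str                      # 'interval' | 'terminal'


@dataclass
class CompositeMap:
    """Framework plus scaled-in unique markers for one linkage group."""

    framework: GeneticMap
    inserted: list[InsertedMarker]
    group_id: int = 1

    @property
    def full_order(self) -> list[tuple[str, float, str]]:
        """(name, position cM, provenance) merged and shifted to start at 0.

        Unique markers from either population falling in the same interval
        are merged by scaled position, ties broken by population then name.
        """
        fw_pos = self.framework.positions_cm
        rows = [(nm, float(p), "shared")
                for nm, p in zip(self.framework.marker_names, fw_pos)]
        rows += [(m.name, m.position_cm, f"{m.source_population}-only")
                 for m in self.inserted]
        rows.sort(key=lambda t: (t[1], t[2], t[0]))
        if rows:
            base = rows[0][1]
            rows = [(nm, p - base, prov) for nm, p, prov in rows]
        return rows

    @property
    def n_markers(self) -> int:
        return self.framework.n_markers + len(self.inserted)

    @property
    def length_cm(self) -> float:
        rows = self.full_order
        return rows[-1][1] - rows[0][1] if rows else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.group_id, nm, round(p, 4), prov)
             for nm, p, prov in self.full_order],
            columns=["linkage_group", "marker_name", "position_cM",
                     "provenance"],
        )


def _shared_names(map1: GeneticMap, map2: GeneticMap) -> list[str]:
    in2 = set(map2.marker_names)
    return [nm for nm in map1.marker_names if nm in in2]


def build_framework(
    map1: GeneticMap, map2: GeneticMap,
    ds1: PopulationDataset, ds2: PopulationDataset,
    epsilon: float = 0.05,
) -> GeneticMap:
    """Initial framework over shared markers with jointly estimated rf.

    The two candidate orders (each individual map's order restricted to the
    shared markers) are scored with the joint EM; the higher-likelihood one
    wins (population 1 on ties).  Raises ``ValueError`` with fewer than two
    shared markers.
    """
    shared = _shared_names(map1, map2)
    if len(shared) < 2:
        raise ValueError(
            f"only {len(shared)} shared marker(s); no framework possible")
    order1 = shared
    in1 = set(shared)
    order2 = [nm for nm in map2.marker_names if nm in in1]
    fit1 = em_fit_joint(order1, ds1, ds2, epsilon=epsilon)
    if order2 == order1 or order2 == order1[::-1]:
        return fit1
    fit2 = em_fit_joint(order2, ds1, ds2, epsilon=epsilon)
    return fit1 if fit1.loglik >= fit2.loglik else fit2


def _lcs(a: list[str], b: list[str]) -> list[str]:
    """Longest common subsequence, lexicographically smallest among maxima."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1), dtype=int)
    for i in range(n - 1, -1, -1):
        for j in range(m - 1, -1, -1):
            if a[i] == b[j]:
                dp[i, j] = dp[i + 1, j + 1] + 1
            else:
                dp[i, j] = max(dp[i + 1, j], dp[i, j + 1])
    out: list[str] = []
    i = j = 0
    while i < n and j < m:
        if a[i] == b[j] and dp[i, j] == dp[i + 1, j + 1] + 1:
            out.append(a[i])
            i += 1
            j += 1
        elif dp[i + 1, j] > dp[i, j + 1]:
            i += 1
        elif dp[i + 1, j] < dp[i, j + 1]:
            j += 1
        else:
            # tie: advance on the side whose current element is larger,
            # keeping smaller names available for the subsequence
            if a[i] <= b[j]:
                j += 1
            else:
                i += 1
    return out


def conflict_set(order1: list[str], order2: list[str]) -> list[str]:
    """Shared markers whose relative order differs between the two maps.

    The conflict set is the complement of the longest common subsequence of
    the two orders (the second reversed if that matches better, since a map
    and its mirror are equivalent).
    """
    lcs_f = _lcs(order1, order2)
    lcs_r = _lcs(order1, order2[::-1])
    lcs = lcs_f if len(lcs_f) >= len(lcs_r) else lcs_r
    keep = set(lcs)
    return [nm for nm in order1 if nm not in keep]


def resolve_conflicts(
    framework: GeneticMap,
    map1: GeneticMap, map2: GeneticMap,
    ds1: PopulationDataset, ds2: PopulationDataset,
    epsilon: float = 0.05,
    window: int = 4,
    score_iters: int = 20,
) -> GeneticMap:
    """Re-place order-conflicting shared markers at their joint argmax.

    Conflict markers (outside the LCS of the two restricted orders) are
    processed in decreasing order of joint two-point information; each is
    removed and scored at every position of the framework, the best position
    accepted before the next marker is evaluated.  A joint ripple finishes.
    The joint log-likelihood never decreases.
    """
    shared = set(framework.marker_names)
    order1 = [nm for nm in map1.marker_names if nm in shared]
    order2 = [nm for nm in map2.marker_names if nm in shared]
    conflicts = conflict_set(order1, order2)

    fitter = Fitter((ds1, ds2), epsilon=epsilon, score_iters=score_iters)
    current = list(framework.marker_names)

    def _info(nm: str) -> tuple:
        info = (ds1.marker(nm).n_informative_meioses
                + ds2.marker(nm).n_informative_meioses)
        return (-info, nm)

    for nm in sorted(conflicts, key=_info):
        reduced = [x for x in current if x != nm]
        best = None
        for pos in range(len(reduced) + 1):
            cand = reduced[:pos] + [nm] + reduced[pos:]
            ll = fitter.loglik(cand)
            if best is None or ll > best[0] + 1e-12:
                best = (ll, cand)
        current = best[1]

    gm = fitter.fit(current, full=True)
    gm = ripple(gm, (ds1, ds2), window=window, epsilon=epsilon,
                fitter=fitter)
    if gm.loglik < framework.loglik - 1e-9:
        return framework
    return gm


def _oriented_positions(gm: GeneticMap, fw_pos: dict[str, float]
                        ) -> dict[str, float]:
    """Individual-map positions, flipped if the map mirrors the framework."""
    pos = {nm: p for nm, p in zip(gm.marker_names, gm.positions_cm)}
    common = [nm for nm in gm.marker_names if nm in fw_pos]
    if len(common) >= 2:
        x = np.array([pos[nm] for nm in common])
        y = np.array([fw_pos[nm] for nm in common])
        if np.corrcoef(x, y)[0, 1] < 0:
            length = gm.length_cm
            pos = {nm: length - p for nm, p in pos.items()}
    return pos


def insert_unique(
    composite: GeneticMap | CompositeMap,
    map1: GeneticMap, map2: GeneticMap,
) -> CompositeMap:
    """Insert population-unique markers at scaled positions.

    For a unique marker between two common markers of its own map, its
    distance from the left common flank is multiplied by (composite interval
    length / individual interval length); beyond the outermost common marker
    the ratio of total group lengths is used, anchored at that outermost
    common marker.
    """
    framework = (composite.framework if isinstance(composite, CompositeMap)
                 else composite)
    fw_pos = {nm: p for nm, p in zip(framework.marker_names,
                                     framework.positions_cm)}
    fw_len = framework.length_cm
    inserted: list[InsertedMarker] = []
    for gm, pop in ((map1, "pop1"), (map2, "pop2")):
        pos = _oriented_positions(gm, fw_pos)
        ind_len = gm.length_cm
        common = sorted((nm for nm in gm.marker_names if nm in fw_pos),
                        key=lambda nm: pos[nm])
        if not common:
            continue
        t_factor = fw_len / ind_len if ind_len > 0 else 1.0
        for nm in gm.marker_names:
            if nm in fw_pos:
                continue
            p = pos[nm]
            left = [c for c in common if pos[c] <= p]
            right = [c for c in common if pos[c] > p]
            if left and right:
                lft, rgt = left[-1], right[0]
                d_ind = pos[rgt] - pos[lft]
                d_comp = fw_pos[rgt] - fw_pos[lft]
                factor = abs(d_comp) / d_ind if d_ind > 0 else 1.0
                sign = 1.0 if d_comp >= 0 else -1.0
                newpos = fw_pos[lft] + sign * (p - pos[lft]) * factor
                scope = "interval"
            elif left:
                anchor = left[-1]
                newpos = fw_pos[anchor] + (p - pos[anchor]) * t_factor
                factor = t_factor
                scope = "terminal"
            else:
                anchor = right[0]
                newpos = fw_pos[anchor] - (pos[anchor] - p) * t_factor
                factor = t_factor
                scope = "terminal"
            inserted.append(InsertedMarker(
                name=nm, source_population=pop,
                position_cm=float(newpos), scaling_factor=float(factor),
                scope=scope))
    group_id = composite.group_id if isinstance(composite, CompositeMap) else 1
    return CompositeMap(framework=framework, inserted=inserted,
                        group_id=group_id)


@dataclass
class CompositeResult:
    """End-to-end output: composite groups plus re-expressed individual maps."""

    composite_groups: list[CompositeMap]
    individual_maps: dict[str, list[GeneticMap]]
    unmerged: dict[str, list[GeneticMap]] = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        rows = []
        for cm in self.composite_groups:
            n = cm.n_markers
            length = cm.length_cm
            rows.append({
                "linkage_group": cm.group_id,
                "n_markers": n,
                "n_shared": cm.framework.n_markers,
                "length_cM": round(length, 2),
                "marker_density": round(length / (n - 1), 2) if n > 1 else "NA",
            })
        return pd.DataFrame(rows)

    def map_table(self) -> pd.DataFrame:
        """All composite groups, plus unmerged single-population groups
        appended as their own linkage groups."""
        frames = [cm.to_frame() for cm in self.composite_groups]
        gid = len(self.composite_groups)
        for pop in sorted(self.unmerged):
            for gm in self.unmerged[pop]:
                gid += 1
                frames.append(pd.DataFrame(
                    [(gid, nm, round(float(p), 4), f"{pop}-only")
                     for nm, p in zip(gm.marker_names, gm.positions_cm)],
                    columns=["linkage_group", "marker_name", "position_cM",
                             "provenance"]))
        if not frames:
            return pd.DataFrame(columns=["linkage_group", "marker_name",
                                         "position_cM", "provenance"])
        return pd.concat(frames, ignore_index=True)


def match_groups(
    maps1: list[GeneticMap], maps2: list[GeneticMap], min_shared: int = 2
) -> list[tuple[GeneticMap, GeneticMap, int]]:
    """Pair homologous groups greedily by shared-marker count."""
    pairs = []
    for i, g1 in enumerate(maps1):
        for j, g2 in enumerate(maps2):
            n = len(_shared_names(g1, g2))
            if n >= min_shared:
                pairs.append((n, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used1, used2, out = set(), set(), []
    for n, i, j in pairs:
        if i in used1 or j in used2:
            continue
        used1.add(i)
        used2.add(j)
        out.append((maps1[i], maps2[j], n))
    return out


def build_composite(
    ds1: PopulationDataset,
    ds2: PopulationDataset,
    maps1: list[GeneticMap],
    maps2: list[GeneticMap],
    epsilon: float = 0.05,
    window: int = 4,
    score_iters: int = 20,
) -> CompositeResult:
    """Framework -> conflict resolution -> joint ripple -> unique insertion.

    ``maps1``/``maps2`` are the finished per-group individual maps.  Shared
    markers mapped to non-homologous groups are excluded with a warning;
    groups with fewer than two shared markers pass through unmerged.
    """
    matched = match_groups(maps1, maps2)
    matched_ids1 = {id(a) for a, _, _ in matched}
    matched_ids2 = {id(b) for _, b, _ in matched}
    unmerged = {
        "pop1": [g for g in maps1 if id(g) not in matched_ids1],
        "pop2": [g for g in maps2 if id(g) not in matched_ids2],
    }
    # shared markers split across different homologous pairs are conflicted
    # between maps at the group level and excluded from frameworks
    composite_groups: list[CompositeMap] = []
    individual: dict[str, list[GeneticMap]] = {"pop1": [], "pop2": []}
    for gid, (g1, g2, n_shared) in enumerate(matched, start=1):
        fw = build_framework(g1, g2, ds1, ds2, epsilon=epsilon)
        fw = resolve_conflicts(fw, g1, g2, ds1, ds2, epsilon=epsilon,
                               window=window, score_iters=score_iters)
        cm = insert_unique(fw, g1, g2)
        cm.group_id = gid
        composite_groups.append(cm)
        # re-express each individual map in the final composite order
        full_names = [nm for nm, _, _ in cm.full_order]
        from .hmm import em_fit  # local import to avoid cycle at module load
        for ds, key in ((ds1, "pop1"), (ds2, "pop2")):
            names = [nm for nm in full_names if nm in ds
                     and (nm in g1.marker_names if key == "pop1"
                          else nm in g2.marker_names)]
            if len(names) >= 2:
                individual[key].append(em_fit(names, ds, epsilon=epsilon))
    if unmerged["pop1"] or unmerged["pop2"]:
        log.warning("groups without a homologous partner passed through "
                    "unmerged: pop1=%d, pop2=%d",
                    len(unmerged["pop1"]), len(unmerged["pop2"]))
    return CompositeResult(composite_groups=composite_groups,
                           individual_maps=individual, unmerged=unmerged)
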