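"""Simulation of connected F1 populations with known truth.

The generator emulates the crossing design the mapping method targets: two
full-sib F1 populations sharing the female parent (default sizes 160 and
184).  Markers are drawn from the five joint configuration classes at the
empirically observed proportions for shared markers (D1.10-D1.10 36.88%,
B3.7-B3.7 25.34%, D2.15-D2.15 21.59%, B3.7-D1.10 8.94%, D1.10-B3.7 7.25%).
Gametes are generated by a Markov walk over intervals with the true
recombination fractions and no crossover interference; the Kosambi function
is used only as a distance transform, so recovery checks compare r to r
where exactness matters.

Genotyping error (each call replaced by a uniformly chosen different
observable class with probability epsilon) and missing data are injected
after the clean genotypes are formed, emulating the error model the HMM
emissions assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import (
    AA, AB, MISSING, CrossType, JointCrossType, MarkerData, kosambi,
)
from .io import PopulationDataset

__all__ = ["SimConfig", "TruthMap", "make_truth", "simulate_connected",
           "inject_noise", "DEFAULT_JOINT_PROPORTIONS"]

# Observed proportions of the five joint configuration classes among shared
# markers in the motivating crossing design.
DEFAULT_JOINT_PROPORTIONS: dict[JointCrossType, float] = {
    JointCrossType.D1_10_D1_10: 0.3688,
    JointCrossType.B3_7_B3_7: 0.2534,
    JointCrossType.D2_15_D2_15: 0.2159,
    JointCrossType.B3_7_D1_10: 0.0894,
    JointCrossType.D1_10_B3_7: 0.0725,
}


@dataclass
class SimConfig:
    """Study conditions for the connected-population generator.

    Defaults reproduce the design the method targets: population sizes 160
    and 184, genotyping-error probability 0.05, 10% missing data, and the
    joint-type proportions above.  ``unique_fraction`` is the fraction of
    markers present in only one population (split evenly).  A seed is
    mandatory for reproducibility.
    """

    n1: int = 160
    n2: int = 184
    epsilon: float = 0.05
    missing_rate: float = 0.10
    unique_fraction: float = 0.0
    seed: int = 0
    joint_proportions: dict[JointCrossType, float] = field(
        default_factory=lambda: dict(DEFAULT_JOINT_PROPORTIONS))

    def __post_init__(self) -> None:
        if not (0 <= self.epsilon < 1 and 0 <= self.missing_rate < 1):
            raise ValueError("epsilon and missing_rate must lie in [0, 1)")
        if not 0 <= self.unique_fraction <= 1:
            raise ValueError("unique_fraction must lie in [0, 1]")
        total = sum(self.joint_proportions.values())
        if total <= 0:
            raise ValueError("joint-type proportions must sum to > 0")
        self.joint_proportions = {
            k: v / total for k, v in self.joint_proportions.items()}


@dataclass
class TruthMap:
    """Known truth behind a simulated pair of connected populations."""

    marker_names: list[str]
    rf: np.ndarray                   # (k-1,) per-interval truth
    joint_types: list[JointCrossType]
    presence: list[str]              # 'shared' | 'pop1' | 'pop2'
    female_phase: np.ndarray         # orientation per marker; -1 where hom
    male1_phase: np.ndarray
    male2_phase: np.ndarray

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def positions_cm(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum(kosambi(self.rf))])

    def names_in(self, pop: str) -> list[str]:
        keep = {"shared", pop}
        return [nm for nm, p in zip(self.marker_names, self.presence)
                if p in keep]

    def to_frame(self) -> pd.DataFrame:
        pos = self.positions_cm
        return pd.DataFrame({
            "linkage_group": 1,
            "marker_name": self.marker_names,
            "position_cM": np.round(pos, 4),
            "cross_type": [jt.value for jt in self.joint_types],
            "provenance": self.presence,
            "rf_to_next": np.append(np.round(self.rf, 5), np.nan),
            "female_phase": self.female_phase,
            "male1_phase": self.male1_phase,
            "male2_phase": self.male2_phase,
        })


def make_truth(
    n_markers: int,
    config: SimConfig,
    rf_range: tuple[float, float] = (0.01, 0.2),
    rng: np.random.Generator | None = None,
    prefix: str = "M",
) -> TruthMap:
    """Draw a random truth map under ``config``.

    Per-interval recombination fractions are uniform on ``rf_range``; joint
    types follow ``config.joint_proportions``; parental phases are random
    where the parent is heterozygous.  ``unique_fraction`` of markers are
    flagged pop1- or pop2-only, alternately.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_markers < 2:
        raise ValueError("need at least two markers")
    names = [f"{prefix}{i + 1:03d}" for i in range(n_markers)]
    rf = rng.uniform(rf_range[0], rf_range[1], size=n_markers - 1)
    types = list(config.joint_proportions.keys())
    probs = np.array([config.joint_proportions[t] for t in types])
    joint_types = [types[i] for i in rng.choice(len(types), size=n_markers,
                                                p=probs)]
    n_unique = int(round(config.unique_fraction * n_markers))
    presence = ["shared"] * n_markers
    unique_idx = rng.choice(n_markers, size=n_unique, replace=False)
    for rank, idx in enumerate(sorted(unique_idx)):
        presence[idx] = "pop1" if rank % 2 == 0 else "pop2"

    def _phases(het: list[bool]) -> np.ndarray:
        return np.array([rng.integers(0, 2) if h else -1 for h in het])

    female_het = [jt.pop1 is not CrossType.D2_15 for jt in joint_types]
    male1_het = [jt.pop1 is not CrossType.D1_10 for jt in joint_types]
    male2_het = [jt.pop2 is not CrossType.D1_10 for jt in joint_types]
    return TruthMap(
        marker_names=names, rf=rf, joint_types=joint_types,
        presence=presence,
        female_phase=_phases(female_het),
        male1_phase=_phases(male1_het),
        male2_phase=_phases(male2_het),
    )


def _gametes(n: int, rf: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """(n, k) homolog indices from a no-interference Markov walk."""
    k = rf.size + 1
    h = np.empty((n, k), dtype=np.int8)
    h[:, 0] = rng.integers(0, 2, size=n)
    if k > 1:
        rec = rng.random((n, k - 1)) < rf[None, :]
        h[:, 1:] = h[:, [0]] ^ np.bitwise_xor.accumulate(
            rec.astype(np.int8), axis=1)
    return h


def _pop_dataset(
    truth: TruthMap, pop: str, n: int, female_id: str, male_id: str,
    male_phase: np.ndarray, cross_of, rng: np.random.Generator,
) -> PopulationDataset:
    k = truth.n_markers
    hm = _gametes(n, truth.rf, rng)
    hp = _gametes(n, truth.rf, rng)
    female_het = truth.female_phase >= 0
    male_het = male_phase >= 0
    # allele 'b' transmitted iff the parent is het and the gamete carries the
    # homolog opposite the one holding the reference allele
    a_f = female_het[None, :] & (hm != np.where(female_het,
                                                truth.female_phase, 0)[None, :])
    a_m = male_het[None, :] & (hp != np.where(male_het,
                                              male_phase, 0)[None, :])
    geno = a_f.astype(np.int8) + a_m.astype(np.int8)

    keep = [j for j in range(k)
            if truth.presence[j] in ("shared", pop)]
    markers = []
    for j in keep:
        ct = cross_of(truth.joint_types[j])
        female_gt = "ab" if female_het[j] else "aa"
        male_gt = "ab" if male_het[j] else "aa"
        markers.append(MarkerData(
            name=truth.marker_names[j], female_gt=female_gt,
            male_gt=male_gt, calls=geno[:, j], cross_type=ct))
    progeny = [f"{pop}_{i + 1:03d}" for i in range(n)]
    return PopulationDataset(pop, female_id, male_id, progeny, markers)


def simulate_connected(
    truth: TruthMap, config: SimConfig
) -> tuple[PopulationDataset, PopulationDataset]:
    """Generate the two connected populations described by ``truth``.

    Maternal meioses in both populations sample the same female genome
    (identical phasing), paternal meioses the population's own father.
    Noise and missingness from ``config`` are injected after the clean
    genotypes; everything is deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    ds1 = _pop_dataset(truth, "pop1", config.n1, "TCO", "BR",
                       truth.male1_phase, lambda jt: jt.pop1, rng)
    ds2 = _pop_dataset(truth, "pop2", config.n2, "TCO", "DP",
                       truth.male2_phase, lambda jt: jt.pop2, rng)
    if config.epsilon > 0 or config.missing_rate > 0:
        ds1 = inject_noise(ds1, config.epsilon, config.missing_rate, rng)
        ds2 = inject_noise(ds2, config.epsilon, config.missing_rate, rng)
    return ds1, ds2


def inject_noise(
    dataset: PopulationDataset, epsilon: float, missing_rate: float,
    rng_or_seed,
) -> PopulationDataset:
    """Return a copy with genotyping errors and missing calls injected.

    Each call is independently replaced by a uniformly chosen *different*
    observable class with probability ``epsilon``, then set missing with
    probability ``missing_rate``.
    """
    if not (0 <= epsilon < 1 and 0 <= missing_rate < 1):
        raise ValueError("rates must lie in [0, 1)")
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(rng_or_seed))
    markers = []
    for m in dataset.markers:
        calls = m.calls.copy()
        classes = np.array(m.cross_type.observable_classes, dtype=np.int8)
        err = (rng.random(calls.size) < epsilon) & (calls != MISSING)
        if err.any():
            idx = np.nonzero(err)[0]
            # uniform over the other observable classes
            offsets = rng.integers(1, classes.size, size=idx.size)
            pos = np.searchsorted(classes, calls[idx])
            calls[idx] = classes[(pos + offsets) % classes.size]
        miss = rng.random(calls.size) < missing_rate
        calls[miss] = MISSING
        markers.append(MarkerData(
            name=m.name, female_gt=m.female_gt, male_gt=m.male_gt,
            calls=calls, cross_type=m.cross_type))
    return PopulationDataset(
        dataset.population_id, dataset.female_id, dataset.male_id,
        list(dataset.progeny_ids), markers)
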