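"""Core domain types for outcrossing F1 linkage mapping.

An F1 full-sib cross between two non-inbred diploid parents segregates at any
biallelic SNP where at least one parent is heterozygous.  Three cross types are
informative for map construction:

* ``B3.7``  — ``ab x ab``: both parents heterozygous, progeny segregate 1:2:1
  over ``aa``/``ab``/``bb``.
* ``D1.10`` — ``ab x aa``: only the female parent heterozygous (a maternal
  testcross), progeny segregate 1:1 over ``aa``/``ab``.
* ``D2.15`` — ``aa x ab``: only the male parent heterozygous (a paternal
  testcross), 1:1.

When two crosses share the female parent, a marker segregating in both can be
described by a *joint* cross type; exactly five joint configurations carry
information for integrating the populations.

This module also provides the Kosambi map function and a Bonferroni-style LOD
threshold helper; everything here is pure and deterministic.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AA", "AB", "BB", "MISSING",
    "GT_CODES", "GT_NAMES",
    "CrossType", "JointCrossType", "MarkerData", "PhaseAssignment",
    "NonInformativeError", "NoIntegrationInfoError",
    "classify_cross_type", "classify_joint_type",
    "joint_phase_assignments",
    "kosambi", "kosambi_inverse", "suggest_lod",
]

# Integer genotype-class coding used throughout: number of "b" alleles.
AA, AB, BB = 0, 1, 2
MISSING = -1

GT_CODES = {"aa": AA, "ab": AB, "bb": BB, "-": MISSING}
GT_NAMES = {AA: "aa", AB: "ab", BB: "bb", MISSING: "-"}


class NonInformativeError(ValueError):
    """Both parents homozygous: the marker does not segregate."""


class NoIntegrationInfoError(ValueError):
    """The marker carries no information to integrate the two populations."""


class CrossType(str, enum.Enum):
    B3_7 = "B3.7"
    D1_10 = "D1.10"
    D2_15 = "D2.15"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def observable_classes(self) -> tuple[int, ...]:
        """Genotype classes a progeny call may legally take."""
        if self is CrossType.B3_7:
            return (AA, AB, BB)
        return (AA, AB)

    @property
    def expected_ratio(self) -> tuple[float, ...]:
        """Mendelian expectation over :attr:`observable_classes`."""
        if self is CrossType.B3_7:
            return (0.25, 0.5, 0.25)
        return (0.5, 0.5)


class JointCrossType(str, enum.Enum):
    """Simultaneous segregation pattern of a marker shared by two crosses."""

    B3_7_B3_7 = "B3.7-B3.7"
    B3_7_D1_10 = "B3.7-D1.10"
    D1_10_B3_7 = "D1.10-B3.7"
    D1_10_D1_10 = "D1.10-D1.10"
    D2_15_D2_15 = "D2.15-D2.15"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value

    @property
    def pop1(self) -> CrossType:
        return CrossType(self.value.split("-", 1)[0])

    @property
    def pop2(self) -> CrossType:
        return CrossType(self.value.split("-", 1)[1])


def classify_cross_type(female_gt: str, male_gt: str) -> CrossType:
    """Classify a marker from its parental genotypes.

    Parameters are unphased genotype strings in ``{"aa", "ab"}`` ("a" is the
    reference allele after import).  Raises :class:`NonInformativeError` when
    both parents are homozygous.
    """
    _check_parent_gt(female_gt, "female")
    _check_parent_gt(male_gt, "male")
    female_het = female_gt == "ab"
    male_het = male_gt == "ab"
    if female_het and male_het:
        return CrossType.B3_7
    if female_het:
        return CrossType.D1_10
    if male_het:
        return CrossType.D2_15
    raise NonInformativeError(
        f"marker with parents {female_gt} x {male_gt} does not segregate"
    )


def classify_joint_type(
    female_gt: str, male1_gt: str, male2_gt: str
) -> JointCrossType:
    """Joint configuration of a marker shared by two crosses with a common mother.

    Raises :class:`NoIntegrationInfoError` when the female parent is homozygous
    and either male parent is homozygous: such a marker segregates in at most
    one population, so the two data sets cannot be connected through it.
    """
    _check_parent_gt(female_gt, "female")
    _check_parent_gt(male1_gt, "male1")
    _check_parent_gt(male2_gt, "male2")
    female_het = female_gt == "ab"
    m1_het = male1_gt == "ab"
    m2_het = male2_gt == "ab"
    if female_het:
        if m1_het and m2_het:
            return JointCrossType.B3_7_B3_7
        if m1_het:
            return JointCrossType.B3_7_D1_10
        if m2_het:
            return JointCrossType.D1_10_B3_7
        return JointCrossType.D1_10_D1_10
    if m1_het and m2_het:
        return JointCrossType.D2_15_D2_15
    raise NoIntegrationInfoError(
        f"parents {female_gt} x {male1_gt}/{female_gt} x {male2_gt}: "
        "no information to integrate the populations"
    )


def _check_parent_gt(gt: str, who: str) -> None:
    if gt not in ("aa", "ab"):
        raise ValueError(f"{who} parental genotype must be 'aa' or 'ab', got {gt!r}")


@dataclass(frozen=True)
class PhaseAssignment:
    """Pairwise linkage phase for a marker pair.

    ``"C"`` (coupling) puts the reference alleles of the two loci on the same
    parental homolog, ``"R"`` (repulsion) on opposite homologs.  The phase of a
    parent homozygous at either locus is undefined and recorded as ``None``.
    The joint form for two connected crosses holds the shared female phase plus
    one male phase per cross; with all three parents informative this gives
    exactly eight states.
    """

    female: str | None
    male: str | None = None
    male2: str | None = field(default=None)

    def __post_init__(self) -> None:
        for p in (self.female, self.male, self.male2):
            if p not in (None, "C", "R"):
                raise ValueError(f"phase must be 'C', 'R' or None, got {p!r}")


def joint_phase_assignments() -> list[PhaseAssignment]:
    """Enumerate the joint phase states for a fully informative marker pair.

    The female phase is shared between the two crosses, so the state space is
    {C,R} (female) x {C,R} (male 1) x {C,R} (male 2) = 8 assignments.
    """
    return [
        PhaseAssignment(f, m1, m2)
        for f, m1, m2 in itertools.product("CR", repeat=3)
    ]


@dataclass
class MarkerData:
    """One marker in one F1 population.

    ``calls`` is an int8 vector over progeny with entries in
    ``{0: aa, 1: ab, 2: bb, -1: missing}``; ``bb`` is only legal for B3.7
    markers (a homozygous parent cannot transmit "b" at a D-type locus).
    """

    name: str
    female_gt: str
    male_gt: str
    calls: np.ndarray
    cross_type: CrossType = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        inferred = classify_cross_type(self.female_gt, self.male_gt)
        if self.cross_type is None:
            self.cross_type = inferred
        elif CrossType(self.cross_type) is not inferred:
            raise ValueError(
                f"marker {self.name}: declared cross type {self.cross_type} "
                f"inconsistent with parents {self.female_gt} x {self.male_gt}"
            )
        self.calls = np.asarray(self.calls, dtype=np.int8)
        legal = set(self.cross_type.observable_classes) | {MISSING}
        bad = [v for v in np.unique(self.calls) if int(v) not in legal]
        if bad:
            idx = int(np.nonzero(self.calls == bad[0])[0][0])
            raise ValueError(
                f"marker {self.name}: call {GT_NAMES.get(int(bad[0]), bad[0])!r} "
                f"for individual {idx} is inconsistent with cross type "
                f"{self.cross_type.value}"
            )

    @property
    def n_progeny(self) -> int:
        return int(self.calls.size)

    @property
    def female_het(self) -> bool:
        return self.female_gt == "ab"

    @property
    def male_het(self) -> bool:
        return self.male_gt == "ab"

    @property
    def missing_fraction(self) -> float:
        return float(np.mean(self.calls == MISSING)) if self.calls.size else 0.0

    @property
    def n_informative_meioses(self) -> int:
        """Non-missing calls times number of heterozygous parents."""
        n_obs = int(np.sum(self.calls != MISSING))
        return n_obs * (int(self.female_het) + int(self.male_het))


_LN10_X2 = 2.0 * math.log(10.0)


def kosambi(r) -> float | np.ndarray:
    """Kosambi map distance in cM: ``d = 25 ln((1+2r)/(1-2r))``.

    Strictly increasing on [0, 0.5); diverges at r = 0.5.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r >= 0.5):
        raise ValueError("recombination fraction must lie in [0, 0.5)")
    d = 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))
    return float(d) if d.ndim == 0 else d


def kosambi_inverse(d) -> float | np.ndarray:
    """Inverse of :func:`kosambi`: ``r = tanh(d/50)/2`` for d >= 0 (cM)."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * np.tanh(d / 50.0)
    return float(r) if r.ndim == 0 else r


def suggest_lod(n_markers: int, alpha: float = 0.05) -> float:
    """LOD threshold from a Bonferroni correction over all two-point tests.

    With ``C = n_markers * (n_markers - 1) / 2`` pairwise tests, the threshold
    is the chi-square(1) quantile at ``1 - alpha / C`` expressed on the LOD
    scale (divided by ``2 ln 10``).
    """
    if n_markers < 2:
        raise ValueError("need at least two markers")
    n_tests = n_markers * (n_markers - 1) // 2
    q = stats.chi2.isf(alpha / n_tests, df=1)
    return float(q / _LN10_X2)
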