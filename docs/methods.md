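# Methods

## Genetic model and assumptions

`conmap` targets F1 full-sib crosses of non-inbred diploid parents. Markers
are biallelic SNPs coded with the reference allele as "a"; the three
informative cross types are `B3.7` (ab × ab, 1:2:1), `D1.10` (ab × aa, 1:1)
and `D2.15` (aa × ab, 1:1). Both parents' meioses are modelled; a marker
heterozygous in only one parent is simply silent about the other parent's
chain at that position. Throughout, one recombination fraction per marker
pair (two-point) or per interval (multipoint) is shared by the two parents,
and — in the joint two-population estimators — by both crosses. Sex- and
population-specific recombination rates are deliberately not modelled: the
package's purpose is the integrated and composite map, whose estimator pools
meioses under homogeneity. No crossover interference is modelled in the
likelihoods; the Kosambi map function is used purely as a distance
transform.

Linkage phases are represented as per-marker homolog orientations (which
homolog carries the reference allele), with the pairwise coupling/repulsion
phase derived from consecutive orientations. The likelihood is invariant
under flipping all orientations of one parent, so the first heterozygous
marker of each parent is canonically fixed; reported phasings are unique up
to that convention, and order comparisons treat a map and its mirror as
identical.

## Two-point estimation

For a pair of markers the sixteen gamete configurations (maternal/paternal
homolog at each locus) have probabilities `(1−r)/2` or `r/2` per parent;
given phases they map deterministically onto the 9 (B3.7 × B3.7) or fewer
observable joint genotype classes. The maximum-likelihood r is found by EM
on this finite mixture: posterior expected recombination events among
*informative* meioses (a parent heterozygous at both loci) divided by their
number. A non-informative parent's posterior events equal the prior r and
are excluded from both numerator and denominator — including them would
bias the fixed point. For testcross pairs the class-to-configuration map is
invertible and the EM converges to the closed-form count ratio in one step,
so a single code path covers all configurations; a 1e-5-step grid search
over the enumerated likelihood serves as the correctness oracle in the test
suite. EM starts at r = 0.25 with tolerance 1e-8 and at most 200 iterations.
Two numerical safeguards finish the maximization: the per-phase likelihood
is a low-degree polynomial in r that can hold an interior stationary point
distinct from the constrained maximum (notably when the maximum sits at the
r = 0.5 boundary for a weakly linked pair), so a 51-point coarse grid
locates the global basin and EM restarts from its best point when that
wins; and because EM converges geometrically slowly on nearly flat
likelihoods, a two-round local grid refinement (windows 5e-3 and 1e-4)
pins the maximizer to ~2e-6.
Estimates at the 0.5 boundary are reported with LOD 0. Pairs where no parent
is heterozygous at both loci (e.g. D1.10 × D2.15) carry no two-point linkage
information and report r = 0.5, LOD 0; such markers connect through
flanking markers in the multipoint model instead.

The joint estimator for two populations sharing the female parent sums the
two populations' log-likelihoods at a common r and enumerates the shared
female phase times each cross's male phase — eight assignments when all
three parents are informative, fewer otherwise (degenerate phases are
reported as null, never enumerated, to avoid spuriously tied likelihoods).

## Multipoint HMM and EM

The hidden state per progeny per position is the inherited (maternal,
paternal) homolog pair — four states, uniform prior. Transitions are the
tensor product of the one-parent 2×2 recombination matrix with itself at
the interval's r. Emissions use a symmetric error model: the genotype class
implied by state, phasing and cross type is observed with probability
1 − ε, any other *observable* class with ε/(c−1), where c = 3 for B3.7 and
2 for testcross markers; a missing call emits 1 in every state. ε defaults
to 0.05 (the value used for GBS-derived SNP data; 0.01 is the conventional
upstream default) and is a model parameter, not an estimate.

EM: forward–backward per progeny with per-position scaling; the M-step sets
each interval's r to the expected maternal-plus-paternal recombination
count over `2N` meioses. For two populations the E-step runs per population
(meioses are independent between crosses; male phasings are
population-specific while the female phasing is shared) and the M-step
pools: `r̂_j = Σ_pops E[recombinations_j] / (2(N₁+N₂))`. r is clamped to
[1e-7, 0.49999] — both 0 and 0.5 are absorbing fixed points of the EM map.
Convergence requires both a relative log-likelihood change below 1e-6 *and*
a maximum per-interval r movement below 1e-5; the latter guards against
premature stops when |logL| is large. Initial r values come from chained
two-point estimates at the phases selected during phasing (fallback 0.1
when an adjacent pair is uninformative).

Phasing is greedy and sequential: markers are added left to right, each
candidate orientation (per informative parent; shared female orientation
across populations in the joint case) is scored by the forward likelihood
of the prefix, and the argmax is kept. When the adjacent pair is
uninformative its two-point r̂ is 0.5, which would make the transition fully
mixing and the orientation choice blind; a moderate linked value (0.15) is
substituted for scoring only, letting the forward message carry phase
information across locally uninformative steps.

The greedy pass has a structural blind spot: for a pair with both parents
heterozygous at both loci, attributing the recombination to the maternal
versus the paternal chain gives *identical* two-point likelihoods (the
parents are exchangeable in the genotype-class table), and the prefix alone
cannot break the tie — only markers added later can. A flip-polish pass
therefore follows: sweeping over markers, every combination of
informative-parent orientation flips at one marker is re-scored by a full
forward pass (interval r values re-chained from the two-point tables under
the implied phases), and flips are accepted while the total likelihood
improves. Without this polish, candidate orders evaluated during ordering
can carry a mis-phased marker whose understated likelihood corrupts order
comparisons. Phasings are re-canonicalized (first heterozygous marker per
parent at orientation 0) after polishing.

## Grouping and ordering

Linkage groups are connected components of the graph with edges at
two-point LOD ≥ 7.5 and r̂ ≤ 0.35 (defaults; the LOD default matches a
Bonferroni-style construction, `suggest_lod`, which turns the chi-square(1)
quantile at level α divided by the number of marker pairs into a LOD — for
a panel of several thousand markers this lands near 7.5).

Ordering per group: a seed of 6 markers (default) is chosen greedily with
cross-type informativeness as the primary key and maximin r̂ spread to the
already-chosen seed as the secondary key — informativeness first anchors
both parental chains and, importantly, makes seed choices consistent
between two connected populations, which the composite framework depends
on; spread distance counts uninformative pairs as zero so the seed prefers
mutually informative markers. All mirror-deduplicated seed permutations are
scored by multipoint log-likelihood; remaining markers are inserted at
their best gap when it beats the runner-up by ≥ 3.0 log10 units, with
repeated passes over the ambiguous ones (each successful placement adds an
anchor that can disambiguate the next) and a final *touchdown* round that
retries still-ambiguous markers once at a threshold one log10 unit lower —
the conventional final integration step for this family of ordering
algorithms. Insertion scoring uses a reduced EM
budget (20 iterations; the ranking of candidate orders stabilizes well
before full convergence) with converged fits for all final maps.

Suspect-position diagnostics: a framework marker beyond a terminal gap
larger than 15 cM, or an *interior* marker whose removal shrinks the group
by more than 15 cM, is pulled out and re-inserted; if no unambiguous
position exists it is restored at its original position and flagged rather
than dropped. The removal-shrink test deliberately excludes terminal
markers, whose removal always shrinks the map by genuine terminal length.
The 15 cM scale is a configurable diagnostic choice.

The ripple re-scores every permutation of a sliding window (default 4) and
adopts any order improving the log-likelihood by more than 1e-6; sweeps
repeat until a pass makes no change, which terminates because acceptance is
strictly monotone. Deterministic tie-breaking (lexicographic names, then
leftmost position) makes every search reproducible.

## Composite map

Markers mapped in both individual maps form the framework. The initial
framework order is whichever individual map's restriction to the shared
markers has the higher joint likelihood. Conflicts — shared markers outside
the longest common subsequence of the two restricted orders (the second
order reversed when that matches better; LCS ties resolved toward the
lexicographically smallest subsequence) — are processed in decreasing order
of joint two-point information; each is removed and re-scored at every
position with the joint EM, the argmax accepted before the next marker is
evaluated. A joint ripple finishes; the joint log-likelihood is
non-decreasing across framework → conflict resolution → ripple.

Population-unique markers cannot contribute to a multipopulation
recombination fraction; they are placed by scaling, not re-estimation: a
unique marker's distance to its left flanking common marker (on its own
map) is multiplied by the interval factor (composite interval length /
individual interval length), or by the terminal factor (composite group
length / individual group length) beyond the outermost common marker. If an
individual map mirrors the framework (negative position correlation over
common markers), its positions are flipped before scaling. Unique markers
from both populations falling in one interval interleave by scaled
position, ties by population then name. When a unique marker's flanking
common markers are non-adjacent in the framework, the factor is computed
over that whole span. Degenerate zero-length individual intervals use
factor 1.

## Synthetic data

The generator reproduces the targeted crossing design: two populations of
160 and 184 progeny sharing the female parent; shared markers drawn from
the five joint configuration classes at proportions 36.88 / 25.34 / 21.59 /
8.94 / 7.25 % (D1.10-D1.10, B3.7-B3.7, D2.15-D2.15, B3.7-D1.10,
D1.10-B3.7); genotyping-error probability 0.05 and missing rate 0.10 by
default. Gametes follow a Markov walk over intervals with the true r per
interval and no interference; offspring genotypes are the union of gametic
alleles reduced to observable classes. Noise injection replaces each call
with a uniformly chosen different observable class with probability ε, then
masks it with the missing rate — exactly the error process the HMM
emissions assume, so parameter-recovery tests probe estimation rather than
model misspecification. What the generator does *not* emulate: read-depth
driven genotype uncertainty and heterozygote undercalling, segregation
distortion, interference, and population structure; passing tests therefore
demonstrate correctness of the estimators under the stated model, not
robustness to all properties of real GBS data.

Because gametes are generated without interference while distances are
reported through Kosambi (which implies partial interference), recovery
checks compare r to r; cM comparisons are reserved for checks where the
accumulated discrepancy is within the stated tolerance.

## Problem sizes in the shipped studies

The test suite and `scripts/acceptance.py` run three simulation studies
chosen to exercise the estimators at the design's population sizes while
remaining desk-scale: (i) recovery — 20 replicates of a 15-marker group
(r ∈ [0.01, 0.2], N = 160 + 184, ε = 0.05, 10% missing), joint EM on the
true order, mean |r̂ − r| reported; (ii) power — 200 replicates of the same
configuration comparing interval-wise RMSE of the joint versus each
single-population estimator; (iii) order recovery — 50 replicates of a
12-marker group at 5–15 cM spacing, full per-population pipelines (seeded
order search plus ripple), joint framework construction with conflict
resolution, comparing the framework order to the simulated truth up to
mirror. Two-point/HMM agreement checks run on 50 random fixtures with a
1e-5 grid. At these sizes the whole acceptance script completes in roughly
twelve minutes on one CPU.

## Known limitations

* Exactly two populations; the estimator contracts are written for one
  shared (female) parent.
* Dominant legacy markers (e.g. the `ao × ao` type) and multiallelic
  markers are out of scope; VCF import keeps biallelic SNPs only.
* Adjacent-position ambiguity is intrinsic for testcross markers whose
  neighbors are informative in the other parent only: such markers are
  left unplaced rather than forced, so desk-scale maps typically place a
  subset of markers (the insertion threshold is configurable).
* Very tightly linked marker pairs (r → 0) have near-unidentifiable local
  order — discrimination rests on double recombinants, expected
  `N·r₁·r₂` events — and are reported in whichever order the likelihood
  favors; the ripple will not manufacture certainty that the data lack.
* Segregation-distorted markers are flagged, not removed (mapping proceeds
  with all markers; a drop switch exists); the distortion test assumes
  independent progeny.
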