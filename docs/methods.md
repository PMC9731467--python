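# Methods

## Data model and conventions

A survey network is a directed graph of signed nominations: arc
(i, j) = +1 (friendship) or −1 (enmity), at most one arc per ordered pair,
no self-arcs. The unit of downstream analysis is the **reciprocal
projection**: an unordered pair carries a sign only when both directed
nominations exist and agree. Conflicting pairs (one +, one −) are treated
as non-reciprocal; both arcs are dropped and tallied separately in the
drop report, and in the tie census each contributes one one-way positive
and one one-way negative tie. All `w`-symbols in the quality functions are
unweighted edge counts; weighted edges are rejected at construction.

When reproducing published summary tables, means and percentages are
**floor-truncated** to one decimal rather than rounded. The evidence in
the source tables is unambiguous (2·583/473 = 2.465 printed as 2.4;
32/127 = 25.196 % printed as 25.1 %); both raw and truncated values are
exposed, with the reporting mode recorded on the summary object.

## Negative-link completion

Electronic surveys under-report enmities, so many negative nominations
stay one-way. A pair is a completion candidate when exactly one negative
arc exists and there is no reciprocal negative; by default a pair whose
reverse arc is *positive* is excluded (completing it would overwrite a
declared friendship — a permissive mode includes such pairs, and only in
that mode can an existing arc be re-signed). For a candidate {i, j}, every
common reciprocal neighbour v closes the triad {i, j, v}; assuming the
edge {i, j} = −1, the triad is balanced iff the sign product is +1. The
reverse arc is added on a **strict majority** of balanced triads; ties and
empty contexts reject. All candidates of a pass are judged against the
same pre-completion projection, making the result deterministic and
order-independent. A single pass is the default — repeated passes would
compound the method's known bias toward adding balanced triads — with an
optional `iterate` flag that runs to fixpoint for sensitivity analysis.

## Community detection

Detection runs on the positive subnetwork only.

**Leading-eigenvector (deterministic).** The modularity matrix
B = A − k kᵀ/2m is bisected recursively: for a group g, the generalized
B⁽ᵍ⁾ subtracts within-group row sums on the diagonal; the split follows
the sign pattern of the leading eigenvector (computed with a dense
symmetric eigensolver; sign convention: first nonzero component positive,
entries equal to zero assigned to the positive side). Each split is
refined by Kernighan–Lin-style sweeps — every vertex flipped at most once
per sweep in greedy order, reverting to the best intermediate state —
and is accepted only if its modularity contribution is positive. A group
whose leading eigenvalue is ≤ 1e−10 is left undivided. Connected
components are processed independently; isolated nodes become flagged
singleton communities. The method has no resolution parameter.

**Louvain (stochastic, seeded).** Standard two-phase local-move/aggregate
maximization of γ-modularity; a fixed seed fixes the node-visiting order
and hence the partition bit-for-bit. The resolution γ multiplies the
null-model term; γ = 1 recovers the plain definition.

**Calibration.** For each γ in a grid, R seeded runs are compared by mean
pairwise normalized mutual information (arithmetic normalization; all
pairs when R(R−1)/2 ≤ 1000, otherwise 1000 sampled pairs), with the
mean/spread of the community count K and mean Q⁺ reported alongside. The
γ with the highest mean similarity wins; ties break toward γ nearest 1.
The robustness score had to be operationalized — run-to-run NMI is the
most common choice and is what this package uses. Two single-community
partitions compare as NMI 1 by convention.

## Perturbation metrics

Given the positive-subnet partition, the negative edges are laid back
onto it ("signed communities") and:

- Q⁻ is the same modularity functional evaluated on the negative
  subnetwork (convention: Q⁻ = 0, flagged, when w⁻ = 0, so that
  Qˢ = Q⁺ holds exactly in the absence of enmities);
- Qˢ = (2w⁺Q⁺ − 2w⁻Q⁻)/(2w⁺ + 2w⁻);
- frustration F counts negative-intra plus positive-inter edges,
  normalized by w⁺ + w⁻ (0 = perfect signed partition);
- CSB is the balanced fraction of within-community triangles under the
  strong-balance convention ((−,−,−) unbalanced); each triangle counts
  once; communities of fewer than three nodes contribute none, and a
  sensitivity flag can exclude 2-node communities from all community
  statistics;
- PPC = 100(Q⁺ − Qˢ)/Q⁺, undefined (flagged) when Q⁺ ≤ 0. The identity
  PPC = 100·(2w⁻/(2w⁺+2w⁻))·(Q⁺+Q⁻)/Q⁺ is verified to 1e−12 in tests.

**Stability classes.** The stable / semi-stable / unstable split is an
operational three-way cut on PPC with half-open intervals and default
thresholds (10, 25) percent. The underlying qualitative classification
has no published numeric thresholds, so these defaults are an explicit
package choice; they are configurable everywhere and echoed into every
report. **Negative hubs** are nodes whose within-community negative
degree reaches a threshold (default 3).

Degenerate inputs never crash the metric layer: an edgeless network (or
one with no positive edges) yields a fully flagged report; undefined
ratios (Dunbar with zero reciprocal pairs, modularity on an edgeless
subnetwork, PPC at Q⁺ ≤ 0) raise `UndefinedMetricError` at the
single-metric level.

## Synthetic generator

The generator emulates sociometric school networks. Nodes are partitioned
into blocks (explicit sizes, or a geometric sampler with mean λ, minimum
block size 2, mirroring the roughly exponential community-size
distributions of real school data). Per unordered pair a single uniform
draw selects one of five mutually exclusive categories: reciprocal
positive (p_pos_in within / p_pos_out between, 0 between by default —
survey-sparse networks), reciprocal negative (p_neg_in within — the
perturbation knob — / p_neg_out between), a one-way positive arc in
either direction (p_posone_in per direction, within blocks only), or
nothing. Mutual exclusivity keeps every count an exact binomial (see
`expected_counts`) and guarantees one-way arcs stay one-way under
projection. Defaults:

- p_posone_in = 1.5·p_pos_in (capped by feasibility), so the expected
  exclusive Dunbar ratio (one-way arcs / reciprocal pairs) is exactly 3 —
  a tuning default chosen to hit the empirical ≈ 3 target, not an
  empirical claim;
- censoring degrades each reciprocal negative pair to a one-way arc
  (uniform direction) with probability censor_prob, recording the pair in
  the ground truth, so the expected one-way:reciprocal enmity ratio is
  censor/(1−censor);
- injected hubs add reciprocal within-block enmities on free pairs first,
  converting reciprocal friendships only when the block is too dense —
  this guarantees the requested hub degree (recorded per hub in the
  ground truth) at the cost of a small deviation from the closed-form
  m⁺ expectation when conversions occur (none in the default regimes).

`table2_regime(label)` solves p_pos_in, p_neg_in, p_neg_out so the
expected reciprocal link counts equal one of nine published school rows
exactly (blocks of ~10 students; the within-block share of enmities is
set per school level — 0.40 elementary, 0.10 secondary, 0.08 high
school/university — to echo the published intra-community negative
percentages). Censoring is off in these regimes because the published
counts are post-completion.

**What the generator does not emulate:** degree heterogeneity within
blocks, classroom/spatial structure, kinship-driven triads, antagonistic
subgroup structure inside communities, and any dependence between pairs.
Passing recovery tests therefore show correctness of the algorithms under
block-independent sampling, not performance guarantees on real survey
data.

## Study conditions used in tests

- **Censored-enmity recovery** (100 seeds): 4 blocks of 15,
  p_pos_in = 0.9, p_neg_out = 0.4, censor_prob = 0.3 — a strongly
  balanced regime chosen by a design calculation (expected ≈ 7 balanced
  vs ≈ 2.3 unbalanced context triads per censored pair) so that the
  majority rule is informative. Because censoring is the only source of
  one-way enmities here, precision measures that nothing outside the
  censored set is added; recall is the substantive number.
- **Planted-partition recovery**: the esSC-like regime (108 nodes), both
  detectors, NMI against the planted blocks.
- **Exponential fit**: λ is recovered from 500 draws at mean 6.9; the
  least-squares mode regresses log CCDF on x at observed sizes (intercept
  free, λ̂ = −1/slope) with R² reported on the CCDF scale; the MLE mode
  returns the sample mean.
- Brute-force oracles (set-partition enumeration, O(n³) triad census,
  independent pairwise modularity summation) are confined to ≤ 8-node
  graphs, where enumeration is exact and fast.

Problem sizes throughout (n ≤ 1429 for accounting, n ≤ 108 for detection
ensembles, 100–500 replicate draws) were chosen so the full suite
completes in a few seconds while keeping Monte-Carlo standard errors well
inside the asserted tolerances.

## Known limitations

- The adjacency reader infers header rows/label columns by
  non-numeric-ness; purely numeric node labels in a labeled file are
  indistinguishable from data and will be misread.
- The leading-eigenvector implementation uses dense eigendecomposition:
  fine to a few thousand nodes, not intended for large graphs.
- Louvain quantities are averages over a seeded ensemble; single-run
  values at small sizes can differ noticeably from the ensemble mean.
- Completion evaluates candidates against the pre-completion projection
  only; evidence created by other additions in the same pass is not used
  (by design, for determinism).
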