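# Methods

## Model and procedure

The unit of analysis is the *combination*: all patients sharing one level
of every categorical prognostic factor. The pipeline makes no parametric
assumption about the survival distributions themselves; it assumes only
independent right censoring and that a two-sample survival test is a
meaningful measure of outcome difference between two combinations.

**Initial dissimilarity.** dis₀ is the chi-square-form statistic U²/V of a
weighted log-rank-family test. The chi-square form (rather than a signed
z) is used so the dissimilarity is nonnegative for any pair. Conventions:

- Ties between events at a shared time use the pooled hypergeometric
  variance; a time where the pooled risk set has ≤ 1 subject contributes
  nothing to V.
- A censored observation tied with an event time counts as at risk at
  that time.
- If V = 0 (no usable events in the pooled pair), the statistic is
  defined as 0 with p-value 1 and the pair is flagged degenerate; inside
  the pipeline such a pair gets dissimilarity 0 and a logged warning.
- p-values are the upper chi-square(1) tail, computed in full double
  precision (this is what exposes the saturation failure of the 1 − p
  baseline: for well-separated large cohorts 1 − p rounds to exactly 1).

Because the statistic scales with the information both cohorts
contribute, it measures *evidence* of a survival difference, not effect
size: doubling the cohorts roughly doubles dis₀ at a fixed hazard ratio.
The consensus step exists precisely to convert this size-confounded
quantity into a bounded, rank-based one.

**Consensus step.** Each of the m runs draws K uniformly from the
inclusive integer interval [K₁, K₂] and a partitioner uniformly from the
configured collection (default: PAM with random initial medoids only) and
partitions dis₀; the consensus dissimilarity of a pair is the fraction of
runs separating it. The unscaled PAM objective Σᵢ dis₀(xᵢ, medoid(xᵢ)) is
optimized — the 1/K prefactor sometimes written in the within-scatter
criterion does not change the argmin at fixed K, and the reported
objective is the unscaled sum. One PAM start per run; no run is excluded
for any reason (ties in the K draw or trivial swap phases included).

**PAM.** Random initialisation draws k distinct medoids uniformly;
BUILD initialisation (used by the direct-PAM baseline A4, matching R's
`pam` default) greedily adds the medoid with the largest objective
decrease. The swap phase is steepest-descent over all single
medoid↔non-medoid exchanges and accepts only strict improvements
(tolerance 1e-12), so it terminates; ties in assignment and in swap
choice break to the lowest index, making the outcome a deterministic
function of the initial medoid set. The implementation memoizes partitions
by (K, initial medoid set) within one ensemble call — with n = 12 there
are only ~4 × 10³ distinct initialisations, so m = 10⁴ costs well under a
second — which affects runtime only, never output.

**Agglomeration.** Inter-cluster dissimilarity is recomputed from the
input matrix (mean/max/min over cross pairs for average/complete/single
linkage). When two candidate merges tie exactly, the pair whose clusters
have the smallest minimum leaf indices merges first; this determinism is
what makes tree topologies comparable across seeds and tests. Topology is
represented as the set of internal-node leaf sets, so two trees compare
equal iff they contain the same clades regardless of merge order among
disjoint subtrees.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| m | 10000 | consensus runs; Monte-Carlo error ~ O(1/√m), < 0.05 max-abs at m = 10⁴ |
| K₁, K₂ | 2, n−1 | range of the per-run cluster count (inclusive) |
| test | log-rank | weight scheme of the two-sample statistic (wⱼ = 1, nⱼ, √nⱼ) |
| linkage | average | agglomeration rule |
| seed | — | drives every random draw; identical seed ⇒ bit-identical output |

## The synthetic generator

`generate_cohorts` draws, per combination: exponential event times at the
combination's hazard, exponential dropout times (default 0.01/month)
truncated by an administrative follow-up cutoff (default 132 months), the
observed time as their minimum with the event indicator, and raw
covariates (tumor size in cm, involved-node count) uniform within the
level's clinical bounds (T1 ≤ 2 cm, T2 2–5 cm, T3 5–15 cm; N0 = 0,
N1 1–3, N2 4–10, N3 11–30 nodes). Exponential time models were chosen for
the analytic censoring fraction h/(h + c), which the tests verify.

`standard_fixture` is the canonical scenario: the 3×4 T×N grid,
1000 patients per combination, and four planted outcome tiers whose
monthly hazards are 0.004, 0.016, 0.06 and 0.24 (fourfold spacing;
median survival from ~14 years down to ~3 months). The tiers deliberately
cut across the factor grid (e.g. T1N3 sits in the third tier with T3N1),
so factor-value clustering cannot reproduce them. Within each tier the
hazards are *graded*, not flat: one pair per tier shares an identical
hazard (its unambiguous first merge) and the remaining members sit at
hazard ratios of 1.25–1.75. Exactly tied within-tier hazards would make
the within-tier merge order a coin flip decided by sampling noise —
different tests would then legitimately disagree on the fine structure —
whereas real registry curves are tiered but never exactly tied. With the
graded design the whole dendrogram is signal-determined, and topology
equality across the three tests and across ensemble seeds holds for every
fixture seed tried.

`size_sensitivity_fixture` is a separate scenario for the size-sensitivity
experiment: compressed tiers (twofold spacing) with T1N0 alone at a hazard
~2× below the lowest tier. A two-sample statistic's information saturates
in the larger cohort (n_a n_b / (n_a + n_b) ≤ n_b), so inflating one
cohort twentyfold roughly doubles its pairwise statistics; the scenario is
built so that this doubling pushes T1N0's average dissimilarity past the
final merge height of the direct-statistic clustering (A1), isolating it
as a root-adjacent singleton, while equal sizes reproduce the consensus
topology. On the standard fixture this artifact cannot occur — its tier
spacing is too wide for a ≤ 2× boost to matter, which is itself an
illustration that the artifact is a knife-edge property of the
statistic-as-dissimilarity approach.

What the generator does **not** emulate: dependence between covariates and
survival within a combination, non-proportional hazards, stage migration,
calendar-time effects, or the covariate joint distribution of a real
registry. Passing tests therefore show that the pipeline recovers planted
proportional-hazards tiers under independent censoring — not that it
resolves the subtler structure of real registry data.

## Numerical choices

- Two-sample risk sets are computed by sorted counting
  (O(N log N)) rather than time×subject indicator matrices, so pairs with
  tens of thousands of subjects stay cheap.
- Swap acceptance and height comparisons use absolute tolerance 1e-12;
  dissimilarity CSVs round to 6 decimals (Newick heights are written at
  full precision).
- Zero rows in dis₀ (indistinguishable combinations) are legal; PAM
  resolves the resulting ties by index order.
- Degenerate inputs: empty cohorts and k outside [1, n] raise; an
  all-censored cohort yields the constant survival function 1.

## Problem sizes

The test suite and the acceptance script run the full method at the scale
of the canonical scenario — 12 combinations, 12 000 patients, m = 10⁴
consensus runs, five ensemble seeds — which completes in seconds thanks to
the PAM memoization; oracle comparisons use 100–200 random instances of
5–8 items. These sizes were chosen as the smallest at which the planted
structure, the Monte-Carlo convergence band (< 0.05 at m = 10⁴) and the
baseline failure modes are all decisively visible.

## Known limitations

- Only two-sample tests: no multi-group, stratified or trend statistics.
- The consensus is defined over partitions of dis₀ only; the pluggable
  partitioner interface accepts alternatives to PAM, but none ship here.
- Average/complete/single linkage only; no inversion-prone methods
  (Ward, centroid) since heights must be monotone for the k-cut to be
  meaningful.
- The A3 baseline requires raw continuous covariates; with only
  categorical levels the per-combination means are constants and the
  procedure is undefined (it raises).
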