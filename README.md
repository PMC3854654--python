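# eaccd — ensemble clustering of censored survival cohorts

Cancer staging systems such as TNM classify patients by combinations of
categorical prognostic factors (tumor size level T, nodal status level N,
...), and outcome prediction rests on grouping those combinations into
prognostically homogeneous tiers. `eaccd` implements an ensemble
(consensus) clustering algorithm for this problem: it groups
factor-level combinations by the similarity of their censored survival
experiences, rather than by the factor values themselves.

## The method

Let **x**₁, …, **x**ₙ be the combinations (e.g. the 12 cells of a 3×4 T×N
grid), each holding the records (xᵢ₀, δᵢ) of observed time and event
indicator for its patients.

1. **Initial dissimilarity.** For each pair, dis₀(**x**ᵢ, **x**ⱼ) is a
   weighted two-sample survival-test statistic in chi-square form,
   U²/V with

       U = Σⱼ wⱼ (d_aj − n_aj dⱼ / nⱼ),
       V = Σⱼ wⱼ² (n_aj/nⱼ)(1 − n_aj/nⱼ)((nⱼ − dⱼ)/(nⱼ − 1)) dⱼ,

   summing over pooled distinct event times (dⱼ pooled deaths, nⱼ pooled
   at risk). Weights wⱼ = 1, nⱼ, √nⱼ give the log-rank, Gehan–Wilcoxon and
   Tarone–Ware statistics. dis₀ is nonnegative and grows with both the
   survival difference and the sample sizes.
2. **Learnt (consensus) dissimilarity.** For l = 1, …, m: draw K uniformly
   from [K₁, K₂], partition the n combinations into K clusters by PAM
   (k-medoids, random initial medoids) on dis₀, and set δ_l(i, j) = 1 if
   the run separates **x**ᵢ and **x**ⱼ. Then

       dis(**x**ᵢ, **x**ⱼ) = Σ_{l=1}^{m} δ_l(i, j) / m  ∈ [0, 1].

   Pairs from the same latent outcome group are rarely separated; the
   consensus converges at the Monte-Carlo rate O(1/√m), so large m
   (≥ 10000) gives reproducible dendrograms.
3. **Hierarchical clustering.** Average- (or complete-/single-) linkage
   agglomeration of the consensus matrix produces the dendrogram; cutting
   it at k clusters yields the prognostic groups.

The package also implements four simpler baselines for comparison — A1
(cluster standardized dis₀ directly), A2 (cluster 1 − p), A3/A3\*
(cluster covariate means, optionally with the consensus step), A4 (PAM
directly at each k) — and a synthetic-cohort generator with planted
outcome tiers that makes every pipeline property testable end to end.

## Worked example

```sh
eaccd simulate --outdir demo --n-per-combination 300 --seed 20130
eaccd run --input demo/patients.csv --outdir demo/run -m 10000 --seed 1 --cut 4
```

prints

```
wrote 3600 patients in 12 combinations
merge heights: [0.0, 0.105, 0.2028, 0.3038, 0.4022, 0.5278, 0.6224,
                0.6772, 0.8497, 0.8529, 0.9984]
```

The heights are consensus dissimilarities: the first merges happen near 0
(pairs that virtually always co-cluster, e.g. T2N3 + T3N3), and the final
merge at ≈ 1.0 splits the cohort into a favorable and an unfavorable
branch that almost never share a PAM cluster. `demo/run/` contains the
initial and consensus matrices (CSV), the dendrogram (Newick + JSON), the
k = 4 cluster assignments, and a manifest with the exact configuration.
The k = 4 cut recovers the generator's four planted outcome tiers:

```
T1N0,T1N1,T2N0 → 1   T1N2,T2N1,T3N0 → 2
T1N3,T2N2,T3N1,T3N2 → 3   T2N3,T3N3 → 4
```

`eaccd stability` repeats the ensemble across values of m and reports
topology agreement and cophenetic correlations between repeats (small m:
unstable trees; m ≥ 10000: identical trees); `eaccd a1 … a4` run the
baselines.

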