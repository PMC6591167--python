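# Methods

## Model and assumptions

The pipeline targets the classic early-warning picture of critical
transitions: as a system approaches a tipping point, the variables most
coupled to the destabilizing direction show rising variance and rising
mutual correlation, while their recovery rate from perturbations falls.
For cross-sectional time-course data (different animals at each age, no
repeated measures of one individual) only variance- and
correlation-based statistics are identifiable; autocorrelation-based
measures would require repeated measurements of the same individual at
short intervals and are deliberately absent. A third classic statistic —
the correlation between candidate genes and the rest of the transcriptome
— is also omitted: it is informative only when the dominant eigenvector
of the system's Jacobian contains exactly zero entries, an unstable
condition in noisy biology.

All statistics use the unbiased K−1 denominator. Correlations involving
a constant gene are undefined; such genes are excluded from the
variance-ratio ranking (and reported), and their |r| entries are treated
as 0 inside the correlation-gain sums.

## Selection and scoring parameters

| parameter | meaning | default | rationale |
|---|---|---|---|
| θ₁ | % of S₀ kept by SD ratio | 10 | standard preset of the three-step procedure |
| θ₂ | % of S₁ kept by within-S₁ correlation gain | 50 | idem |
| θ₃ | % of S₁ excluded as non-specific gainers | 80 | idem; aggressive — S\* is a small, precise subset of S₂ |
| q | BH FDR level for DEG testing | 0.05 | conventional |
| fold-change threshold | strict \|Δlog2 mean\| bound | 1 | "more than two-fold" read as a strict inequality |
| cluster cutoff | 1 − r dissimilarity for flat clusters | 0.5 | average linkage |
| parallel analysis | shuffles / percentile | 100 / 95th | per-gene permutations |

`top_fraction` keeps `max(1, floor(θ/100 · n))` genes and breaks ties at
the cutoff by ascending gene id. Both choices are conventions (the
procedure is silent on rounding and ties); determinism is required so
that leave-one-out overlap statistics measure data sensitivity, not
implementation noise.

The correction term c(M) in I_r is the expected |Pearson r| of two
independent standard-normal samples of size M, computed from the null
density f(r) ∝ (1−r²)^((M−4)/2): c(M) = 2/((M−2)·B(½, (M−2)/2)), giving
c(4) = 1/2 exactly and c(5) = 4/(3π) ≈ 0.4244. The closed form
generalizes the two tabulated constants to any M ≥ 3 and is
Monte-Carlo-verified in the tests and the acceptance script.

The θ sweep ranks a triple by *peak sharpness* at a target time point:
for each of I_s and I_r on the case-group series, (score at the target −
best other week) / (max − min across weeks); the triple's sharpness is
the smaller of the two, so a candidate set must peak simultaneously in
both statistics. This formalizes "a sharp peak in both scores" as a
scale-free quantity in (−∞, 1]; triples with |S\*| < 2 rank last.

The relative recovery rate is reported as 1/λ_max of the sample
covariance of the S\*-restricted slice. It is meaningful only up to a
common scale across conditions; its minimum over time marks the point of
slowest recovery (critical slowing down).

Enrichment uses the hypergeometric upper tail; the DAVID-style modified
form substitutes (x−1, n₁−1) and defines x = 0 → p = 1. Following the
exploratory usage it replicates, no multiple-testing correction is
applied to enrichment p-values; sets are filtered at p ≤ 0.05 and
overlap ≥ 2 and ranked by overlap size (ties: p, then name).

## Preprocessing conventions

Probes without a gene-symbol annotation are dropped; multi-probe genes
are collapsed by the per-sample arithmetic mean of raw intensities
*before* normalization (the stages are applied in this order
deliberately; collapsing after normalization would give slightly
different trimmed means). The 2% trimmed mean discards
floor(0.02·n) observations per side — the floor convention keeps columns
with fewer than 50 values untrimmed. Genes are ordered lexicographically
after collapsing for reproducible indices.

## What the synthetic generator emulates — and what it does not

The generator mimics the emulated study design: two groups × five weekly
time points × ~5 replicates, log-normal baseline intensities,
multiplicative per-sample array effects (removed by trimmed-mean
normalization), probe-level redundancy and unannotated probes. The
planted DNB module uses a single shared latent factor per sample in the
case group at the peak week: with total variance (sd_ratio·noise_sd)²
split as target_abs_corr : (1 − target_abs_corr) between common and
idiosyncratic parts, the population SD inflation equals sd_ratio and the
population pairwise correlation equals target_abs_corr — an
equicorrelated, exactly solvable design with two free parameters.
Differential-expression clusters are constant mean shifts from an onset
week. Defaults (500 genes, 50-gene module, sd_ratio 3, |r| target 0.6,
noise SD 0.5 log2 units, 5 replicates) represent a strong, compact
pre-disease signature at desk scale; per-condition sample sizes are
configurable since real designs are rarely balanced.

Not emulated: realistic gene-gene co-expression in the background
(background genes are independent), scanner artifacts, strain-specific
biology, heavy-tailed noise, batch structure beyond per-sample scale
factors. Consequently, passing recovery tests demonstrates that the
selection finds a variance-and-correlation module against an independent
background — not that it would isolate one inside the correlated modules
of a real transcriptome. One behavior worth noting: because background
genes are mutually independent, the step-3 statistic v⁽³⁾ has no signal
on synthetic data and the θ₃ = 80% exclusion removes a near-random 80%
of S₂; the resulting S\* is small but precise (most members are planted).
On real data v⁽³⁾ responds to systemic correlation shifts, which is what
the exclusion step exists for.

## Numerical choices and degenerate inputs

- |r| values are clipped to 1 to absorb floating-point overshoot.
- Welch tests with zero variance in both groups return t = 0, p = 1 when
  the means agree (keeping the gene universe stable) and p = 0 otherwise;
  fewer than two values per group is an error.
- BH is applied per week across genes, not pooled over weeks — mirroring
  per-age group comparisons. This is an assumption, not a derived fact.
- Parallel analysis shuffles within genes (independent permutation of
  each gene's values across samples), which destroys inter-gene
  correlation while preserving each gene's marginal distribution; a
  whole-matrix shuffle would also mix gene-level means and variances into
  the null. The meaningful-PC count is the number of eigenvalues
  exceeding their rank-matched null percentile.
- Leave-one-out requires ≥4 samples per slice so every reduced slice
  still supports correlations. In the special case of two distinct
  samples each measured twice (n = 4), dropping one copy leaves all K−1
  statistics exactly unchanged — a useful exactness check; with more
  distinct samples the statistics do shift, which is precisely what the
  overlap mean ± SEM quantifies.
- The t-SNE embedding is delegated to scikit-learn with a precomputed
  dissimilarity (perplexity 100 capped at (n−1)/3, early exaggeration
  10, seeded); the bespoke part is the dissimilarity 1 − |r| + |r′|,
  whose diagonal is 1 by the formula and zeroed before embedding. Axes
  of the embedding are not individually interpretable.

## Known limitations

- S\* can legitimately be empty or a singleton; scores are then undefined
  and reported as such rather than imputed.
- The correction c(M) removes the *mean* small-sample bias of |r|; the
  variance of I_r at M = 4–5 remains large, so single-condition I_r
  values should be read as curves across conditions, not in isolation.
- Full-scale behavior (tens of thousands of genes, unbalanced per-week
  sample counts) is supported by the implementation but validated here
  only at desk scale on synthetic data.
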