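# Methods

## Heritability-partitioning model

The regression engine assumes the standard additive polygenic model: for
variant *j* with partitioned LD scores ℓ(j, C) and GWAS sample size N,

    E[chi2_j] = 1 + N * sum_C tau_C * l(j, C).

`fit_sldsc` regresses observed chi-square statistics on {N·ℓ(j, C)} for the
requested model annotations plus a free intercept. The intercept is never
constrained to 1: it absorbs uncontrolled inflation (population
stratification, cryptic relatedness) in real data and miscalibration in
simulation. Coefficient uncertainty comes from a delete-one-block jackknife
over contiguous, equal-count variant blocks in genome order (default 200,
automatically reduced with a warning below 2 variants/block so small inputs
still fit). One-sided p-values test τ_C > 0 — the enrichment direction of
interest; Benjamini–Hochberg is applied across a declared family of
per-tissue tests, and total SNP heritability is h² = Σ_C τ̂_C·|C| with its
SE taken from the same jackknife replicates (so point estimate and
uncertainty share one resampling scheme).

**Weights.** By default a single reweighting pass applies heteroskedasticity
weights w_j = 1/(2·(1 + N·τ̄·ℓ_tot(j))²), where τ̄ is a crude first-pass
slope ((mean χ² − 1)/(N·mean ℓ_tot)) and ℓ_tot defaults to the row-sum of
the model's LD-score columns floored at 1. This approximates the variance of
a chi-square with inflated mean without iterating to convergence; weighting
changes efficiency only, and the test suite verifies that weighted and
unweighted fits both recover planted τ. Plain OLS is available
(`use_weights=False`).

**Conditional models.** `fit_conditional` refits with the union of the
target and the conditioning annotations as model terms. Conditioning on
annotations whose LD scores are independent of the target leaves its
coefficient essentially unchanged; conditioning on the truly causal
annotation collapses the coefficient of a merely-overlapping annotation
toward zero — the logic used to ask whether immune-cell enrichment is
independent of brain enrichment. `coefficient_difference_test` compares one
annotation's coefficient between two fits with
Z = (β₁ − β₂)/√(SE₁² + SE₂²), one-sided.

**LD scores.** r² is the plain squared Pearson correlation of allele counts
in the reference panel; the LDSC-style finite-sample adjustment
r² − (1 − r²)/(n − 2) is a flag (default off) whose effect is covered by a
test. Windows are fixed base-pair windows (default 1 Mb) rather than
genetic-map distances — the synthetic genome has no recombination map, and
the window is ordinary config surface. Under independence the estimator has
a noise floor E[r²] = 1/(n − 1), so an all-variant LD score at window size
m_w is ≈ 1 + (m_w − 1)/(n − 1); tests pin this expectation. Disjoint
annotations are exactly additive in ℓ, which the partitioned implementation
preserves to rounding error. LD expansion of lead variants uses r²
strictly greater than the threshold (default 0.8); a lead absent from the
panel is kept as a lead-only neighborhood with a warning rather than
dropped.

## Specificity-rank enrichment

`specificity_scores` implements the processing chain: quantile-normalize
cell-state columns, drop the bottom decile of peaks by mean signal (both
switchable), scale each peak row by its Euclidean norm (per-peak squared
scores then sum to 1), rank peaks within each state (ties broken by peak
order, so ranks are a permutation of 1..N), and normalize ranks by N.
The per-state statistic is the mean normalized rank x̄ of the peaks
overlapped by risk variants, each peak counted once regardless of how many
variants support it. Under the null that overlapped peaks are an i.i.d.
uniform draw, x̄ has mean (N+1)/(2N) and SE √((N²−1)/(12N²n)); the reported
p is the one-sided normal tail 1 − Φ((x̄ − μ)/SE), matching common practice
for this statistic. No continuity correction is applied, because the
result type is defined by that formula; the approximation is accurate for
the n·N regimes where the statistic is used (worst absolute error ≈ 0.03
at n = 2–3 for N = 20, shrinking quickly with both n and N) but cannot
track the piecewise-linear exact tail at n = 1. For exactly that small-n
regime an exact null (convolution of the discrete-uniform rank pmf) and a
Monte-Carlo null are provided and compared in tests. The
stimulated-vs-unstimulated contrast is Z = (x̄₁ − x̄₂)/√(2·SE²), valid only
when both results share the peak universe and overlap count (enforced).
Bonferroni across the cell states tested is the multiplicity correction —
specificity ranks are far less correlated across states than the raw
signals, making FDR-style corrections unnecessarily liberal here.

## Clumping

Filters run in order: minor allele count ≥ 10 (derived as
round(2·N·min(f, 1−f)) when no MAC column exists), presence in the
reference panel with MAF strictly > 0.01, genome-wide significance
P < 5·10⁻⁸, MHC exclusion. Two MHC constants are shipped — the extended
GRCh37 region (chr6:25–34 Mb) conventionally excluded from LD-score
regression, and the GRCh38 region (chr6:28,510,120–33,480,577) excluded
before clumping — selected per stage with the build label recorded.
Clumping is greedy: promote the smallest-p remaining variant, discard all
remaining significant variants within ±500 kb on the same chromosome,
repeat. Ties on p break by (chromosome, position), making the outcome
independent of input row order; "±500 kb" is read as *strictly more than*
500,000 bp required between retained leads (a variant exactly at the
distance is clumped), with the boundary pinned by a test. Disorders with
fewer than 3 independent loci are flagged ineligible for the overlap
statistic (configurable).

## Comparisons

Sharing tables count each overlapped peak once in exactly one cell of the
disorder power set, so cells sum to the number of distinct overlapped
peaks. Discordant peaks are cell-selective peaks (normalized specificity
rank > 0.9 in ≥ 1 designated state) overlapped by one disorder but not the
other; element classes attach by the ≥ 1 bp co-location rule, multi-label
by default with a priority collapse (promoter > genic enhancer > enhancer)
for single-label summaries.

Spearman correlation uses S = Σd² on ranks; without ties
ρ = 1 − 6S/(n(n²−1)) and the two-sided p enumerates all n! permutations
for n ≤ 10 (twice the smaller tail of S, capped at 1 — the convention under
which ρ = 0 gives p = 1, consistent with R's `cor.test(exact = TRUE)`,
against which the implementation was verified). With ties the general
mid-rank correlation and a t-approximation are used with a warning.
Confidence intervals are seeded percentile bootstrap over pairs (default
10,000 replicates); at n = 9 the nominal 95% interval undercovers slightly
(measured ≥ 90% on bivariate-normal pairs), which is inherent to
small-sample bootstrap rather than an implementation artifact.

## Pathways

Peaks selected for ORA must exceed the specificity-rank threshold
(strictly > 0.9) in a designated state *and* be overlapped by risk
variants. Peak-to-gene assignment takes genes whose body overlaps the peak,
plus genes whose promoter overlaps it, defaulting to the single nearest
TSS within 10 kb only when both sets are empty (ties by gene id). The
promoter window is TSS ± 3 kb — a common annotation default; it and the
universe (all genes in the loaded model, or all genes in any set) are
explicit configuration recorded in output, since different external tools
hard-code different conventions. The test is the upper-tail hypergeometric
p = P(X ≥ k) per set, BH-adjusted across sets; the BH step-up is
implemented directly and checked against statsmodels to 10⁻¹².

## Synthetic data

The generator's role is to produce inputs with exactly the statistical
structure the estimators assume, plus planted ground truth.

* **Genotypes.** Haplotypes are latent AR-1 Gaussians within fixed-size
  variant blocks (independent across blocks), thresholded at the normal
  quantile of the target allele frequency; genotypes are sums of two
  haplotypes (Hardy–Weinberg by construction). The AR-1 parameter ρ_LD
  controls within-block LD (ρ_LD = 0.99 yields adjacent-pair r² well above
  0.5; ρ_LD = 0 yields independence). The target MAF is drawn per *block*
  (uniform on [0.05, 0.5] by default, mirroring a MAF > 0.01 analysis
  filter with margin): variants in strong LD share allele frequencies, and
  frequency mismatch would otherwise cap attainable r² far below the
  latent correlation. Monomorphic columns (possible at small n) are
  repaired minimally so every variant is polymorphic.
* **Summary statistics.** Two modes. *Analytic* draws
  χ²_j = (1 + N·Σ τ_C·ℓ(j,C)) × χ²₁ directly from the regression model
  using panel-derived LD scores — the engine is validated against its own
  assumption. *Phenotype* draws per-variant effects with variance
  Σ τ_C·a_jC on standardized genotypes, builds a unit-variance phenotype on
  the panel individuals (environmental variance 1 − h²) and runs marginal
  per-variant regressions — the engine is validated against the
  data-generating process. Configurations implying h² > 1 are rejected;
  N = 0 is allowed as the no-association limit. The realized genetic
  variance is recorded and matches Σ τ_C·|C| within 10% at 20,000 variants.
* **Peaks.** Log-normal background signal shared across states
  (σ = 0.5 between peaks) with modest state noise (σ = 0.2); each state
  gets a disjoint subset of peaks (specificity_fraction, default 5%)
  boosted ×6 in that state only. With no planted signal no peak's
  specificity score exceeds twice its row mean; planted peaks land in the
  top decile of their state's ranks. Peak intervals are non-overlapping by
  construction.
* **Risk variants.** With probability π (default 0.8) a lead falls
  uniformly inside a peak specific to the target state, else uniformly on
  the genome; π = 0 yields calibrated-uniform downstream p-values, π = 1
  puts every lead in a specific peak.
* **Seeding.** One master seed spawns a named, independent stream per
  stage, so any stage is reproducible in isolation and identical configs
  give bit-identical outputs.

What the generator does **not** emulate: realistic human LD maps and
recombination hotspots, MAF–LD coupling, population stratification and
relatedness, sex chromosomes, imputation error, and peak-calling artifacts.
Passing tests therefore demonstrate correctness of the estimators under
their stated models and robustness to the generator's perturbations — not
robustness to every pathology of real consortium data.

## Problem sizes and numerical choices

Statistical suites run at sizes chosen to make Monte-Carlo error small
relative to the tested effect while keeping the default test run fast:
s-LDSC recovery uses 20,000 variants, N = 50,000, τ* = 5·10⁻⁶, 100
replicates (recovery within 3 jackknife SEs in ≥ 95), with 200-replicate
null calibration checked by Kolmogorov–Smirnov at α = 0.01;
specificity-rank recovery uses 5,000 peaks, 6 states, 50 leads, π = 0.8
over 100 replicates. Brute-force oracles (per-base coverage, double-loop
LD scores, exhaustive permutation/combination enumeration) run at 100 kb
genomes, 500-variant panels and universes ≤ 12, where exhaustive
computation is exact and cheap. Rank-deficient regression designs are
rejected with the offending annotations named (QR diagonal test at
relative tolerance 10⁻¹⁰); regression ties, rank ties and clumping ties
all break deterministically in genome or identifier order.

## Known limitations

* The regression weights are a one-pass approximation, not the iterative
  scheme of the reference LDSC software; no baseline annotation files are
  bundled (an all-variants column plus user annotations play that role).
* Genetic-map-based LD windows, liability-scale conversion and cross-trait
  genetic correlation are out of scope.
* The normal null for the specificity-rank statistic is inaccurate at
  n = 1 overlapped peak (use the exact mode there).
* Cross-dataset peak matching (comparing implicated peaks between two
  independently peak-called datasets) is not implemented.
* Plot rendering is out of scope; all outputs are tabular.
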