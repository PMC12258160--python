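# Methods

## The model

SGSEA couples two standard pieces. First, for each gene *i* a univariate
Cox proportional-hazards model

h(t | x_i) = h0(t) · exp(β_i x_i)

is fitted to the cohort, with x_i the gene's normalized expression
(log2-CPM) and h0(t) an unspecified baseline hazard eliminated by the
partial likelihood. β_i — the log hazard ratio per unit of log2-CPM — is
the ranking statistic: positive β means higher expression goes with higher
instantaneous mortality risk. Second, gene sets are tested for
concentration at the extremes of the β-ranking with the weighted
Kolmogorov–Smirnov-like running sum: walking the list from top to bottom,
set members add |β|^p normalized by the in-set total (p = 1 by default),
non-members subtract 1/(N − N_hits), and the enrichment score (ES) is the
walk's extremum by absolute value, so ES ∈ [−1, 1] and the walk closes at
exactly zero. The case-control mode is identical except that the ranking
statistic is a negative-binomial GLM log2 fold change.

Proportional hazards is assumed per gene but never tested: with thousands
of fits the goal is a ranking statistic, not per-gene inference, and the
pathway-level permutation calibration is what carries the inferential
weight. Genes act marginally — each fit sees one gene (plus any shared
clinical covariates); co-expression enters only through the permutation
null being computed on the observed ranking.

## Significance

The null model samples gene sets: for a pathway with k members in the
ranked universe, random size-k subsets are drawn uniformly without
replacement and their ES computed on the same ranking. This is the
preranked null — the ranking already encodes the outcome, so permuting
genes, not phenotypes, is the exchangeable operation. NES = ES divided by
the mean |ES| of same-sign null draws; the p-value is the add-one
proportion of same-sign null draws at least as extreme. Null draws are
shared across same-size pathways within a run. Permutations start at
1,000 and escalate tenfold (to 10^6 by default in the library, lower caps
in the bundled workflows) for any pathway whose p-value sits at the
resolution limit (p < 10/nperm), so small p-values are resolved without
paying the maximal cost everywhere. `log2err` is the Monte-Carlo standard
error of log2(p̂) implied by the permutation count — an honest uncertainty
for a simple permutation p-value, deliberately *not* comparable to the
split-sampling error estimates some other GSEA implementations report.
Benjamini–Hochberg adjustment runs across all tested pathways;
the package-wide default significance level is padj < 0.15, the
conventional omics screening threshold for this method family.

Numerical details: an exact tie between the positive and negative walk
extremum (within 1e-12) resolves to the positive one; ES is clamped to
[−1, 1] against one-ULP float excursions; a set whose members all carry
zero statistic falls back to equal hit weights; ranked-list ties are
broken lexicographically by gene id, making every run bit-reproducible
under a fixed seed.

## Per-gene Cox fitting

The partial likelihood (Efron tie correction by default; Breslow
available) is maximized by Newton–Raphson with step-halving, starting at
β = 0 on a centered covariate, converging when the relative log-likelihood
change drops below 1e-9 (max 25 iterations). The engine precomputes the
time ordering, risk-set boundaries and tie structure once per dataset, so
each additional gene costs a handful of cumulative sums — ~1 ms per gene
at n = 300. |β| > 15 is treated as quasi-separation. Non-converged,
separated and zero-variance genes are *excluded* from the ranking (and
counted), not clipped: a clipped β = ±15 would colonize the extremes of
the list and distort every ES. Wald z/p come from the observed-information
standard error at the optimum. Clinical covariates, when supplied, enter
every per-gene fit through one shared design matrix with the gene column
swapped per fit.

## Preprocessing

Genes averaging fewer than 0.1 reads per sample (1 read per 10 samples)
are removed before analysis; the rule is a strict less-than, so a gene
exactly on the boundary stays. Normalization for the survival mode is the
voom recipe: log2((count + 0.5)/(library + 1) × 10^6), a lowess trend
(span 0.5) of the square-root residual SD on the mean log2-count, and
per-observation precision weights as the inverse fourth power of the
trend prediction. The log2-CPM values match limma::voom to numerical
precision; the weights track its trend closely but not bit-identically
(different lowess internals). The weights are computed and stored, but the
Cox stage consumes only the log2-CPM values: nothing in the method's
specification makes the partial likelihood weight observations, and an
unweighted fit is the defensible default; the weights remain available for
sensitivity analysis. The case-control mode instead leaves counts raw and
uses median-of-ratios size factors as GLM offsets, letting the NB
likelihood do the normalization.

## The NB fold-change mode

Per-gene dispersion α is estimated by method of moments on size-factor
normalized counts (residual variance pooled within condition), then
refined by maximizing the NB likelihood in α with the group means held at
their normalized sample means; floor 1e-8. The fold change comes from a
log-link NB GLM (intercept + condition, optional pair-indicator block for
paired designs, offsets = log size factors); log2FC = coefficient / ln 2.
Standard errors use the expected (Fisher-scoring) information — for NB2
with fixed α the difference from observed information is negligible at
these sample sizes. No dispersion-trend shrinkage and no LFC shrinkage are
applied: the fold change here is an input to enrichment, not a reported
effect size, and a plain Wald GLM keeps the estimator transparent. Genes
entirely zero in one condition get a 0.5 pseudo-mean fold change and a
flag.

## FDR audit and mode comparison

The audit estimates how often each pathway would be called significant
when no expression–outcome association exists: each sample's (time,
status) pair is shuffled *jointly* across samples — independent shuffling
would fabricate censoring patterns that never occurred — the Cox ranking
and enrichment are rerun, and the per-pathway frequency of padj < alpha
over B replicates is the estimated FDR. Filtering and normalization do not
depend on the outcome and are computed once. The mode comparison is plain
set arithmetic on the shared pathway names at a common alpha, reported as
Venn partition counts.

## The synthetic cohort generator

Counts are NB with log-normal gene means (median ≈ 55 reads) and a common
dispersion (default 0.2 — mid-range for bulk RNA-seq). Survival follows
the analysis model itself: an exponential baseline hazard (the simplest
hazard consistent with a proportional-hazards world) scaled per sample by
exp(Σ_signal β·z), with z the standardized log2-CPM of each planted gene,
so β is the per-SD log hazard ratio. Censoring is an independent
Uniform(0, c) time with c bisected until the censored fraction hits the
target ±0.05. Defaults mirror the motivating kidney-cancer cohort: 520
samples, 69% censoring (360 of 520 alive at last follow-up), one planted
20-gene pathway with β = 0.8 among random pathways of the same size and
naming scheme — the ground truth never leaks into the observable files.
Gene counts default to 2,000 (desk scale) rather than transcriptome scale.

What the generator does *not* emulate: gene–gene correlation (real
pathways are co-expressed, which widens the null ES spread relative to
independent genes), batch structure, library-size pathology, non-NB
overdispersion, informative censoring, and time-varying effects. Passing
tests therefore demonstrate correctness of the machinery and calibration
under the stated model, not robustness to everything real cohorts do.

The parameter-recovery panel deserves a note: recovering β̂ ≈ β_true
requires each gene to drive its own survival vector, because a joint
hazard over hundreds of genes with per-SD effects of SD 0.5 would put
variance ≈ 50 on the linear predictor and attenuate every marginal fit
beyond recognition. The panel therefore draws one expression matrix and
200 independent survival vectors, gene g's outcome depending on gene g
alone.

## Problem sizes and defaults used in the bundled checks

The statistical acceptance checks run at: 200 genes × 300 samples
(recovery), 2,000 genes × 520 samples with 100 pathways (null
calibration), 1,000 genes × 200 samples × 50 outcome permutations (FDR
audit), and 100 seeds of 1,020 genes × 300 samples (planted-pathway
power), with permutation caps of 10^3–10^4. These sizes give each check
comfortable Monte-Carlo resolution while keeping the whole suite in the
minutes range on a single core.

## Known limitations

- Exact parity with other implementations is a non-goal: the enrichment
  p-values use adaptive simple permutation, not split-sampling multilevel
  estimation, and the NB mode is a plain Wald GLM without shrinkage.
- The per-gene Cox fits inherit every caveat of marginal screening:
  confounding between co-expressed genes is not resolved, and
  proportional-hazards violations bias individual β's (the pathway-level
  permutation calibration, not per-gene inference, is the intended
  output).
- Orientation auto-detection needs sample identifiers shared with the
  survival table; an overlap tie is a hard error by design.
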