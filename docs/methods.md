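# Methods

This note documents the statistical model implemented by `mmclassify`,
the default parameter choices and why they were made, the synthetic-data
generator used for calibration, and the package's known limitations.

## 1. Problem setting

The cohort is a set of *n* tumors (default study size *n* = 44), each
with a 16S-derived taxa × samples abundance table (collapsed to genus
level, a few hundred taxa) and a set of binary mutation features
(gene- or pathway-level loss-of-function indicators).  For each mutation
feature the question is whether the tumor-adjacent microbial community
differs between mutated and wildtype tumors, and if so, how well
community composition predicts mutation status out of sample.

## 2. Discriminant-taxon screen (LEfSe-style)

Stage 1 — for every taxon, a tie-corrected two-group Kruskal–Wallis rank
test (equivalent to a Wilcoxon rank-sum up to the χ²(1) reference
distribution); taxa with p < `kw_alpha` (default 0.05) pass.  Constant
taxa are assigned p = 1.

Stage 2 — over the screened taxa, `n_bootstrap` = 30 bootstrap rounds
each draw `bootstrap_fraction` = 2/3 of each class without replacement
and fit a one-dimensional Fisher LDA (pooled within-class scatter with a
small relative ridge, 10⁻⁶ · tr(S)/k, for degenerate subsamples).  The
per-taxon effect size is the mean over bootstraps of
½(|w_t · d_t| + |d_t|), where w is the unit-norm LDA direction and d the
raw class-mean difference; the reported score is log₁₀(effect · 10⁶ + 1),
mapping proportion-scale effects onto the conventional per-million LDA
scale.  Taxa scoring ≥ `lda_threshold` = 2.0 are selected and signed by
the class with the larger raw mean.

The bootstrap subsample draw is keyed to original sample positions, which
makes the selection *bit-exactly* invariant to swapping which class is
called "positive" — the basis of the label-swap antisymmetry invariant.

## 3. Risk index, leave-one-out, and significance

The risk index of sample *s* is the unweighted difference of summed
arcsine-root-transformed relative abundances over the positively and
negatively enriched selected taxa.  The sum is deliberately unweighted:
with tens of selected taxa and ~44 samples, reusing LDA coefficients
would overfit; arcsine-root is the classical variance-stabilizing
transform for proportions.

Held-out indices come from leave-one-out: for every sample the *entire*
selection (KW + LDA) and model construction is re-run on the other n−1
samples.  A fold whose screen selects nothing yields a missing index;
if more than 20% of folds are empty the run aborts with a diagnostic —
the screen finds no signal at these thresholds, and reporting a
statistic from the few non-empty folds would be misleading.

Significance: (i) two-sided Mann–Whitney U between the held-out indices
of the two classes; (ii) an empirical permutation null — labels shuffled
B = 999 times, the full leave-one-out pipeline re-run per permutation,
p = (1 + #{|Δ_perm| ≥ |Δ_obs|}) / (B_valid + 1) with the +1 pseudocount
(so p ≥ 1/(B+1); permutations that themselves trip the no-signal abort
are excluded from the null and the denominator).  Benjamini–Hochberg
q-values are computed across mutation features.

## 4. Evaluation

AUC uses the rank (Mann–Whitney) formulation with ties counted ½, which
equals the area under the empirical ROC exactly.  Ten-fold evaluation is
stratified; each fold's model is retrained from scratch and its held-out
scores form a fold-local empirical ROC.  Per-fold curves are evaluated
as right-continuous step functions on a fixed 101-point FPR grid and
averaged vertically; linear interpolation was rejected because with
4–5 test samples per fold it systematically inflates the mean curve
(measured null AUC ~0.73 instead of ~0.5).  The accuracy-optimal cutoff
is searched over midpoints of adjacent distinct scores (provably
sufficient for a step-function accuracy), with ties resolved to the
midpoint of the first contiguous run of optimal candidates; the
fixed-specificity operating point takes the smallest cutoff reaching the
requested specificity (default 0.80).

## 5. Mutation profiles

Mutation calls are classified into LoF (premature stop, stop loss,
frameshift, start loss), missense, synonymous, or other; composite
annotations resolve to the most severe class.  Gene-level binary
matrices OR all qualifying calls; pathway-level matrices OR member
genes (KEGG/PID membership via a 3-column idmapping file, matched on
ENSEMBL id with gene-symbol fallback).  Features mutated in fewer than
`min_patients` = 10 tumors are dropped.  Confounding with stage
(1–2 vs 3–4) is checked per feature by two-sided Fisher's exact test
with BH correction.

## 6. SparCC networks

Compositional correlations between basis abundances are estimated from
log-ratio variances t_ij = Var[log(x_i/x_j)], solving
(𝟙 + diag(D−2)) w = rowsums(T) for the basis variances, with iterative
exclusion of the strongest pair above |r| = 0.1 (10 iterations), over
20 Dirichlet(counts+1) resamples (element-wise median).  Significance is
a shuffle pseudo p-value (each taxon permuted independently, 100
shuffles, +1 pseudocount).  Networks keep edges with |r| ≥ 0.25 and
p ≤ 0.05, built separately for mutated and wildtype strata.

## 7. Robustness models

Per taxon (after a prevalence ≥ 5 samples, mean abundance ≥ 0.001
filter), OLS of arcsine-root abundance on mutation status plus age and
sex, two-sided t-test on the status coefficient, BH over taxa.  This is
a deliberately simple covariate-adjusted analogue of multivariate
association tools, not a reimplementation of any of them.

## 8. Synthetic-data generator

Per dataset: a base composition drawn once from a log-normal
(σ = 2.5 across taxa — a few dominant genera, a long rare tail), binary
labels at prevalence 0.5, planted effects as multiplicative shifts of
chosen taxa in labeled samples *before* renormalization (so boosting one
taxon depresses the rest, preserving compositional coupling), and counts
drawn Dirichlet-multinomial at Poisson(120 000) depth.  Labels, base,
and counts use independent child streams of one seed, so planting an
effect changes neither the labels nor the base ranking
(`planted_indices_by_rank` exploits this to plant in known abundance
tiers).

The total Dirichlet concentration defaults to 500.  This was originally
50, which produced tables so zero-inflated that most genera were
untestable — inconsistent with genus-level 16S tables at ~120k reads,
where most genera are detected in most samples, and with the expectation
that a null screen passes ≈ α·(number of taxa) taxa.  At concentration
500 a genus at 10⁻³ relative abundance is detected in ~93% of samples
while between-sample noise remains strongly overdispersed relative to
multinomial sampling (CV ≈ 44% vs 0.9% for a 1% genus).  Measured on
null tables (200 taxa, 8 seeds): 2–14 taxa pass the KW screen, centred
on the nominal 10.

## 9. Calibration and power (measured, seed 0)

* Type-I error of the permutation test over 40 null features at B = 99:
  rejection fraction within the binomial 95% band around 0.05.  A null
  table on which the leave-one-out pipeline aborts (no-signal contract;
  measured incidence 1/40) counts as a non-rejection — it cannot claim
  an association.
* Held-out Mann–Whitney p-values are **not** uniform under the null
  (KS p ≈ 10⁻³ across master seeds; 12–26% of null replicates below
  p = 0.05).  This is a property of the method, not the implementation:
  taxa are re-selected in every leave-one-out fold using 43 of the 44
  labels, so the held-out scores are mutually dependent and
  label-coupled, violating the exchangeability the rank test assumes.
  Scoring the same null tables with a fixed, label-independent risk
  model gives exactly uniform MWU p-values (KS p = 0.51, 2.5% below
  0.05 over 200 replicates).  Inference should therefore rest on the
  permutation p (which re-runs the full selection + leave-one-out per
  permutation and is calibrated); the MWU p is reported as a
  descriptive within-sample statistic.
* Planted recovery (5 taxa, 4-fold, 20 seeds): recovery fraction 1.0,
  mean 10-fold AUC 1.0, permutation power 1.0.
* SparCC: null median off-diagonal |r| ≈ 0.035; a planted basis
  correlation of 0.8 recovered within ±0.01 at n = 200.
* Held-out AUC is monotone in the planted fold change (1→2→4→8).

## 10. Numerical and scope limitations

* The χ²(1) reference for the Kruskal–Wallis statistic is an
  approximation; at n = 4+4 it deviates from the exact permutation
  distribution by up to ~0.11 in the mid-p range (an intrinsic property
  of the approximation, shared by standard implementations).  Agreement
  with exact enumeration to 0.02 holds in the small-p tail where the
  screen operates.
* Permutation p-values are bounded below by 1/(B+1); with B = 999 the
  smallest attainable q after BH correction depends on the number of
  features.
* SparCC's basis-variance solution assumes sparse true correlation; it
  needs ≥ 4 taxa and ≥ 4 samples and degrades for dense correlation
  structure.
* The robustness linear model treats arcsine-root abundances as
  homoscedastic and does not model zero inflation.
* The generator plants effects only on the first mutation feature and
  draws features independently unless an overlap is requested; it does
  not model batch effects or phylogenetic correlation between taxa.
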