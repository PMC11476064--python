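# Methods

This note documents the statistical procedures `gradesig` implements, the
defaults it ships, the numerical choices made where a published description
was silent or ambiguous, and what the synthetic test bed does and does not
establish.

## Data model

Expression is a genes × samples matrix of log2 intensities with unique string
identifiers on both axes and no missing values (a missing or non-numeric cell
is a load error naming the gene and sample).  The phenotype table carries one
row per sample: a binary grade (`grade2`/`grade3`), and optionally survival
months with a 0/1 event indicator (an event flag is required whenever months
are present).  Matrix orientation is fixed genes-in-rows; a transposed file is
recovered only when the caller opts in *and* the row ids match the phenotype
table's sample ids, because silent transposition is a classic corruption
source.

Quantile normalisation maps every sample onto the common reference
distribution (the per-rank mean of the sorted columns).  Ties within a column
receive the mean of the reference values over their rank span — the
"ties = average" dialect — which makes the result deterministic and invariant
to gene order, at the cost of exact multiset equality between columns when
ties exist.  Row z-scores use the sample standard deviation; constant rows map
to zeros with a warning rather than erroring, since null synthetic data
legitimately contains near-constant genes.  PCA operates on samples in gene
space with genes centred internally; hierarchical clustering offers average or
complete linkage under Euclidean or correlation distance, dropping
zero-variance items under correlation (their distance is undefined).

## Selection methods

**Differential expression.**  Per gene, log2FC = mean(grade3) − mean(grade2)
and a two-sample *t* statistic: pooled-variance by default, Welch by option,
or a `moderated_t` variant that shrinks per-gene variances toward the grand
mean with a method-of-moments weight (the fraction of gene-to-gene variance
dispersion exceeding the χ² sampling noise).  The plain *t* is the default
because at ≈50 samples per group it is asymptotically equivalent to
empirical-Bayes moderation while remaining fully transparent.  P-values are
Benjamini–Hochberg adjusted over all tested genes; selection is
`adj_p < 0.01 OR |log2FC| > 1` by default, with an `and` mode available —
the disjunction is the literal reading of the published rule, and the
alternative is kept because an OR rule (which admits large-fold-change,
non-significant genes) is unusual enough that both dialects deserve support.

**STIR (statistical ReliefF).**  Features are min-max scaled to [0, 1];
sample-to-sample distances are Manhattan.  For each sample, its *k* nearest
same-class neighbours (hits) and *k* nearest other-class neighbours (misses)
contribute per-gene absolute differences to two pools; *k* defaults to
⌊n/6⌋.  The statistic is (miss mean − hit mean) over the pooled standard
error with Welch–Satterthwaite degrees of freedom, one-sided (misses should
exceed hits for discriminative features; a two-sided flag exists), then
BH-adjusted with selection at adjusted p < 0.01.  Fixed-*k* neighbourhoods
follow classic ReliefF conventions; the Welch-type test over difference pools
is the documented stand-in for the original method's exact degrees-of-freedom
formula, which is not restated here.

**Boruta.**  Each run pairs every surviving feature with a shuffled shadow
copy, fits a random forest on real + shadow columns, and scores a *hit* for
features whose importance exceeds the maximum shadow importance.  Importance
is the permutation z-score: mean training-accuracy drop over shuffles of the
feature's column divided by the standard deviation over repeats (5 by
default), with all permuted copies predicted in stacked blocks for speed.
Hits accumulate into a two-sided binomial test (hit probability ½) with
Bonferroni correction over the feature count; significant excess confirms,
significant deficit rejects, and rejected features leave the model.  The loop
ends when nothing is tentative or at `max_runs` (default 1000); leftover
tentative features are resolved by the rough fix — confirmed iff their median
importance over runs exceeds the median of the per-run maximum shadow
importance.

**Iterative random forest.**  Each iteration scores an `mtry` grid (default:
√p halving down to 2) by repeated cross-validated balanced accuracy, then
keeps genes whose permutation-importance z exceeds 2 (the z scale is assumed
for the published "importance > 2", which does not name its scale).  The loop
stops when the gene set stabilises or would drop below two genes; the
returned signature is the iteration with the highest recorded CV balanced
accuracy, which degrades gracefully to the all-genes model if the very first
reduction empties the set.

**LASSO.**  L1-penalised logistic regression on standardised features over a
λ grid (0.01–0.35 in steps of 0.01), using the glmnet-style mapping
C = 1/(nλ) onto the liblinear solver.  λ is chosen by repeated-CV balanced
accuracy with ties resolved toward the larger λ; the signature is the set of
nonzero coefficients at the chosen λ in the final full-data fit.  λ = 0 is
dropped (with a warning) whenever features ≥ samples, where the unpenalised
fit is non-identifiable.

**CACTUS.**  Each gene's expression is abstracted to a flip: U when strictly
above the gene's cut-off, D otherwise (equality maps to D for deterministic
boundary behaviour).  The cut-off maximises single-feature training accuracy
over all midpoints between consecutive distinct values (±∞ sentinels) and
both orientations; ties break to the smallest cut-off, and a balanced-accuracy
criterion is available by flag.  Feature filtration uses the binomial margin
of error ME(z, p, n) = z·√(p(1−p)/n) with z = 5 and n the number of features
— the standard-error reading of a formula whose printed form is
typographically garbled but whose symbol legend (z-score, single-feature
accuracy, feature count) matches exactly this construction.  Two comparison
rules are provided because the filtration direction is not published:
`band_below_max` (default) keeps genes within one margin of the best single
feature; `above_half` keeps genes whose accuracy clears 0.5 + ME.  The
fitted model stores σ_{s,i}(f) = (count of flip f for gene i in class s +
smoothing)/(n_s + 2·smoothing), Laplace-smoothed with add-1 by default so no
class cost ever collapses to zero on unseen flips (with smoothing 0, an
unseen flip correctly produces a −∞ log cost).  A sample is classified by
log C_s = Σ_i log σ_{s,i}(f_i) — a naive-Bayes score with uniform priors, the
only reading consistent with "conditional probability of the flip given the
class" — with exact ties going to the class with the larger training prior,
then grade2.

A consequence worth stating plainly: with n in the thousands the margin is a
few hundredths, so `band_below_max` is a *top-slice* selector.  On the default
synthetic cohort it selects 1–6 genes with precision 1.0 but recall ≈ 0.1
over planted effects ≥ 0.8 log2 units, because single-feature accuracies
spread far wider than one margin.  The alternative `above_half` rule has the
opposite failure mode at desk scale: in-sample optimised accuracy of null
genes at n ≈ 107 samples is ≈ 0.6, well above 0.5 + ME, so it selects most of
the matrix.  Small, high-precision signatures are inherent to the method's
default configuration, not a tuning accident.

## Classification benchmark

The cohort is split stratified 72/35 (largest-remainder apportionment keeps
class proportions within one sample); selectors are fitted on the training
split only, and every (selector ∪ all-genes) × classifier pair is judged on
the same held-out samples.  Features are z-scored with training statistics
only.  KNN tunes odd k from 1 to min(21, n_train − 1) by 10-fold × 3 repeated
CV on plain accuracy (ties to the smaller k); SVM uses cost 1 with kernel
scale 1/(n_features·Var) for radial and sigmoid kernels; logistic regression
is unpenalised with bounded iterations and an explicit quasi-separation
warning when fitted probabilities are numerically 0/1.  Folds lacking both
classes are skipped with a warning.  Metrics: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), balanced accuracy (Se+Sp)/2, with grade 3 as the
positive class (detecting the higher grade is the clinically sensible
positive; every report header records the convention).  Zero denominators
raise rather than silently producing 0.

## Concordance, enrichment, survival

Signature concordance is the full Venn partition: one count per nonempty
membership pattern, which provably sums to the union size and marginalises to
per-set totals.  Volcano tables carry log2FC, −log10 adjusted p, and
threshold flags at |log2FC| > 1 and adjusted p < 0.01.  Over-representation
uses the hypergeometric upper tail P(X ≥ overlap) per term with BH adjustment
across tested terms and size bounds [5, 500]; by default the universe is
exactly what the caller supplies, with an opt-in restriction to the
collection's membership for annotation-backed collections (the pipeline entry
points enable it).  Suggested significance conventions: adjusted p < 0.01 for
a GO-like collection, p < 0.05 (adjusted, by default) for a KEGG-like one;
both configurable.

Survival screening standardises each gene to unit SD before Cox fitting, so
hazard ratios are per SD of expression (recorded in output headers).  Fits
use lifelines' partial-likelihood optimiser with Efron tie handling; the
univariate model has the gene alone, the interaction model gene + grade3 +
gene×grade3, both with Wald p-values (significance 0.01 by default).
Proportional hazards is checked per term with the Schoenfeld-residual test
(KM time transform) at α = 0.05; violating or non-converged genes are
excluded from downstream tables with a logged warning rather than an error.
Kaplan–Meier curves and the two-group log-rank test compare grades directly;
a group with zero events makes the comparison undefined and raises.

## The simulator

`simulate_expression` draws value(g, s) = μ_g + Δ_g·1[grade3] + λ·F_{b(g),s}
+ ε with μ_g ~ U(5, 12) log2 units, gene noise σ_g ~ U(0.4, 1.0), planted
effects |Δ| ~ U(0.3, 1.2) on 60 of 2000 genes (85% up-regulated in grade 3),
and ten co-regulation blocks of 5–20 genes sharing a per-sample N(0,1) factor
with loading 0.6, giving within-class gene–gene correlation λ²/(λ²+σ²) ≈
0.3–0.6.  The 55/52 class split, the effect and intensity ranges, and the
predominance of up-regulation emulate the motivating astrocytoma cohort; the
gene count is 2000 rather than ~10,000 so the full suite runs on one CPU in
minutes (a full-scale configuration is one constructor argument away, and the
open question of how the original ~54k probe sets were reduced to ~10k genes
is deliberately not emulated).  Gaussian log2 intensities are used instead of
resampled real data because they match RMA-scale data shape while keeping
power analytically checkable.  `strong_signal_config` (|Δ| ~ U(1.5, 2.5),
σ ~ U(0.3, 0.6), 40 planted genes) is the clearly separable variant used for
end-to-end direction checks.

`simulate_survival` draws Weibull times T = base_scale·(−ln U·e^{−lp})^{1/k}
(shape k = 1.5, base scale 60 months) with log hazard linear in the grade
indicator and any listed genes (standardised first), so proportional hazards
holds by construction.  Censoring is independent uniform on [0, c_max], with
c_max tuned by bisection against the requested censoring fraction.
Expression and survival use independent seed sub-streams: changing any
survival parameter never changes expression values, and uncensored event
times are unchanged when only the censoring fraction moves.

What the simulator does **not** model: batch effects, missing values, array
spatial artefacts, heavy-tailed or discrete intensity distributions, and
class-dependent covariance.  Passing tests therefore demonstrate internal
correctness and calibration under a favourable Gaussian world, not
performance on real cohort data.

## Numerical choices and degenerate inputs

- BH adjustment is the exact step-up (vectorised cumulative minimum),
  verified against a literal brute-force implementation.
- ROC cut-off ties break to the smallest threshold, scanning the "positive
  above" orientation first; a gene constant across samples yields the
  majority-class accuracy.
- STIR zero-variance pools give statistic 0 and p 1 (never selected).
- Permutation-importance z is 0 when both mean and spread of the accuracy
  drops are 0; otherwise the spread is floored at 1e−12.
- Cox non-convergence and separation are caught and reported as NA rows, not
  crashes; fits are invariant to rescaling the time axis (rank dependence),
  which the tests assert.
- All randomness flows from explicit integer seeds through
  `numpy.random.SeedSequence` sub-streams; identical config + seed gives
  byte-identical outputs.

## Problem sizes used by the test suite

Module tests run on toy fixtures (tens of genes) and the default simulator
(2000 × 107).  Calibration checks use 5–10 seeds for recall/FDR, 40 seeds at
n = 400 for Cox null coverage, and 200 replicates for log-rank uniformity —
sizes chosen so the whole suite completes in a few minutes on a single CPU
while keeping binomial envelopes meaningful.  Boruta runs cap `max_runs` at
100 in tests; decisions under both null and strong signal resolve within
~20 runs, so the cap does not bind the assertions.
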