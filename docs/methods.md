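# Methods

This note documents the statistical procedures implemented in `metabotype`,
the defaults and why they were chosen, what the synthetic cohort generator
does and does not emulate, and the package's known limitations.

## Preprocessing

**Missing-value filtering.** Samples with a missing fraction strictly
greater than 1/3 are dropped first; variable missing fractions are then
recomputed on the surviving samples and variables above 1/3 are dropped.
The order matters (a variable can be rescued by removing bad samples) and
the operation is idempotent.

**KNN imputation.** Each missing entry is replaced by the
inverse-distance-weighted mean of that feature over the k nearest samples
that observe it. Distances are Euclidean over the mutually observed,
autoscaled features. Default k = 10 with inverse-distance weighting — the
convention of the classical expression-matrix KNN imputer; both k and the
weighting are configurable because reasonable analyses differ here. A
sample sharing no observed feature with any donor falls back to the feature
median and is logged. Observed entries are never altered.

**Autoscaling.** Mean 0, SD 1 per feature, with the sample (n−1) variance
denominator used consistently everywhere variance is computed (autoscaling,
block scaling, Q²). Numerically constant features are centred, left
unscaled and flagged. Inside the validation loop, scaling parameters are
estimated on each bootstrap training set and applied to its test set, so no
test information leaks into the transform; a `global_scaling` switch
reproduces the simpler scale-once reading, which differs negligibly at
these sample sizes but is not leakage-safe.

**Block scaling (fusion).** Each block is autoscaled per feature and then
divided by √p_block. Every block then contributes total variance exactly
1, so a 2000-feature LC-MS block cannot drown a 19-variable clinical panel.

**Class definitions.** Age: under 50 vs older than 65, with ages in
[50, 65] excluded; BMI: ≤ 25 vs > 30, with (25, 30] excluded; sex keeps
everyone. Boundary semantics are strict ("under", "over"), so exactly 50
and 65 are excluded.

## Models and tuning

PLS-DA (PLS regression on a −1/+1 class code, assignment by the nearer
code), linear-kernel SVM, random forest, and PLS regression for
quantitative traits. Hyperparameters are grid-searched by 7-fold
cross-validation on the training data only — components 1–15 for PLS
(bounded by min(p, n_train − fold size)), C ∈ {0.01, 0.1, 1, 10, 100} for
the SVM, and features-per-split ∈ {√p, p/4, p/2} at 500 trees for the
forest. The CV objective is balanced accuracy for classification
(consistent with the reported metric) and RMSEP for regression; ties break
toward the simpler model (fewer components, stronger regularization).
Experiment-grid defaults reduce these to components 1–5 and 200 trees so a
full grid finishes in minutes on one CPU; the full grids remain available
through `ModelSpec`.

## Validation

**Bootstrap + permutation NULL.** Each of B iterations draws n training
indices with replacement; the out-of-bag complement is the test set
(expected 63.2%/36.8% split, closed form 1 − (1 − 1/n)ⁿ). Iterations whose
test or training set lacks a class are redrawn (counted and reported). For
the skewed age/BMI problems the training classes are equalized by random
under-sampling of the majority class — inside the loop, before scaling and
tuning. The NULL model is trained on the same (balanced, scaled) training
set with labels randomly permuted and evaluated on the same test set; test
labels are never permuted. Per-iteration seeds derive deterministically
from the master seed (seed + iteration index), so runs are reproducible and
parallelizable.

**Empirical p-value.** The fraction of iterations in which the NULL model
strictly beats the observed model (ties do not count); a zero count is
reported as "< 1/B". A smoothed (x+1)/(B+1) estimator is available.

One property of this estimator deserves emphasis: it is a *paired count*,
not a permutation-distribution tail probability. When the data carry no
signal at all, the observed and NULL models are exchangeable within each
iteration, so the count/B concentrates near 0.5 rather than being uniform
on [0, 1] (we measure approximately Normal(0.5, 0.15) over independent
signal-free cohorts at n = 300, B = 100). It is therefore a conservative
significance heuristic — small values still indicate genuine signal — but
its null distribution should not be assumed uniform, and the package's
calibration suite checks the mean balanced accuracy (≈ 0.5 on null
cohorts) as the primary no-signal guarantee.

**Confusion matrices** follow the predicted-in-rows, actual-in-columns
convention with the positive class first ([[TP, FP], [FN, TN]]); the
summary matrix averages per-iteration percentages. **Balanced accuracy** is
the mean of the two per-class recalls.

**Learning curves** use stratified random splits at training fractions
0.1–0.9 (stratification avoids empty-class test sets at the extremes, and
is the one place the implementation goes beyond plain random splitting),
repeated (default 100×) with the same scale-on-train/tune/test contract.
Expect the spread to widen at high training fractions as test sets shrink.

**Q² vs RMSEP.** Q² uses the test-set mean of the true response in its
denominator (n is defined on the test set, so the test-set mean is the
consistent reading). Q² = 1 iff RMSEP = 0 for non-constant truth; a
constant test-set truth leaves Q² undefined and only RMSEP is returned.

## VIP panel selection

VIP_j = √( p · Σ_a SS_a (w_ja/‖w_a‖)² / Σ_a SS_a ), with SS_a the response
sum of squares explained by component a. The mean square of the VIPs is 1
by construction, which motivates the standard strict greater-than-one
selection rule. VIPs are available for PLS-DA and PLS-R fits; other model
kinds raise an error rather than returning a lookalike importance.

## Synthetic cohort generator

The generator exists so every downstream stage is testable end to end
without the original (unreleased) cohort. Defaults describe one fixed set
of study conditions:

* **Phenotypes** — sex Bernoulli(0.5); age uniform on 19–81 years (the
  published range; the real cohort's age histogram is not uniform, but only
  its range is available numerically); BMI lognormal(ln 25.2, 0.22), tuned
  so that among class-retained subjects ~71% fall below 25 kg/m² and ~29%
  above 30, matching the published class skew.
* **Clinical panel** — 19 variables at the published median/SD. TRIG,
  TBIL, ALT, AST, GGT and HDLC are lognormal (their published percentile
  intervals are right-skewed; for HDLC a Gaussian with the published SD
  would also produce non-positive concentrations); the rest are Gaussian,
  floored at 1% of the median. RATIO is computed as CHOL/HDLC with 5%
  multiplicative noise rather than drawn independently, so the lipid
  sub-block is genuinely correlated and the known univariate-vs-VIP
  discordance for correlated lipid measures can be reproduced.
* **Planted effects** — expressed in within-group (residual) SD units on
  the generation scale (log scale for lognormal variables). Sex: CREA −1.5
  in females (the dominant marker) plus smaller sex differences on 16
  further variables (liver enzymes, urea, blood pressure, ALP lower or HDL
  higher in females). The secondary effects are calibrated so the
  whole-panel separability gives bootstrap PLS-DA balanced accuracies in
  the high 80s — the level population cohorts of this kind actually reach —
  because skewed lognormal analytes discriminate less on the measurement
  scale than their log-scale shifts suggest. Age: standardized slopes on
  SBP (+0.40), PROT (−0.30), SGLUC (+0.30) and smaller lipid/DBP/ALT terms,
  giving a population R² ≈ 0.35 for the optimal linear predictor. BMI:
  ALT (+0.35), DBP (+0.30), HDLC (−0.30), RATIO (+0.20) and smaller terms,
  R² ≈ 0.32. These match the moderate quantitative predictability (Q² ≈
  0.3) reported for such panels.
* **Metabolomics blocks** — latent-factor matrices: ~10% of features per
  trait load on the standardized phenotype scores (strength 0.8 sex, 0.45
  age, 0.35 BMI, alternating signs, trait subsets overlapping by half so
  blocks are partially complementary to the clinical panel), plus five
  shared background factors for realistic inter-feature correlation and
  unit noise. Default widths (126/200/200) are scaled down from the real
  2000-feature LC-MS blocks for speed; widths are configurable.
* **Missingness** — MCAR at 6% in the clinical block, never leaving a row
  or column fully missing. The real missingness mechanism is
  uncharacterized; MCAR is the neutral choice.

What the generator does **not** emulate: chromatographic drift, batch and
QC structure, non-uniform age demographics, non-MCAR missingness, and
heavy-tailed intensity distributions of real MS features. Passing tests
therefore demonstrate that the *machinery* is correct and well calibrated,
not that real cohorts will reach the same accuracies.

## Numerical choices and degenerate inputs

Sample variance (ddof = 1) throughout; constant features flagged rather
than erroring; Wilcoxon tests use exact enumeration when both classes have
≤ 25 members and the midrank normal approximation with tie correction
otherwise; correlation-heatmap leaf orders come from average-linkage
clustering on 1 − R within each block (linkage and distance are
conventional choices and configurable ambitions, not contracts); PLS
component counts are capped by the training-fold size; empirical p-values
with a zero count are labelled "< 1/B" rather than 0.

## Limitations

* The random forest, even after under-sampling, remains somewhat skewed
  toward the majority class; no vote re-weighting is applied.
* Only binary classification is supported; no probability calibration, no
  nonlinear SVM kernels.
* The bootstrap is plain out-of-bag; no .632+ bias correction.
* The empirical p-value concentration property discussed above means its
  resolution and calibration are limited at small B.
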