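# Methods

`eaakit` implements an epigenetic-age-acceleration (EAA) analysis for
multi-study colon-methylome cohorts: clock scoring, control-anchored EAA with
mixed-model adjustment, tissue-type association statistics, and a
dataset-aware elastic-net classifier of colorectal-cancer (CRC) status. This
note records the models, the defaults and why, the numerical choices, and
what the synthetic test bed does and does not show about real data.

## Tissue vocabulary and study design

Samples carry one of four tissue labels: **healthy** (normal colon from
individuals without CRC), **normal** (histologically normal colon adjacent
to a CRC tumour), **tumour**, and **adenoma**. The scientific question the
pipeline serves is whether epigenetic ageing measures differ between these
tissues — in particular between *healthy* and *normal*, where field
cancerisation may leave a methylation signature before histology shows one —
and whether those differences support a diagnostic classifier. Cohorts are
unions of independent datasets (array batches) on two Illumina platforms
(450k, EPIC); a patient never spans datasets, and a patient may contribute a
tumour plus its adjacent-normal sample.

## Clock scoring

Three clock families are scored against a CpG × sample beta matrix:

* **linear** clocks: `raw = intercept + Σ_i w_i·β_i`, optionally followed by
  the Horvath-style inverse transform (`raw ≤ 0 → (1+A)·e^raw − 1`,
  `raw > 0 → (1+A)·raw + A`, adult-age knot `A = 20` by default — the value
  standard for the original transform, configurable);
* **mean-methylation** clocks: the plain mean beta over a CpG panel, with a
  stored orientation (hyper: higher methylation = more accumulated cell
  divisions; hypo: lower = more). The orientation is interpretive metadata
  only; the score is the unmodified mean;
* **mitotic-fit** clocks: per-sample division count `n` minimising
  `Σ_i (β_i − (a_i + b_i·c_i^n))²` over per-CpG parameters `(a, b, c)` with
  `c ∈ (0,1) ∪ (1,∞)` bounded away from 1. Default bounds on `n` are
  (1, 10⁴) divisions, reflecting that colon-crypt division counts are
  measured in the thousands over a lifetime.

Missing clock CpGs are handled by a configurable policy — `error`,
`observed-only` (drop terms, no renormalisation; the default) or
`impute-cohort-mean` — with per-sample coverage (fraction of the clock's
CpGs observed) always reported. The published clocks' original coefficient
sets are not redistributed with the package; any user-supplied definition
file in the documented CSV format is validated and scored, and the test
fixtures use synthetic clocks built from the simulator's ground truth.

The mitotic optimiser brackets the optimum on a 96-point geometric grid and
refines by bounded 1-D minimisation (tolerance 1e-6 on `n`). A flat model
(all `b_i = 0`) leaves the objective constant; the lower bound is returned
and flagged non-identifiable. Identifiability also degrades numerically once
`c_i^n` underflows (for `c ≈ 0.995`, beyond `n ≈ 3000`): estimates there sit
on a flat objective and should not be over-interpreted.

## Control-anchored EAA

EAA is defined against an **anchor** regression fitted by OLS on a reference
tissue class only — healthy colon by default:

1. `EA ~ CA + sex` (association mode) or `EA ~ CA` (classifier mode,
   optionally `+ platform`), fitted on anchor-class samples (≥ 3 required;
   sex coded 0 = female, 1 = male; platform 0 = 450k, 1 = EPIC);
2. raw EAA for *every* sample = EA − anchor prediction;
3. adjusted EAA = conditional residual of the random-intercept model
   `EAA ~ (1|dataset) + (1|patient)` fitted by REML: the raw EAA minus the
   fixed intercept and the predicted (BLUP) dataset and patient intercepts.

Anchoring on controls, rather than regressing on the whole cohort, keeps the
EAA of every clock on a common residual scale — including mitotic clocks
whose output (divisions or a 0–1 score) is not comparable to chronological
age — and makes "difference from the control class" the direct meaning of a
nonzero group mean.

The mixed model treats patients as nested in datasets (guaranteed by the
sample-sheet invariant). Variance components whose REML estimate collapses
to ~0 are dropped and the model refitted (their BLUPs are exactly zero; this
also avoids predicting from a singular covariance): with no repeated
patients the patient term is dropped, with a single dataset the dataset
term, and with neither grouping the adjustment reduces to grand-mean
centering. The fit uses L-BFGS with at most 200 iterations; if REML fails
outright the package falls back to group-mean centering with a warning. The
adjustment is fitted per clock independently.

**Outlier screening** uses the simple difference EAAd = EA − CA, defined for
first/second-generation clocks only (for mitotic clocks the difference is
meaningless). Per clock, mean and SD (ddof = 1) are computed over the whole
table, candidates included — exclusion-based z-scores would differ and are
deliberately not used. A sample is screened out when it lies outside
mean ± 3·SD (strict inequality) in at least `min_clocks` clocks: 2 in
association mode, 1 in classifier mode. Outliers are removed before the
anchor is fitted; a flag reverses the order for sensitivity analysis.

## Association statistics

Pearson correlation (EA vs CA per clock and tissue, Fisher-z CI), Spearman
rank correlation (EAA vs age/sex/side, binary covariates coded 0/1, unknown
side excluded), and Welch two-sample t-tests between tissue types
(Welch–Satterthwaite df, two-sided p, 95% CI on the mean difference). Strata
under 3 samples are reported as absent rather than zero; zero-variance
strata yield an undefined estimate. Raw p-values are reported with star bins
(ns > 0.05, * ≤ 0.05, ** < 1e-3, *** < 1e-4); a Benjamini–Hochberg column is
emitted for convenience and never gates anything. All tests are two-sided.

## Classifier

The classifier predicts tissue class among histologically normal samples
(positive class: tumour-adjacent *normal*; negative: *healthy*) from sex
plus one EAA feature per clock. Leakage control is structural:

* the train/test split is at dataset granularity — a dataset (a batch) is
  never divided;
* cross-validation folds are unordered dataset pairs: the two paired
  datasets form the fold test set, the rest the fold train set; a pair is
  valid only if both sides contain both classes (and, for the
  platform-adjusted variant, the fold-train healthy samples span both
  platforms, which shrinks the valid-pair set);
* inside every fold, the per-clock anchors (`EA ~ CA`, optionally
  `+ platform`, on fold-train healthy only) and the feature scaler
  (standard-normal, training means/SDs) are refitted on the fold train side;
  fold test features are scaled with the *training* statistics, never their
  own;
* each anchor, scaler and final fit records the sample IDs it used, so
  disjointness from evaluation data is assertable.

The elastic-net logistic model minimises

    (1/n) Σ deviance + λ·(α·‖β‖₁ + (1−α)/2·‖β‖₂²)

with an unpenalized intercept — glmnet's objective and (α, λ) scale, so
parameter pairs are comparable across software. The in-package solver is
IRLS with an inner cyclic coordinate-descent loop, soft-threshold updates,
a 1e-5 floor on IRLS weights and convergence tolerance 1e-7 on the maximum
coefficient change (at a joint fixed point the surrogate's KKT conditions
coincide with the true penalized-likelihood KKT conditions). Strict mode
raises on non-convergence; grid search runs non-strict because an
unpenalized fit on a separable fold diverges by construction, and the last
iterate's rankings are what the fold metric needs.

Grid search covers α ∈ {0, 0.05, …, 1} and λ ∈ {0, 0.01, …, 1} by default
(2121 points per fold) and selects the maximum mean ROC-AUC across folds;
ties break toward larger λ then larger α — the sparser model. ROC-AUC is
computed as the Mann–Whitney U statistic with ties counted ½ (identical to
trapezoidal ROC integration); its 95% CI uses DeLong's method. The PR curve
is summarised by step-wise average precision, with class prevalence as the
no-skill baseline.

## Synthetic cohorts and what they show

The generator emulates the structure the analyses rely on, under a
logit-normal methylation model:

    logit(β_is) = b0_i + m·(CA_s + Δ_s) + m·batch_d + platform + ε_is

for age-informative CpGs, where `m` is the drift per year on the logit scale
(default 0.02, placing lifetime drift within the near-linear range of the
sigmoid), `Δ_s` is the sample's true EAA offset in years (tissue group shift
plus N(0, 1 y) jitter), `batch_d ~ N(0, batch_sd)` is the dataset intercept
*in years* — applied through the slope so its effect on any clock's EAA is
directly in years and the batch-removal test has well-defined units — and
`platform` is an additive logit offset applied to every CpG of
EPIC-labelled datasets (EA impact ≈ platform_effect/m years). Background
CpGs carry the batch/platform terms without age signal; a sex-probe block
separates the sexes (mean beta 0.7 vs 0.3); a mitotic block follows
`β = a + b·c^n` with per-sample divisions `n = 500 + 20·Δ_s + N(0, 25)` —
tied to the planted EAA offset and *not* to chronological age, so mitotic
scores correlate weakly with CA (as mitotic clocks do) and carry exactly
zero class signal when all group shifts are zero (which makes the
leakage-null check clean). Biological dispersion (EAA and division jitter)
belongs to the stochastic regime: with `noise_sd = 0` the cohort is exactly
deterministic given age and tissue, which the exactness tests exploit.

Default cohort: 4 datasets × 80 samples, tissue mix 40/30/25/5%
(healthy/normal/tumour/adenoma, echoing the proportions typical of pooled
open-access colon series), ages uniform on 30–88, platforms alternating by
dataset, half the tumours paired with an adjacent normal from the same
patient (shared age/sex/patient ID). Group shifts default to −5 years in
adjacent-normal tissue (chosen for test power; the real-world effect sizes
per tissue are not established) with tumour/adenoma set positive. One root
random stream is seeded from the config; per-dataset sub-streams are
spawned deterministically, so identical config + seed is bit-identical.

Fixture clocks invert the generator: linear clocks use weights
`1/(p·m·β₀(1−β₀))` (the linearised inverse around mid-age; exact up to
sigmoid curvature, r > 0.99 with CA on noise-free healthy data), every
second one targeting the Horvath-transformed scale; mean-beta clocks
average the hyper-/hypo-methylating mitotic blocks; mitotic-fit clocks
reuse the planted `(a, b, c)` exactly.

What the synthetic bed does **not** emulate: probe chemistry and
normalisation artefacts, realistic CpG-level covariance (CpGs are
conditionally independent given the planted factors), non-linear age
trajectories, cell-type composition shifts, CpG-island methylator phenotype
structure, missing-not-at-random patterns, or platform effects that differ
per probe. Passing tests therefore demonstrate that the *procedures* are
correct and leak-free under the stated model, not that the classifier's
synthetic AUC transfers to real cohorts.

## Validation battery and problem sizes

The test suite checks, among other things: solver agreement with an
independent proximal-gradient optimizer (1e-4 on 20 random 40 × 12
problems) and with Newton/IRLS at λ = 0; ROC-AUC identity with the
Mann–Whitney statistic to 1e-12; recovery of a planted −5-year shift to
±0.5 y with Welch rejection in ≥ 95/100 seeds (2 × 200 samples, noise
SD 0.02); mixed-model removal of 3-year batch offsets to < 0.5 y dataset
means (5 × 200 samples); a cross-validation leakage null (6 × 70 samples,
batch SD 3, no class signal) where every grid point's mean ROC-AUC must
stay in [0.40, 0.60]; held-out ROC-AUC ≥ 0.85 in ≥ 18/20 seeds with the
planted multi-clock signal, and the platform-adjusted variant matching or
beating the unadjusted one in ≥ 16/20 seeds under a strong (1-logit)
planted platform offset; mitotic estimates within 1e-3 of a dense two-stage
grid oracle on 50 fixtures; and exact boundary arithmetic of the QC and
outlier filters (a sample at exactly 1% bad calls is retained; a value at
exactly 3 SD is not an outlier). Reduced grids (α step 0.25–0.5,
λ ∈ {0, 0.02–0.5}) and these cohort sizes keep each property cheap enough
to re-check on every run while leaving the planted effects overwhelmingly
detectable.

## Known limitations

* The mixed-model adjustment relies on statsmodels' MixedLM; extremely
  unbalanced or tiny groups can push REML to a boundary, in which case the
  affected component is dropped (BLUPs = 0) rather than regularised.
* The platform model is a single binary label; dialects within a platform
  are not represented.
* PR-AUC is step-wise average precision, which differs slightly from
  trapezoidal PR integration used by some R packages.
* The fold rule enumerates all dataset pairs; with many datasets this grows
  quadratically and no subsampling of folds is implemented.
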