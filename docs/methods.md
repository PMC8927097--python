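# Methods

## Problem setting

A transmission hyperspectral microscope images an H&E-stained section as a
hypercube: 640×480 pixels × 100 spectral channels covering 500–1000 nm in
5 nm steps. Values are transmittance — the fraction of lamp light passing
the slide at each wavelength after a two-point white/dark calibration
`T = (raw − dark)/(white − dark)`. The calibration formula itself is our
choice (only the fact of a black/white balancing is standard practice for
such instruments); it is the universal flat-field convention for
transmission imaging. T is clipped below at 0 but *not* above 1, so the
additive-noise statistics that SNV relies on survive calibration. Because
the microscope's glass optics pass little light above ~750 nm, all analysis
is restricted to 500–750 nm (51 bands).

Four tissue classes are annotated with circular ROIs: squamous epithelium,
EAC cells, tumor stroma, background. EAC and stroma are merged into one
tumor class for classification — their cell structure and staining are too
similar to separate reliably — leaving the fixed 3-class order
(tumor, squamous, background). Disc membership is Euclidean distance ≤
radius evaluated at integer 0-based pixel centers, origin top-left,
row-major; this convention is arbitrary but must be pinned for reproducible
pixel counts. Pixels claimed by overlapping discs of different labels are
excluded (and counted) rather than resolved by a priority rule, since no
annotation ordering is defined.

## Preprocessing

Fixed order: Gaussian smoothing → SNV → band selection.

* **Gaussian smoothing**, σ = 1 band (5 nm), spectral axis only, kernel
  truncated at 4σ and renormalized, edge replication at the window borders.
  Smoothing acts on raw transmittance; smoothing *after* SNV would destroy
  the unit-variance contract.
* **SNV**: per spectrum `(S − mean S)/sd S` over the full usable 500–750 nm
  window (population sd, ddof 0). Zero-variance spectra cannot be
  normalized; they are excluded with a logged count. A spectrum counts as
  zero-variance below sd = 1e−12·max(1, |mean|) — a numerically constant
  spectrum has rounding-level rather than exactly zero sd.
* **Band selection**: 560–675 nm inclusive on the 5 nm grid → 24 bands.
  All stated wavelength ranges in this package are inclusive at both ends.

The classifier features are computed on the **smoothed transmittance, not
the SNV output**: the ratio features are defined in transmittance units,
and SNV introduces zero crossings that make ratios ill-posed. SNV output
feeds the class-histogram diagnostics and an optional classifier variant
(`PreprocessConfig.snv_enabled`), kept for sensitivity analysis.

## Features

Two six-band sets pair index-wise in ascending order — k-set
{560,565,570,575,580,585} nm on the eosin flank, i-set
{650,655,660,665,670,675} nm on the hematoxylin flank — giving

    E_j = S(k_j)/S(i_j), j = 1…6;  E7 = mean_k S;  E8 = mean_i S.

Index-aligned pairing is the only assignment consistent with six features
whose first and last ratios are S560/S650 and S585/S675 on a 5 nm grid.
Ratios are invariant to any per-pixel or per-slide intensity gain; E7/E8
keep the absolute level. Pixels whose ratio denominator is ≤ 1e−12, or any
feature non-finite, are excluded with a logged count — no imputation, which
would inject label-correlated bias. The RGB baseline uses the three
synthetic-RGB channel means (R 585–725, G 540–590, B 530–560 nm) as
features instead.

## Classifier

A multi-layer perceptron with hidden layers (32, 16), tanh activations,
Adam optimizer. Architecture is fixed; the remaining settings are ordinary
defaults logged in the training manifest: learning rate 1e−3, batch 256,
max 200 epochs, early stop after a 10-epoch training-loss plateau
(tol 1e−4). Features are standardized to zero mean/unit variance with
training-fold statistics only (tanh saturates on unbounded ratios); the
scaler is part of the persisted model. Class scores are the softmax output
layer; prediction is the argmax with ties resolved toward the first class
in the fixed order, and invalid-feature pixels are labeled `unclassified`.

Balancing: EAC, stroma and background are each downsampled without
replacement to the squamous row count (squamous is the scarcest annotated
tissue in practice); classes already at or below that count are kept whole
with a warning, since upsampling would duplicate pixels. Balancing is
applied on the 4-class table before merging, and **inside each training
fold only** — the held-out patient keeps the natural pixel distribution.
Per-fold balancing is the only leakage-free reading; a global mode would
let test pixels influence the training subsample.

## Evaluation

LOPOCV over four arms: all patients (HSI-8), patients without neoadjuvant
treatment, patients with neoadjuvant treatment (CTx or RCTx), and all
patients with RGB-3 features. Per fold, one-vs-rest confusion counts give
sensitivity, specificity, accuracy and F1; ROC-AUC is the Mann–Whitney
pair probability (ties ½). Zero-denominator metrics are NaN with a logged
reason and excluded from cohort means (pooling would silently change n).
Cohort aggregation weights patients equally: mean ± SD across folds.

**Weighted accuracy** (the per-specimen correctness score) is the
support-weighted mean of per-class recall over the test pixel pool, which
equals plain pooled accuracy; a specimen is "correct" when it exceeds 60%.
A macro-average mode (balanced accuracy) exists for sensitivity analysis;
it is also the statistic used for the null-cohort check below, because its
expectation under any truth-independent predictor is exactly 1/3 for three
classes — pooled accuracy is not chance-calibrated here, since the
balance-then-merge rule gives the merged training set a (1/2, 1/4, 1/4)
prior and the test pool a similar composition, so even a
collapse-to-tumor predictor would score ~0.5 pooled.

Arm comparisons use a two-tailed paired t-test (α = 0.05) on per-patient
ROC-AUC differences; an all-zero difference vector is reported as t = 0,
p = 1 and flagged degenerate.

TNM-category/grading classification ("tenfold CV, 30% test" in the
original description is contradictory as printed) is implemented as 10
repeated patient-grouped 70/30 splits — honoring both the count and the
fraction — over four classifiers: logistic regression, poly-kernel SVM,
random forest, and the 32/16 MLP. Grouping by patient prevents pixel
leakage across the split. Levels with a single patient are dropped with a
warning; ties for best mean accuracy go to the simpler model
(LR < SVM < RF < MLP).

## Synthetic cohort generator

No public dataset exists for this task, so the generator emulates the
staining optics end-to-end and *defines the study conditions* for all
statistical tests.

Generative law: Beer–Lambert transmission with additive camera noise,

    T(λ) = g · 10^−A(λ) + ε(λ),
    A(λ) = c_E·A_eosin(λ) + c_H·A_hema(λ) + slope·(λ − 500 nm),

with Gaussian dye absorbance profiles peaking at 524 nm (eosin, width
30 nm) and 630 nm (hematoxylin, width 40 nm). This is the simplest physics
reproducing the observed dye peaks and the exactly log-linear background.
ε is N(0, 0.01) below 750 nm and N(0, 0.08) above (the optics make the NIR
channels nearly pure noise); T is clipped at 0.

Default dye loads (absorbance units, mean / patient-SD / pixel-SD):

| class      | eosin c_E          | hematoxylin c_H    | slope (1/nm) |
|------------|--------------------|--------------------|--------------|
| squamous   | 0.45 / 0.07 / 0.07 | 0.10 / 0.02 / 0.02 | 0            |
| EAC        | 0.42 / 0.07 / 0.07 | 0.50 / 0.08 / 0.08 | 0            |
| stroma     | 0.48 / 0.07 / 0.07 | 0.38 / 0.06 / 0.06 | 0            |
| background | 0                  | 0                  | 8e−4         |

These were chosen analytically, before any pipeline run, to encode three
qualitative facts: cancer cells' higher nucleus-to-plasma ratio means
stronger hematoxylin staining (squamous ≪ stroma < EAC, so EAC transmits
least at 630 nm); eosin loads are nearly equal across tissue classes, so
class densities almost coincide near 520 nm and separate on the
hematoxylin flank (555/655 nm) — the discriminative-band structure the
feature window exploits; and the unstained background is log-linear.
Variability is hierarchical (patient-level draw, then pixel-level draw
around it, negatives truncated at 0 and counted) with patient-SD ≈
pixel-SD, reproducing high inter- and intra-patient spread.

A per-patient illumination/staining gain g ~ N(1, 0.12) multiplies the
whole spectrum, emulating slide-to-slide staining and exposure
differences. This is the mechanism behind the HSI-vs-RGB contrast: the
band ratios E1–E6 cancel g exactly, while broadband RGB channel means
inherit it, so the RGB arm degrades across patients by construction — the
direction, not the magnitude, of the clinical finding.

Neoadjuvant chemotherapy multiplies eosin loads by 0.8 (a free knob, not a
literature estimate: only the location of the effect — the eosin peak — is
established, not its size or sign). TNM/G categories are sampled from the
cohort's marginal frequencies (T1/T2/T3/T4 = 45/21/29/0, N0/N+ = 55/40,
M0/M+ = 91/4, G1/G2/G3/n.a. = 3/13/28/51 per 95) and add small
multiplicative shifts (0.12 per level index) on the tumor hematoxylin
load, so category classification has recoverable signal. Treatment arms
get exact counts, `round(n·fraction)`, over a seeded shuffle.

Default cohort: 20 patients, one 64×64 cube each (a deliberate
scale-down from 640×480 to keep simulations desk-sized; the spectral
dimension and all processing are identical), quadrant region layout with
one class per quadrant, 5 circular ROIs of radius 3 px per class —
echoing the at-least-5-annotated-cells practice. One seed determines
everything; identical seeds give bit-identical cohorts and reports.

What the generator does **not** emulate: cell morphology and texture
(regions are spatially homogeneous), optical blur/PSF, stain co-
localization within a pixel, annotation error, and the severe class
imbalance of real annotation campaigns (all classes get equal ROI counts).
Passing tests therefore demonstrate correctness and statistical sanity of
the pipeline — balancing, fold disjointness, chance behavior under a null
cohort, the HSI>RGB direction under gain variability — not clinical
performance. The original study's headline numbers (e.g. 78% tumor
accuracy over 95 patients) derive from data that are not public and are
deliberately not targets here; on the clean synthetic conditions the same
pipeline scores higher (~95–99%), as expected for a generator without
morphological confounds.

## Numerical choices and degenerate inputs

* `nearest_band` rounds to the nearest grid wavelength with exact ties
  toward the lower band.
* hsic container writes are byte-deterministic (sorted JSON header + raw
  C-order float64 payload); the ENVI dialect (text header + band-sequential
  float64) is provided for interoperability with generic HSI tools.
* Calibration rejects references with white ≤ dark on more than 10% of
  entries; all-bad bands are flagged in cube metadata.
* ROC-AUC with single-class truth, recalls with zero support, and paired
  t-tests with < 3 finite pairs are all reported NaN/degenerate-flagged,
  never silently coerced.
* Fold seeds and balancing seeds derive from the run seed through a
  numpy `SeedSequence`, keeping every derived seed below 2^31.

## Known limitations

* The MLP is scikit-learn's; training a 20-fold LOPOCV on the default
  cohort takes ~1 minute per arm on one CPU. Whole-frame prediction of a
  640×480 cube takes a few seconds.
* The SNV-variant classifier path is implemented but not the default;
  ratio features on SNV output discard many pixels near zero crossings.
* The generator's treatment and TNM effect sizes are plausibility knobs;
  conclusions about subgroup differences on synthetic data reflect those
  knobs, nothing more.
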