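# spectropath

Pixel-wise classification of H&E-stained esophageal specimens from
hyperspectral microscopy data.

Histopathological diagnosis of esophageal adenocarcinoma (EAC) rests on
telling malignant from non-malignant cells in stained tissue sections.
A hyperspectral transmission microscope records, for every pixel, a full
transmittance spectrum (here 640×480 pixels × 100 bands over 500–1000 nm)
instead of three broadband color channels; the differential uptake of the
two stains — eosin (absorbance peak 524 nm, cytoplasm/stroma) and
hematoxylin (peak 630 nm, nuclei) — then leaves a class-specific spectral
fingerprint. This package implements the complete analysis pipeline for
that setting, for image-analysis researchers and methods developers:

* **Cube I/O and calibration** — white/dark two-point balancing
  `T = (raw − dark)/(white − dark)`, spectral cropping to the usable
  500–750 nm window (glass optics block the near infrared), and a
  synthetic-RGB preview (B = 530–560 nm, G = 540–590 nm, R = 585–725 nm
  channel means).
* **Preprocessing** — Gaussian spectral smoothing (σ = 1 band), per-spectrum
  standard-normal-variate (SNV) normalization, and selection of the
  discriminative 560–675 nm analysis window (24 bands).
* **Features** — eight spectral features per pixel: six index-paired band
  ratios over the k-set (560…585 nm) and i-set (650…675 nm),

      E_j = S(k_j) / S(i_j),  j = 1…6        (E1 = S560/S650 … E6 = S585/S675)
      E7  = mean of S over the k-set,  E8 = mean of S over the i-set,

  plus a 3-feature synthetic-RGB baseline variant.
* **Classifier** — a multi-layer perceptron with two hidden layers
  (32 and 16 tanh units, Adam optimizer) over standardized features; the
  four-class annotation taxonomy (squamous epithelium, EAC, tumor stroma,
  background) is merged to three classes (tumor = EAC + stroma) and the
  training set is balanced by downsampling every class to the squamous
  count.
* **Evaluation** — leave-one-patient-out cross-validation (LOPOCV) with
  per-class sensitivity, specificity, accuracy, F1 and ROC-AUC; the
  correct-classification rule (support-weighted recall > 60%); subgroup
  arms (with/without neoadjuvant chemotherapy, RGB-only baseline); paired
  t-tests on per-patient ROC-AUC; and grouped 70/30 repeated splits for
  TNM-category / grading classification.
* **Synthetic cohort generator** — Beer–Lambert transmission spectra with
  class-dependent dye loads, hierarchical patient/pixel variability,
  per-slide illumination gain and inflated noise above 750 nm, so the whole
  pipeline is testable without clinical data (see `docs/methods.md`).

## Worked example

Simulate a small 6-patient cohort and run the hyperspectral and RGB arms:

```bash
cat > small.yaml <<'YAML'
cohort:
  n_patients: 6
  cube_height: 48
  cube_width: 48
  roi_radius: 2.5
YAML
spectropath simulate --config small.yaml --seed 0 --out cohort/
spectropath run --cohort cohort/ --config small.yaml --seed 0 --out run/ \
    --arms all-hsi,all-rgb
```

which prints (numbers from this exact invocation):

```
wrote 6 cubes and 120 ROIs to cohort/
all-hsi: fraction correct 1.00 over 6 folds
all-rgb: fraction correct 1.00 over 6 folds
```

and writes, per arm, `*_mean.csv` / `*_sd.csv` (metrics × classes, in %),
`*_folds.csv` (per-patient metrics), a `*_table.csv` rendering
(`mean ± SD`), per-patient classification maps under `run/maps/` (tumor
green, squamous blue, background yellow) and a paired t-test table
`ttest_hsi_vs_rgb.csv`. From `run/all-hsi_mean.csv` of that run:

```
,tumor,squamous,background
sensitivity,92.481884,96.260221,100.000000
specificity,98.209653,94.932845,100.000000
accuracy,95.316636,95.316636,100.000000
f1,94.320179,92.727344,100.000000
roc_auc,99.974192,99.116809,100.000000
```

Every specimen clears the 60% weighted-accuracy rule
(`fraction correct 1.00`), the tumor class is recovered with ~95% mean
accuracy across held-out patients, and the background is trivially
separable (its spectrum is linear, unstained). In Python the same run is

```python
import spectropath as sp
cohort = sp.simulate_cohort(sp.CohortConfig(n_patients=6, cube_height=48,
                                            cube_width=48, roi_radius=2.5))
cubes = [sp.crop_spectral(c, 500, 750) for c in cohort.cubes]
table = sp.extract_spectra(cubes, cohort.rois, cohort.patients)
report, folds = sp.lopocv(table, "all-hsi")
print(report.to_dataframe())
```

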