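"""Synthetic H&E-stained hypercube cohort generator.

No public hyperspectral histopathology cohort exists for this task, so the
pipeline is exercised on simulated specimens built from the staining optics
of transmission microscopy:

* Beer-Lambert transmission: ``T(lambda) = g * 10**(-A(lambda)) + noise``
  with total absorbance ``A = c_E * A_eosin + c_H * A_hema + slope * (lambda
  - 500)``.  Dye absorbance profiles are Gaussian bumps peaking at 524 nm
  (eosin) and 630 nm (hematoxylin).
* Class structure: tumor cells (EAC) carry the strongest hematoxylin load
  (high nucleus-to-plasma ratio), stroma an intermediate one, squamous
  epithelium very little; the background is unstained with a small linear
  absorbance trend only, so its log10-transmittance is exactly linear.
* Eosin loads are nearly equal across tissue classes, so transmittance
  distributions almost coincide near 520 nm and separate in the 555-675 nm
  hematoxylin region -- the discriminative-band structure the feature set
  relies on.
* Variability is hierarchical: per-patient dye-load draws, then per-pixel
  draws around the patient value, plus a per-patient illumination/staining
  gain ``g`` multiplying the whole spectrum.  The gain emulates slide-to-
  slide staining and exposure differences; band *ratios* cancel it, broadband
  channel means do not.  Camera noise is additive Gaussian, inflated above
  750 nm where the microscope optics block most light.
* Neoadjuvant chemotherapy (CTx) multiplies the eosin load, moving the
  between-group spectral difference onto the eosin peak; TNM category and
  grading add small multiplicative shifts on the tumor hematoxylin load so
  the category classifiers have recoverable signal.

Every draw flows from one seed; identical seeds give bit-identical cohorts.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import asdict, dataclass, field, replace
from typing import Mapping

import numpy as np

from .annotation import (AnnotationROI, BACKGROUND, CLASSES_4, EAC,
                         PatientRecord, SQUAMOUS, STROMA, write_annotations,
                         write_patients, read_annotations, read_patients)
from .cube_io import Hypercube, WavelengthGrid, read_cube, write_cube
from .errors import LayoutError, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Dyes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DyeSpectrum:
    """Gaussian absorbance profile of one stain."""

    peak_nm: float
    width_nm: float
    base_amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0 or self.base_amplitude < 0:
            raise ValidationError("dye width must be > 0 and amplitude >= 0")


EOSIN = DyeSpectrum(peak_nm=524.0, width_nm=30.0)
HEMATOXYLIN = DyeSpectrum(peak_nm=630.0, width_nm=40.0)


def dye_absorbance(wavelength_nm, dye: DyeSpectrum):
    """Absorbance at ``wavelength_nm``: a Gaussian bump with maximum at the peak."""
    lam = np.asarray(wavelength_nm, dtype=np.float64)
    if np.any(lam < 400.0) or np.any(lam > 1000.0):
        raise ValidationError("wavelength outside 400-1000 nm")
    out = dye.base_amplitude * np.exp(-((lam - dye.peak_nm) ** 2)
                                      / (2.0 * dye.width_nm ** 2))
    return float(out) if np.isscalar(wavelength_nm) else out


# ---------------------------------------------------------------------------
# Tissue class models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DyeLoad:
    """Dimensionless stain concentration: mean with patient- and pixel-level SD."""

    mean: float
    patient_sd: float
    pixel_sd: float


@dataclass(frozen=True)
class TissueClassModel:
    label: str
    eosin_load: DyeLoad
    hematoxylin_load: DyeLoad
    baseline_slope: float = 0.0       # absorbance per nm (background trend)
    noise_sd: float = 0.01            # additive transmittance noise < 750 nm
    noise_sd_nir: float = 0.08        # inflated noise above 750 nm


def default_class_models() -> dict[str, TissueClassModel]:
    """Study-condition defaults (absorbance units).

    Eosin loads are close across tissue classes (0.42-0.48) while
    hematoxylin separates them (squamous 0.10 < stroma 0.38 < EAC 0.50), so
    EAC transmits least at 630 nm and class densities overlap near 520 nm
    but not near 555/655 nm.
    """
    return {
        SQUAMOUS: TissueClassModel(SQUAMOUS,
                                   DyeLoad(0.45, 0.07, 0.07),
                                   DyeLoad(0.10, 0.02, 0.02)),
        EAC: TissueClassModel(EAC,
                              DyeLoad(0.42, 0.07, 0.07),
                              DyeLoad(0.50, 0.08, 0.08)),
        STROMA: TissueClassModel(STROMA,
                                 DyeLoad(0.48, 0.07, 0.07),
                                 DyeLoad(0.38, 0.06, 0.06)),
        BACKGROUND: TissueClassModel(BACKGROUND,
                                     DyeLoad(0.0, 0.0, 0.0),
                                     DyeLoad(0.0, 0.0, 0.0),
                                     baseline_slope=8e-4),
    }


def null_class_models() -> dict[str, TissueClassModel]:
    """All four classes share one tissue model: no class signal at all."""
    ref = default_class_models()[SQUAMOUS]
    return {lab: replace(ref, label=lab) for lab in CLASSES_4}


# ---------------------------------------------------------------------------
# Cohort configuration
# ---------------------------------------------------------------------------

#: marginal frequencies of the clinico-pathological categories (counts / 95)
TNM_MARGINALS = {
    "T": (("T1", 45), ("T2", 21), ("T3", 29), ("T4", 0)),
    "N": (("N0", 55), ("N+", 40)),
    "M": (("M0", 91), ("M+", 4)),
    "G": (("G1", 3), ("G2", 13), ("G3", 28), ("n.a.", 51)),
}

#: per-level shift indices used for the tumor hematoxylin factor
_TNM_SHIFT_INDEX = {
    "T1": 0, "T2": 1, "T3": 2, "T4": 3,
    "N0": 0, "N+": 1,
    "M0": 0, "M+": 2,     # rare but strong effect
    "G1": 0, "G2": 1, "G3": 2, "n.a.": 0,
}


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the synthetic cohort (seed fully determines output)."""

    n_patients: int = 20
    fraction_ctx: float = 46.0 / 95.0
    fraction_rctx: float = 3.0 / 95.0
    ctx_eosin_shift: float = 0.8          # multiplies eosin load under CTx/RCTx
    cube_height: int = 64
    cube_width: int = 64
    rois_per_class: int = 5               # >= 5 annotated cells per class
    roi_radius: float = 3.0
    illumination_gain_sd: float = 0.12    # per-patient gain on T
    tnm_hema_shift: float = 0.12          # per level-index step on tumor hematoxylin
    nir_cutoff_nm: float = 750.0
    rng_seed: int = 0
    grid: WavelengthGrid = field(default_factory=WavelengthGrid)
    class_models: Mapping[str, TissueClassModel] = field(default_factory=default_class_models)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_ctx <= 1.0 or not 0.0 <= self.fraction_rctx <= 1.0:
            raise ValidationError("treatment fractions must lie in [0, 1]")
        if self.n_patients < 2:
            raise ValidationError("cohort needs n_patients >= 2")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = self.grid.to_dict()
        d["class_models"] = {k: asdict(v) for k, v in self.class_models.items()}
        return d


@dataclass(frozen=True)
class PatientClassEffect:
    """Patient-level concentration draws for one tissue class, plus the gain."""

    eosin_c: float
    hematoxylin_c: float
    gain: float = 1.0


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def beer_lambert_transmittance(c_eosin: float, c_hema: float, slope: float,
                               wavelength_nm, gain: float = 1.0):
    """Noise-free transmittance: ``g * 10**-(c_E A_E + c_H A_H + slope (lam-500))``."""
    lam = np.asarray(wavelength_nm, dtype=np.float64)
    absorb = (c_eosin * dye_absorbance(lam, EOSIN)
              + c_hema * dye_absorbance(lam, HEMATOXYLIN)
              + slope * (lam - 500.0))
    return gain * np.power(10.0, -absorb)


def _simulate_block(model: TissueClassModel, effect: PatientClassEffect,
                    n_pixels: int, grid: WavelengthGrid,
                    rng: np.random.Generator,
                    nir_cutoff_nm: float = 750.0) -> tuple[np.ndarray, int]:
    """Vectorized pixel spectra for one (class, patient) block."""
    lam = grid.wavelengths
    c_e = rng.normal(effect.eosin_c, model.eosin_load.pixel_sd, size=n_pixels)
    c_h = rng.normal(effect.hematoxylin_c, model.hematoxylin_load.pixel_sd, size=n_pixels)
    n_trunc = int((c_e < 0).sum() + (c_h < 0).sum())
    c_e = np.clip(c_e, 0.0, None)
    c_h = np.clip(c_h, 0.0, None)
    absorb = (np.outer(c_e, dye_absorbance(lam, EOSIN))
              + np.outer(c_h, dye_absorbance(lam, HEMATOXYLIN))
              + model.baseline_slope * (lam - 500.0))
    t = effect.gain * np.power(10.0, -absorb)
    sd = np.where(lam > nir_cutoff_nm, model.noise_sd_nir, model.noise_sd)
    if np.any(sd > 0):
        t = t + rng.normal(0.0, 1.0, size=t.shape) * sd
    return np.clip(t, 0.0, None), n_trunc


def simulate_spectrum(class_model: TissueClassModel, patient_effect: PatientClassEffect,
                      rng: np.random.Generator,
                      grid: WavelengthGrid | None = None,
                      nir_cutoff_nm: float = 750.0) -> np.ndarray:
    """One pixel spectrum over the full grid (hierarchical patient-then-pixel draw)."""
    grid = grid or WavelengthGrid()
    block, n_trunc = _simulate_block(class_model, patient_effect, 1, grid, rng,
                                     nir_cutoff_nm)
    if n_trunc:
        logger.debug("simulate_spectrum: truncated %d negative draws", n_trunc)
    return block[0]


def quadrant_layout(height: int, width: int) -> dict[str, tuple[int, int, int, int]]:
    """Default region spec: one quadrant (y0, y1, x0, x1; half-open) per class."""
    hy, hx = height // 2, width // 2
    return {SQUAMOUS: (0, hy, 0, hx), EAC: (0, hy, hx, width),
            STROMA: (hy, height, 0, hx), BACKGROUND: (hy, height, hx, width)}


def simulate_cube(patient: PatientRecord,
                  effects: Mapping[str, PatientClassEffect],
                  config: CohortConfig,
                  rng: np.random.Generator,
                  layout: Mapping[str, tuple[int, int, int, int]] | None = None,
                  ) -> tuple[Hypercube, list[AnnotationROI]]:
    """One specimen field: region-wise class spectra plus ground-truth ROIs.

    Each present class gets ``rois_per_class`` circular annotations fully
    inside its region, echoing the at-least-5-cells-per-class annotation
    practice.
    """
    h, w = config.cube_height, config.cube_width
    layout = layout or quadrant_layout(h, w)
    values = np.zeros((h, w, config.grid.n_bands))
    n_trunc = 0
    for label in CLASSES_4:
        if label not in layout:
            continue
        y0, y1, x0, x1 = layout[label]
        if not (0 <= y0 < y1 <= h and 0 <= x0 < x1 <= w):
            raise LayoutError(f"region {label} {layout[label]} outside {h}x{w} cube")
        n_pix = (y1 - y0) * (x1 - x0)
        block, nt = _simulate_block(config.class_models[label], effects[label],
                                    n_pix, config.grid, rng, config.nir_cutoff_nm)
        values[y0:y1, x0:x1, :] = block.reshape(y1 - y0, x1 - x0, -1)
        n_trunc += nt
    if n_trunc:
        logger.debug("simulate_cube %s: truncated %d negative concentration draws",
                     patient.patient_id, n_trunc)

    rois: list[AnnotationROI] = []
    r = config.roi_radius
    for label in CLASSES_4:
        if label not in layout:
            continue
        y0, y1, x0, x1 = layout[label]
        if y1 - y0 < 2 * r + 1 or x1 - x0 < 2 * r + 1:
            raise LayoutError(f"region {label} too small for ROI radius {r}")
        for _ in range(config.rois_per_class):
            cy = rng.uniform(y0 + r, y1 - 1 - r)
            cx = rng.uniform(x0 + r, x1 - 1 - r)
            rois.append(AnnotationROI(float(cx), float(cy), r, label,
                                      patient.patient_id))
    cube = Hypercube(values, config.grid, patient.patient_id,
                     meta={"synthetic": True})
    return cube, rois


@dataclass
class Cohort:
    """A simulated study cohort: cubes, ground-truth ROIs, patient records."""

    cubes: list[Hypercube]
    rois: list[AnnotationROI]
    patients: dict[str, PatientRecord]
    config: CohortConfig
    manifest: dict


def _sample_level(rng: np.random.Generator, marginals) -> str:
    levels = [lv for lv, _ in marginals]
    counts = np.array([c for _, c in marginals], dtype=float)
    return str(rng.choice(levels, p=counts / counts.sum()))


def _tnm_factor(patient: PatientRecord, shift: float) -> float:
    f = 1.0
    for level in (patient.T, patient.N, patient.M, patient.G):
        f *= 1.0 + shift * _TNM_SHIFT_INDEX[level]
    return f


def simulate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate the full synthetic cohort from one seed.

    Treatment arms get exact counts (``round(n * fraction)``) assigned over a
    seeded shuffle; TNM/G categories are sampled from the cohort marginal
    frequencies; each patient receives hierarchical dye-load draws, an
    illumination gain, and one hypercube with ground-truth annotations.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.rng_seed)

    n = config.n_patients
    n_ctx = int(round(n * config.fraction_ctx))
    n_rctx = min(int(round(n * config.fraction_rctx)), n - n_ctx)
    treatments = (["CTx"] * n_ctx + ["RCTx"] * n_rctx
                  + ["none"] * (n - n_ctx - n_rctx))
    order = rng.permutation(n)
    assigned = [""] * n
    for slot, treat in zip(order, treatments):
        assigned[slot] = treat

    cubes: list[Hypercube] = []
    rois: list[AnnotationROI] = []
    patients: dict[str, PatientRecord] = {}
    per_patient = []
    for i in range(n):
        pid = f"P{i:03d}"
        patient = PatientRecord(pid, assigned[i],
                                _sample_level(rng, TNM_MARGINALS["T"]),
                                _sample_level(rng, TNM_MARGINALS["N"]),
                                _sample_level(rng, TNM_MARGINALS["M"]),
                                _sample_level(rng, TNM_MARGINALS["G"]))
        patients[pid] = patient

        gain = float(max(rng.normal(1.0, config.illumination_gain_sd), 0.1))
        treated = patient.neoadjuvant != "none"
        tnm_factor = _tnm_factor(patient, config.tnm_hema_shift)
        effects: dict[str, PatientClassEffect] = {}
        for label in CLASSES_4:
            model = config.class_models[label]
            e_mean = model.eosin_load.mean * (config.ctx_eosin_shift if treated else 1.0)
            h_mean = model.hematoxylin_load.mean
            if label in (EAC, STROMA):
                h_mean *= tnm_factor
            c_e = max(float(rng.normal(e_mean, model.eosin_load.patient_sd)), 0.0)
            c_h = max(float(rng.normal(h_mean, model.hematoxylin_load.patient_sd)), 0.0)
            effects[label] = PatientClassEffect(c_e, c_h, gain)
        cube, patient_rois = simulate_cube(patient, effects, config, rng)
        cubes.append(cube)
        rois.extend(patient_rois)
        per_patient.append({"patient_id": pid, "neoadjuvant": patient.neoadjuvant,
                            "gain": gain, "n_rois": len(patient_rois)})

    manifest = {"rng_seed": config.rng_seed, "n_patients": n,
                "config": config.to_dict(), "patients": per_patient}
    logger.info("simulated cohort: %d patients (%d CTx, %d RCTx), %d ROIs",
                n, n_ctx, n_rctx, len(rois))
    return Cohort(cubes, rois, patients, config, manifest)


# ---------------------------------------------------------------------------
# On-disk cohort
# ---------------------------------------------------------------------------

def save_cohort(cohort: Cohort, outdir: str, force: bool = False) -> None:
    os.makedirs(outdir, exist_ok=True)
    existing = [f for f in os.listdir(outdir) if not f.startswith(".")]
    if existing and not force:
        raise FileExistsError(f"{outdir} is not empty (use force=True)")
    cube_files = {}
    for cube in cohort.cubes:
        fname = f"{cube.patient_id}.hsic"
        write_cube(cube, os.path.join(outdir, fname))
        cube_files[cube.patient_id] = fname
    write_annotations(cohort.rois, os.path.join(outdir, "annotations.csv"), cube_files)
    write_patients(cohort.patients, os.path.join(outdir, "patients.csv"))
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(cohort.manifest, fh, indent=2, sort_keys=True)


def load_cohort(cohort_dir: str) -> Cohort:
    with open(os.path.join(cohort_dir, "manifest.json")) as fh:
        manifest = json.load(fh)
    patients = read_patients(os.path.join(cohort_dir, "patients.csv"))
    rois = read_annotations(os.path.join(cohort_dir, "annotations.csv"))
    cubes = [read_cube(os.path.join(cohort_dir, f"{pid}.hsic"))
             for pid in sorted(patients)]
    cfg_dict = manifest["config"]
    config = CohortConfig(
        n_patients=cfg_dict["n_patients"],
        fraction_ctx=cfg_dict["fraction_ctx"],
        fraction_rctx=cfg_dict["fraction_rctx"],
        ctx_eosin_shift=cfg_dict["ctx_eosin_shift"],
        cube_height=cfg_dict["cube_height"],
        cube_width=cfg_dict["cube_width"],
        rois_per_class=cfg_dict["rois_per_class"],
        roi_radius=cfg_dict["roi_radius"],
        illumination_gain_sd=cfg_dict["illumination_gain_sd"],
        tnm_hema_shift=cfg_dict["tnm_hema_shift"],
        nir_cutoff_nm=cfg_dict["nir_cutoff_nm"],
        rng_seed=cfg_dict["rng_seed"],
        grid=WavelengthGrid(**cfg_dict["grid"]),
        class_models={k: TissueClassModel(label=v["label"],
                                          eosin_load=DyeLoad(**v["eosin_load"]),
                                          hematoxylin_load=DyeLoad(**v["hematoxylin_load"]),
                                          baseline_slope=v["baseline_slope"],
                                          noise_sd=v["noise_sd"],
                                          noise_sd_nir=v["noise_sd_nir"])
                      for k, v in cfg_dict["class_models"].items()})
    return Cohort(cubes, rois, patients, config, manifest)
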