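"""Spectral preprocessing: Gaussian denoising, SNV normalization, band selection.

The fixed pipeline order is smooth -> SNV -> band selection.  Smoothing acts
on raw transmittance (denoising before any rescaling); SNV afterwards would
otherwise lose its unit-variance contract.  The band-ratio features are
computed on the *smoothed* transmittance, not the SNV output -- the ratio
definitions are written in transmittance units and SNV introduces
zero-crossings that make ratios ill-posed.  The SNV path therefore feeds
diagnostics (class histograms, sensitivity analyses) and an optional
classifier variant, both selectable through :class:`PreprocessConfig`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .cube_io import BandSet, WavelengthGrid
from .errors import RangeError, ValidationError

logger = logging.getLogger(__name__)

PIPELINE_ORDER = "gaussian_smooth -> snv -> select_bands"


@dataclass(frozen=True)
class PreprocessConfig:
    """Preprocessing knobs.

    gaussian_sigma
        Width of the spectral Gaussian filter in band-index units (1 band =
        5 nm on the native grid).  Default 1.
    snv_enabled
        When True the classifier features are computed from SNV-normalized
        spectra instead of smoothed transmittance (sensitivity variant).
    analysis_lo_nm / analysis_hi_nm
        The analysis window retained for classification (560-675 nm
        inclusive on the 5 nm grid -> 24 bands).
    """

    gaussian_sigma: float = 1.0
    snv_enabled: bool = False
    analysis_lo_nm: float = 560.0
    analysis_hi_nm: float = 675.0
    order: str = PIPELINE_ORDER

    def __post_init__(self) -> None:
        if self.gaussian_sigma <= 0:
            raise ValidationError("gaussian_sigma must be > 0")
        if self.analysis_lo_nm >= self.analysis_hi_nm:
            raise ValidationError("analysis_lo_nm must be < analysis_hi_nm")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessConfig":
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


def gaussian_smooth(spectra: np.ndarray, sigma: float = 1.0) -> np.ndarray:
    """1-D Gaussian convolution along the spectral (last) axis only.

    The kernel is truncated at 4 sigma and renormalized; boundaries use edge
    replication, so a constant spectrum passes through unchanged.  Spatial
    axes are never smoothed.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be > 0")
    spectra = np.asarray(spectra, dtype=np.float64)
    if spectra.shape[-1] < 3:
        raise ValidationError("spectra need at least 3 bands to smooth")
    return gaussian_filter1d(spectra, sigma, axis=-1, mode="nearest", truncate=4.0)


def snv(spectra: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standard-normal-variate: per spectrum ``(S - mean(S)) / sd(S)``.

    Statistics are taken over the bands present in the input (pass the full
    usable 500-750 nm window to match whole-range normalization).  Returns
    ``(normalized, valid_mask)``: zero-variance spectra cannot be normalized
    and are excluded from the output with a logged count, never silently
    zeroed.  ``normalized`` holds only the valid rows, in input order.
    """
    arr = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    # constant spectra have sd at rounding-error level, not exactly zero
    valid = sd[:, 0] > 1e-12 * np.maximum(1.0, np.abs(mean[:, 0]))
    n_bad = int((~valid).sum())
    if n_bad:
        logger.warning("snv: excluded %d zero-variance spectra", n_bad)
    out = (arr[valid] - mean[valid]) / sd[valid]
    if np.asarray(spectra).ndim == 1:
        return out[0] if valid[0] else out.reshape(0, arr.shape[1]), valid
    return out, valid


def select_bands(spectra: np.ndarray, grid: WavelengthGrid,
                 lo_nm: float, hi_nm: float) -> tuple[np.ndarray, BandSet]:
    """Retain bands with ``lo_nm <= wavelength <= hi_nm`` (both inclusive)."""
    idx = grid.band_indices(lo_nm, hi_nm)
    band_set = BandSet(tuple(float(grid.wavelength(int(b))) for b in idx))
    return np.asarray(spectra, dtype=np.float64)[..., idx], band_set


@dataclass
class HistogramSummary:
    """Per-wavelength, per-class transmittance densities plus pairwise overlaps.

    ``density`` is a long-format table (wavelength_nm, label, bin_left,
    bin_right, density); ``overlaps`` maps ``(wavelength, label_a, label_b)``
    to the overlap coefficient -- the integrated minimum of the two
    normalized histograms, 1 for identical distributions, 0 for disjoint
    support.  Low overlap at a wavelength marks it as discriminative.
    """

    density: pd.DataFrame
    overlaps: dict[tuple[float, str, str], float]

    def overlap(self, wavelength_nm: float, a: str, b: str) -> float:
        key = (wavelength_nm, *sorted((a, b)))
        return self.overlaps[key]


def band_class_histograms(spectra: np.ndarray, labels: Sequence[str],
                          grid: WavelengthGrid, wavelengths: Sequence[float],
                          bins: int = 50) -> HistogramSummary:
    """Class-wise transmittance histograms at selected wavelengths.

    Supports the discriminative-band argument: wavelengths where the class
    densities barely overlap carry class information; wavelengths where they
    coincide do not.  Classes with fewer than 2 spectra are omitted with a
    warning.
    """
    spectra = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    labels = np.asarray(labels)
    if spectra.shape[0] == 0:
        raise ValidationError("empty spectrum table")
    if spectra.shape[0] != labels.shape[0]:
        raise ValidationError("spectra / labels length mismatch")

    classes = []
    for lab in dict.fromkeys(labels.tolist()):  # preserve first-seen order
        if (labels == lab).sum() < 2:
            warnings.warn(f"class {lab!r} has < 2 spectra; omitted from histograms")
            continue
        classes.append(lab)
    if not classes:
        raise ValidationError("no class has >= 2 spectra")

    rows = []
    overlaps: dict[tuple[float, str, str], float] = {}
    for lam in wavelengths:
        band = grid.nearest_band(float(lam))
        values = {c: spectra[labels == c, band] for c in classes}
        pooled = np.concatenate(list(values.values()))
        lo, hi = float(pooled.min()), float(pooled.max())
        if hi <= lo:
            hi = lo + 1e-12
        edges = np.linspace(lo, hi, bins + 1)
        width = edges[1] - edges[0]
        dens = {}
        for c in classes:
            d, _ = np.histogram(values[c], bins=edges, density=True)
            dens[c] = d
            for left, right, dd in zip(edges[:-1], edges[1:], d):
                rows.append((float(lam), c, float(left), float(right), float(dd)))
        for i, a in enumerate(classes):
            for b in classes[i + 1:]:
                key = (float(lam), *sorted((a, b)))
                overlaps[key] = float(np.minimum(dens[a], dens[b]).sum() * width)
    density = pd.DataFrame(rows, columns=["wavelength_nm", "label",
                                          "bin_left", "bin_right", "density"])
    return HistogramSummary(density, overlaps)


def preprocess_spectra(spectra: np.ndarray, grid: WavelengthGrid,
                       config: PreprocessConfig) -> tuple[np.ndarray, BandSet, np.ndarray]:
    """Full fixed-order pipeline: smooth, optional SNV, band selection.

    Returns ``(processed, band_set, valid_mask)`` where ``valid_mask`` marks
    input rows that survived (SNV can drop zero-variance spectra).
    """
    logger.info("preprocess order: %s (sigma=%s, snv=%s, window=%s-%s nm)",
                config.order, config.gaussian_sigma, config.snv_enabled,
                config.analysis_lo_nm, config.analysis_hi_nm)
    smoothed = gaussian_smooth(spectra, config.gaussian_sigma)
    if config.snv_enabled:
        smoothed, valid = snv(smoothed)
    else:
        valid = np.ones(np.atleast_2d(smoothed).shape[0], dtype=bool)
    selected, band_set = select_bands(smoothed, grid,
                                      config.analysis_lo_nm, config.analysis_hi_nm)
    return selected, band_set, valid
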