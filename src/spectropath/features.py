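"""The eight band-ratio/band-mean spectral features and the 3-channel RGB variant.

The discriminative window is 560-675 nm.  Two six-band sets are paired
index-wise in ascending order:

* k-set: 560, 565, 570, 575, 580, 585 nm (eosin flank)
* i-set: 650, 655, 660, 665, 670, 675 nm (hematoxylin flank)

giving six ratios ``E_j = S(k_j) / S(i_j)`` (E1 = S560/S650 ... E6 =
S585/S675) plus the two window means E7 = mean(S over k-set) and
E8 = mean(S over i-set).  The ratios are invariant to any per-pixel or
per-slide intensity gain, which is what makes them robust to staining and
illumination variability; E7/E8 keep the absolute transmittance level.

The RGB-3 variant uses the three synthetic-RGB channel means (R, G, B) as
features instead, for the baseline comparison.
"""

from __future__ import annotations

import logging
from typing import Union

import numpy as np
import pandas as pd

from .annotation import SpectrumTable
from .cube_io import RGB_CHANNEL_RANGES_NM, BandSet, Hypercube, WavelengthGrid
from .errors import ConfigurationError, RangeError, ValidationError
from .preprocess import PreprocessConfig, gaussian_smooth, snv

logger = logging.getLogger(__name__)

#: denominator guard for the band ratios
RATIO_EPS = 1e-12

K_RANGE_NM = (560.0, 585.0)
I_RANGE_NM = (650.0, 675.0)

HSI_FEATURES = ("E1", "E2", "E3", "E4", "E5", "E6", "E7", "E8")
RGB_FEATURES = ("R", "G", "B")


def default_band_sets(grid: WavelengthGrid) -> tuple[BandSet, BandSet]:
    """The k-set (560-585 nm) and i-set (650-675 nm) on ``grid``."""
    return (BandSet.from_range(grid, *K_RANGE_NM),
            BandSet.from_range(grid, *I_RANGE_NM))


def ratio_features(spectrum: np.ndarray, grid: WavelengthGrid,
                   k_set: BandSet | None = None,
                   i_set: BandSet | None = None) -> np.ndarray:
    """E1..E6 for one smoothed transmittance spectrum."""
    if k_set is None or i_set is None:
        k_set, i_set = default_band_sets(grid)
    if k_set.n != i_set.n:
        raise ValidationError("k-set and i-set must pair one-to-one")
    spectrum = np.asarray(spectrum, dtype=np.float64)
    num = spectrum[k_set.indices(grid)]
    den = spectrum[i_set.indices(grid)]
    if np.any(den <= RATIO_EPS):
        raise ValidationError("ratio denominator <= eps; pixel is invalid")
    return num / den


def mean_features(spectrum: np.ndarray, grid: WavelengthGrid,
                  k_set: BandSet | None = None,
                  i_set: BandSet | None = None) -> tuple[float, float]:
    """E7 (mean over k-set) and E8 (mean over i-set)."""
    if k_set is None or i_set is None:
        k_set, i_set = default_band_sets(grid)
    spectrum = np.asarray(spectrum, dtype=np.float64)
    return (float(spectrum[k_set.indices(grid)].mean()),
            float(spectrum[i_set.indices(grid)].mean()))


def _hsi8_matrix(spectra: np.ndarray, grid: WavelengthGrid) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized E1..E8 for an ``(n, bands)`` block; returns (features, valid)."""
    k_set, i_set = default_band_sets(grid)
    ki = k_set.indices(grid)
    ii = i_set.indices(grid)
    num = spectra[:, ki]
    den = spectra[:, ii]
    valid = np.all(den > RATIO_EPS, axis=1)
    ratios = np.divide(num, den, out=np.ones_like(num), where=den > RATIO_EPS)
    feats = np.column_stack([ratios,
                             spectra[:, ki].mean(axis=1),
                             spectra[:, ii].mean(axis=1)])
    valid &= np.all(np.isfinite(feats), axis=1)
    return feats, valid


def _rgb3_matrix(spectra: np.ndarray, grid: WavelengthGrid) -> tuple[np.ndarray, np.ndarray]:
    if grid.start_nm > 530.0 or grid.stop_nm < 725.0:
        raise RangeError("RGB features need the 530-725 nm window")
    cols = []
    for name in RGB_FEATURES:
        lo, hi = RGB_CHANNEL_RANGES_NM[name]
        idx = grid.band_indices(lo, hi)
        cols.append(spectra[:, idx].mean(axis=1))
    feats = np.column_stack(cols)
    return feats, np.all(np.isfinite(feats), axis=1)


def extract_features(data: Union[Hypercube, SpectrumTable],
                     config: PreprocessConfig | None = None,
                     variant: str = "hsi8") -> pd.DataFrame:
    """Per-pixel feature table for a cube or an annotated spectrum table.

    Preprocessing (Gaussian smoothing, optionally SNV when
    ``config.snv_enabled``) is applied here; features are computed on the
    smoothed transmittance by default.  Rows follow deterministic order:
    row-major pixel order for cubes (with ``y``/``x`` columns), input row
    order for tables (with ``patient_id``/``label`` columns).  Invalid
    pixels (non-positive ratio denominators, non-finite features,
    zero-variance spectra under SNV) are excluded; the count is logged and
    stored in ``df.attrs["n_excluded"]``.
    """
    config = config or PreprocessConfig()
    if variant not in ("hsi8", "rgb3"):
        raise ConfigurationError(f"unknown feature variant {variant!r}")

    if isinstance(data, Hypercube):
        grid = data.grid
        spectra = data.pixel_spectra()
        h, w, _ = data.shape
        yy, xx = np.divmod(np.arange(h * w), w)
        index = pd.DataFrame({"y": yy, "x": xx})
    elif isinstance(data, SpectrumTable):
        grid = data.grid
        spectra = data.spectra
        index = pd.DataFrame({"patient_id": data.patient_ids.astype(str),
                              "label": data.labels.astype(str)})
    else:
        raise ConfigurationError(f"unsupported input type {type(data).__name__}")

    smoothed = gaussian_smooth(spectra, config.gaussian_sigma)
    pre_valid = np.ones(smoothed.shape[0], dtype=bool)
    if config.snv_enabled:
        normalized, pre_valid = snv(smoothed)
        work = np.zeros_like(smoothed)
        work[pre_valid] = normalized
    else:
        work = smoothed

    if variant == "hsi8":
        feats, valid = _hsi8_matrix(work, grid)
        columns = list(HSI_FEATURES)
    else:
        feats, valid = _rgb3_matrix(work, grid)
        columns = list(RGB_FEATURES)
    valid &= pre_valid

    df = pd.concat([index, pd.DataFrame(feats, columns=columns)], axis=1)
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("extract_features: excluded %d invalid pixels (%s)",
                    n_excluded, variant)
    df = df.loc[valid].reset_index(drop=True)
    df.attrs["n_excluded"] = n_excluded
    df.attrs["variant"] = variant
    return df
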