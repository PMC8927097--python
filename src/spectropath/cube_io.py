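"""Hyperspectral cube container, calibration and spectral bookkeeping.

A transmission-microscopy hypercube is a ``(height, width, n_bands)`` array of
dimensionless transmittance values on a uniform wavelength grid (here 100
bands, 500-995 nm in 5 nm steps).  This module owns the wavelength
arithmetic (band <-> nm), the white/dark two-point calibration, spectral
cropping to the usable 500-750 nm window, and the synthetic-RGB preview
reconstructed from three broadband channel means.

Two on-disk dialects are supported:

* ``hsic`` -- a single-file container: magic bytes, a JSON header (shape,
  grid, patient id, free-form meta) and the raw C-order float64 payload.
  Writes are byte-deterministic, so identical cubes produce identical files.
* ``envi`` -- a minimal ENVI-style text header (``.hdr``) plus a
  band-sequential float64 binary, for interoperability with generic
  hyperspectral tools.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np

from .errors import CalibrationError, FormatError, RangeError, ValidationError

logger = logging.getLogger(__name__)

_MAGIC = b"HSIC\x01\n"

# Synthetic-RGB channel windows (nm, inclusive).  The camera starts at
# 500 nm, so the blue channel is built from 530-560 nm rather than true blue.
RGB_CHANNEL_RANGES_NM = {"R": (585.0, 725.0), "G": (540.0, 590.0), "B": (530.0, 560.0)}


# ---------------------------------------------------------------------------
# Wavelength grid
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength axis: band ``b`` sits at ``start_nm + b * step_nm``."""

    start_nm: float = 500.0
    step_nm: float = 5.0
    n_bands: int = 100

    def __post_init__(self) -> None:
        if self.step_nm <= 0 or self.n_bands <= 0:
            raise ValidationError("wavelength grid needs step_nm > 0 and n_bands > 0")

    @property
    def stop_nm(self) -> float:
        """Wavelength of the last band (inclusive)."""
        return self.start_nm + (self.n_bands - 1) * self.step_nm

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    def wavelength(self, band: int) -> float:
        if not 0 <= band < self.n_bands:
            raise RangeError(f"band {band} outside [0, {self.n_bands})")
        return self.start_nm + band * self.step_nm

    def nearest_band(self, wavelength_nm: float) -> int:
        """Nearest band index; exact on-grid values map exactly, ties round down."""
        if wavelength_nm < self.start_nm - self.step_nm / 2 or wavelength_nm > self.stop_nm + self.step_nm / 2:
            raise RangeError(f"{wavelength_nm} nm outside grid span "
                             f"[{self.start_nm}, {self.stop_nm}] nm")
        pos = (wavelength_nm - self.start_nm) / self.step_nm
        band = math.ceil(pos - 0.5)  # ties toward the lower band
        return int(min(max(band, 0), self.n_bands - 1))

    def band_indices(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of all bands with ``lo_nm <= wavelength <= hi_nm`` (inclusive)."""
        if lo_nm > hi_nm:
            raise RangeError(f"lo {lo_nm} > hi {hi_nm}")
        lam = self.wavelengths
        eps = 1e-9 * self.step_nm
        idx = np.nonzero((lam >= lo_nm - eps) & (lam <= hi_nm + eps))[0]
        if idx.size == 0:
            raise RangeError(f"no bands in [{lo_nm}, {hi_nm}] nm on grid "
                             f"{self.start_nm}..{self.stop_nm} step {self.step_nm}")
        return idx

    def to_dict(self) -> dict[str, Any]:
        return {"start_nm": self.start_nm, "step_nm": self.step_nm, "n_bands": self.n_bands}


@dataclass(frozen=True)
class BandSet:
    """An ordered set of on-grid wavelengths, e.g. the six 560-585 nm bands."""

    wavelengths: tuple[float, ...]

    @property
    def n(self) -> int:
        return len(self.wavelengths)

    @classmethod
    def from_range(cls, grid: WavelengthGrid, lo_nm: float, hi_nm: float) -> "BandSet":
        idx = grid.band_indices(lo_nm, hi_nm)
        return cls(tuple(float(grid.wavelength(int(b))) for b in idx))

    def indices(self, grid: WavelengthGrid) -> np.ndarray:
        return np.array([grid.nearest_band(w) for w in self.wavelengths], dtype=int)


# ---------------------------------------------------------------------------
# Hypercube
# ---------------------------------------------------------------------------

@dataclass
class Hypercube:
    """A ``(height, width, n_bands)`` transmittance array with its wavelength grid.

    Transmittance is dimensionless and non-negative; values above 1 are
    permitted (calibration noise) and only the lower bound is clipped, so the
    noise statistics that standard-normal-variate normalization relies on are
    preserved.
    """

    values: np.ndarray
    grid: WavelengthGrid
    patient_id: str = ""
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.values.ndim != 3:
            raise ValidationError(f"cube must be 3-D, got ndim={self.values.ndim}")
        h, w, b = self.values.shape
        if h <= 0 or w <= 0:
            raise ValidationError("spatial dimensions must be positive")
        if b != self.grid.n_bands:
            raise FormatError(f"cube has {b} bands but grid declares {self.grid.n_bands}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("cube contains non-finite values")
        if np.any(self.values < 0):
            raise ValidationError("transmittance must be non-negative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def pixel_spectra(self) -> np.ndarray:
        """Row-major ``(height * width, n_bands)`` view of the pixel spectra."""
        h, w, b = self.values.shape
        return self.values.reshape(h * w, b)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def _infer_dialect(path: str) -> str:
    return "envi" if str(path).endswith(".hdr") else "hsic"


def write_cube(cube: Hypercube, path: str, dialect: str | None = None) -> None:
    """Write a cube losslessly; ``dialect`` is inferred from the extension."""
    cube.validate()
    dialect = dialect or _infer_dialect(path)
    if dialect == "hsic":
        _write_hsic(cube, path)
    elif dialect == "envi":
        _write_envi(cube, path)
    else:
        raise FormatError(f"unknown dialect {dialect!r}")


def read_cube(path: str, dialect: str | None = None) -> Hypercube:
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    dialect = dialect or _infer_dialect(path)
    if dialect == "hsic":
        return _read_hsic(path)
    if dialect == "envi":
        return _read_envi(path)
    raise FormatError(f"unknown dialect {dialect!r}")


def _write_hsic(cube: Hypercube, path: str) -> None:
    header = {
        "shape": list(cube.values.shape),
        "dtype": "<f8",
        "grid": cube.grid.to_dict(),
        "patient_id": cube.patient_id,
        "meta": cube.meta,
    }
    blob = json.dumps(header, sort_keys=True, separators=(",", ":")).encode()
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(len(blob).to_bytes(8, "little"))
        fh.write(blob)
        fh.write(np.ascontiguousarray(cube.values, dtype="<f8").tobytes())


def _read_hsic(path: str) -> Hypercube:
    with open(path, "rb") as fh:
        magic = fh.read(len(_MAGIC))
        if magic != _MAGIC:
            raise FormatError(f"{path}: not an hsic container")
        n = int.from_bytes(fh.read(8), "little")
        try:
            header = json.loads(fh.read(n))
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: corrupt header") from exc
        for key in ("shape", "grid"):
            if key not in header:
                raise FormatError(f"{path}: header missing {key!r}")
        shape = tuple(header["shape"])
        grid = WavelengthGrid(**header["grid"])
        if len(shape) != 3 or shape[2] != grid.n_bands:
            raise FormatError(f"{path}: shape {shape} inconsistent with grid "
                              f"n_bands={grid.n_bands}")
        payload = fh.read()
    values = np.frombuffer(payload, dtype="<f8")
    if values.size != int(np.prod(shape)):
        raise FormatError(f"{path}: payload has {values.size} values, "
                          f"expected {int(np.prod(shape))}")
    values = values.reshape(shape).copy()
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: non-finite values in payload")
    return Hypercube(values, grid, header.get("patient_id", ""), header.get("meta", {}))


def _write_envi(cube: Hypercube, hdr_path: str) -> None:
    if not hdr_path.endswith(".hdr"):
        raise FormatError("ENVI dialect expects a .hdr path")
    raw_path = hdr_path[:-4] + ".raw"
    h, w, b = cube.values.shape
    lam = ", ".join(f"{x:g}" for x in cube.grid.wavelengths)
    lines = [
        "ENVI",
        f"description = {{spectropath cube, patient {cube.patient_id}}}",
        f"samples = {w}",
        f"lines = {h}",
        f"bands = {b}",
        "header offset = 0",
        "file type = ENVI Standard",
        "data type = 5",          # IEEE 64-bit float
        "interleave = bsq",
        "byte order = 0",
        f"wavelength units = Nanometers",
        f"wavelength = {{{lam}}}",
    ]
    with open(hdr_path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    # band-sequential: (bands, lines, samples) on disk
    bsq = np.ascontiguousarray(np.moveaxis(cube.values, 2, 0), dtype="<f8")
    with open(raw_path, "wb") as fh:
        fh.write(bsq.tobytes())


def _parse_envi_header(text: str) -> dict[str, str]:
    fields: dict[str, str] = {}
    key = None
    buf = ""
    for line in text.splitlines():
        if key is None:
            if "=" not in line:
                continue
            key, _, val = line.partition("=")
            key, buf = key.strip().lower(), val.strip()
            if buf.startswith("{") and not buf.endswith("}"):
                continue  # multi-line value
        else:
            buf += " " + line.strip()
        if not buf.startswith("{") or buf.endswith("}"):
            fields[key] = buf.strip("{} ")
            key, buf = None, ""
    return fields


def _read_envi(hdr_path: str) -> Hypercube:
    with open(hdr_path) as fh:
        fields = _parse_envi_header(fh.read())
    try:
        w = int(fields["samples"])
        h = int(fields["lines"])
        b = int(fields["bands"])
    except KeyError as exc:
        raise FormatError(f"{hdr_path}: missing {exc.args[0]!r}") from exc
    if fields.get("data type", "5") != "5":
        raise FormatError(f"{hdr_path}: only data type 5 (float64) supported")
    lam = np.array([float(x) for x in fields["wavelength"].split(",")])
    if lam.size != b:
        raise FormatError(f"{hdr_path}: {lam.size} wavelengths for {b} bands")
    steps = np.diff(lam)
    if lam.size > 1 and not np.allclose(steps, steps[0]):
        raise FormatError(f"{hdr_path}: non-uniform wavelength grid")
    grid = WavelengthGrid(float(lam[0]), float(steps[0]) if lam.size > 1 else 5.0, b)
    raw_path = hdr_path[:-4] + ".raw"
    data = np.fromfile(raw_path, dtype="<f8")
    if data.size != h * w * b:
        raise FormatError(f"{raw_path}: size mismatch")
    values = np.moveaxis(data.reshape(b, h, w), 0, 2).copy()
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{raw_path}: non-finite values")
    desc = fields.get("description", "")
    patient = ""
    if "patient " in desc:
        patient = desc.split("patient ", 1)[1].strip()
    return Hypercube(values, grid, patient)


# ---------------------------------------------------------------------------
# Calibration / cropping / RGB synthesis
# ---------------------------------------------------------------------------

def calibrate(raw: np.ndarray, white: np.ndarray, dark: np.ndarray,
              grid: WavelengthGrid | None = None, patient_id: str = "") -> Hypercube:
    """Two-point white/dark balancing: ``T = (raw - dark) / (white - dark)``.

    ``white`` and ``dark`` may be full cubes or per-band references (1-D,
    broadcast over the spatial axes).  T is clipped below at 0 but not above.
    Bands where ``white == dark`` everywhere are flagged in ``meta`` and set
    to 0; if white <= dark on more than 10% of entries the references are
    rejected outright.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.ndim != 3:
        raise ValidationError("raw must be a 3-D (h, w, bands) array")

    def _expand(ref: np.ndarray) -> np.ndarray:
        ref = np.asarray(ref, dtype=np.float64)
        if ref.ndim == 1:
            ref = ref[np.newaxis, np.newaxis, :]
        return np.broadcast_to(ref, raw.shape)

    white_b, dark_b = _expand(white), _expand(dark)
    bad = white_b <= dark_b
    if bad.mean() > 0.10:
        raise CalibrationError(
            f"white <= dark on {bad.mean():.1%} of entries (limit 10%)")
    denom = white_b - dark_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, (raw - dark_b) / np.where(denom > 0, denom, 1.0), 0.0)
    t = np.clip(t, 0.0, None)
    grid = grid or WavelengthGrid(n_bands=raw.shape[2])
    invalid_bands = [int(b) for b in range(raw.shape[2]) if np.all(bad[:, :, b])]
    if invalid_bands:
        logger.warning("calibrate: %d bands flagged invalid (white == dark)",
                       len(invalid_bands))
    return Hypercube(t, grid, patient_id, meta={"invalid_bands": invalid_bands})


def crop_spectral(cube: Hypercube, lo_nm: float, hi_nm: float) -> Hypercube:
    """Restrict the cube to bands with ``lo_nm <= wavelength <= hi_nm`` (inclusive)."""
    if lo_nm >= hi_nm:
        raise RangeError(f"lo {lo_nm} must be < hi {hi_nm}")
    try:
        idx = cube.grid.band_indices(lo_nm, hi_nm)
    except RangeError:
        raise RangeError(f"crop [{lo_nm}, {hi_nm}] nm selects no bands") from None
    new_grid = replace(cube.grid,
                       start_nm=float(cube.grid.wavelength(int(idx[0]))),
                       n_bands=int(idx.size))
    return Hypercube(cube.values[:, :, idx[0]:idx[-1] + 1].copy(), new_grid,
                     cube.patient_id, dict(cube.meta))


def synthesize_rgb(cube: Hypercube, rescale: bool = False) -> np.ndarray:
    """Reconstruct an ``(h, w, 3)`` synthetic-RGB image from channel band means.

    Channels are the per-pixel mean transmittance over R = 585-725 nm,
    G = 540-590 nm, B = 530-560 nm (all inclusive), returned in (R, G, B)
    order.  With ``rescale=True`` the image is min-max scaled to [0, 1] for
    display; the default preserves physical transmittance units.
    """
    if cube.grid.start_nm > 530.0 or cube.grid.stop_nm < 725.0:
        raise RangeError(f"cube spans {cube.grid.start_nm}-{cube.grid.stop_nm} nm; "
                         "synthetic RGB needs 530-725 nm")
    channels = []
    for name in ("R", "G", "B"):
        lo, hi = RGB_CHANNEL_RANGES_NM[name]
        idx = cube.grid.band_indices(lo, hi)
        channels.append(cube.values[:, :, idx].mean(axis=2))
    img = np.stack(channels, axis=2)
    if rescale:
        rng = img.max() - img.min()
        img = (img - img.min()) / (rng if rng > 0 else 1.0)
    return img


def write_rgb_png(image: np.ndarray, path: str) -> None:
    """Export an RGB preview as 8-bit PNG after min-max display rescaling."""
    import imageio.v3 as iio

    img = np.asarray(image, dtype=np.float64)
    rng = img.max() - img.min()
    scaled = (img - img.min()) / (rng if rng > 0 else 1.0)
    iio.imwrite(path, (scaled * 255).round().astype(np.uint8))
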