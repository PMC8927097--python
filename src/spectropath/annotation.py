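"""Circular ROI annotations, labeled spectrum extraction, class taxonomy.

Four tissue classes are annotated on the specimen previews: squamous
epithelium, adenocarcinoma (EAC) cells, tumor stroma, and blank/background.
For classification the EAC and stroma classes are merged into a single
"tumor" class -- their cell structure and staining are too similar to keep
apart -- leaving the 3-class taxonomy (tumor, squamous, background) that the
classifiers operate on, always in that fixed order.

Coordinate convention: images are row-major with origin top-left; pixel
coordinates are 0-based integers; a disc annotation covers every integer
pixel center within ``radius`` (Euclidean, inclusive) of its center.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cube_io import Hypercube, WavelengthGrid
from .errors import ValidationError

logger = logging.getLogger(__name__)

SQUAMOUS = "squamous"
EAC = "eac"
STROMA = "stroma"
BACKGROUND = "background"
TUMOR = "tumor"
UNCLASSIFIED = "unclassified"

#: annotation taxonomy (pre-merge)
CLASSES_4 = (SQUAMOUS, EAC, STROMA, BACKGROUND)
#: classification taxonomy (post-merge), fixed model/class order
CLASSES_3 = (TUMOR, SQUAMOUS, BACKGROUND)

#: EAC and stroma collapse to tumor; already-merged labels pass through,
#: so merging is idempotent.
MERGE_MAP = {EAC: TUMOR, STROMA: TUMOR, SQUAMOUS: SQUAMOUS,
             BACKGROUND: BACKGROUND, TUMOR: TUMOR}

NEOADJUVANT_LEVELS = ("CTx", "RCTx", "none")
T_LEVELS = ("T1", "T2", "T3", "T4")
N_LEVELS = ("N0", "N+")
M_LEVELS = ("M0", "M+")
G_LEVELS = ("G1", "G2", "G3", "n.a.")


def merged_label(label: str) -> str:
    try:
        return MERGE_MAP[label]
    except KeyError:
        raise ValidationError(f"unknown class label {label!r}") from None


@dataclass(frozen=True)
class AnnotationROI:
    """Circular region of interest carrying a class label and patient id."""

    center_x: float
    center_y: float
    radius: float
    label: str
    patient_id: str

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValidationError("ROI radius must be > 0")
        if self.label not in MERGE_MAP:
            raise ValidationError(f"unknown class label {self.label!r}")


@dataclass(frozen=True)
class PatientRecord:
    """Clinico-pathological metadata for one patient."""

    patient_id: str
    neoadjuvant: str = "none"      # CTx / RCTx / none
    T: str = "T1"
    N: str = "N0"
    M: str = "M0"
    G: str = "n.a."

    def __post_init__(self) -> None:
        for value, levels, name in ((self.neoadjuvant, NEOADJUVANT_LEVELS, "neoadjuvant"),
                                    (self.T, T_LEVELS, "T"), (self.N, N_LEVELS, "N"),
                                    (self.M, M_LEVELS, "M"), (self.G, G_LEVELS, "G")):
            if value not in levels:
                raise ValidationError(f"{name}={value!r} not in {levels}")


def roi_pixels(roi: AnnotationROI, height: int, width: int) -> list[tuple[int, int]]:
    """Integer pixels ``(y, x)`` inside the disc, clipped to image bounds.

    Membership is Euclidean distance from the center <= radius, evaluated at
    integer pixel centers; output is deterministic row-major order.  A disc
    entirely outside the image yields an empty list with a warning.
    """
    if height <= 0 or width <= 0:
        raise ValidationError("image dimensions must be positive")
    y_lo = max(0, int(np.ceil(roi.center_y - roi.radius)))
    y_hi = min(height - 1, int(np.floor(roi.center_y + roi.radius)))
    x_lo = max(0, int(np.ceil(roi.center_x - roi.radius)))
    x_hi = min(width - 1, int(np.floor(roi.center_x + roi.radius)))
    out: list[tuple[int, int]] = []
    r2 = roi.radius ** 2
    for y in range(y_lo, y_hi + 1):
        dy2 = (y - roi.center_y) ** 2
        for x in range(x_lo, x_hi + 1):
            if dy2 + (x - roi.center_x) ** 2 <= r2:
                out.append((y, x))
    if not out:
        warnings.warn(f"ROI at ({roi.center_x}, {roi.center_y}) r={roi.radius} "
                      f"lies outside the {height}x{width} image")
    return out


@dataclass
class SpectrumTable:
    """Flat table of labeled pixel spectra -- the unit of training/evaluation.

    ``spectra`` is ``(n_rows, n_bands)`` over ``grid``; ``labels`` and
    ``patient_ids`` are parallel string arrays; ``patients`` links every
    patient id to its :class:`PatientRecord`.
    """

    spectra: np.ndarray
    labels: np.ndarray
    patient_ids: np.ndarray
    grid: WavelengthGrid
    patients: dict[str, PatientRecord] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        self.patient_ids = np.asarray(self.patient_ids, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = self.spectra.shape[0]
        if self.spectra.ndim != 2 or self.spectra.shape[1] != self.grid.n_bands:
            raise ValidationError("spectra must be (n, grid.n_bands)")
        if self.labels.shape[0] != n or self.patient_ids.shape[0] != n:
            raise ValidationError("labels/patient_ids length mismatch")
        unknown = set(self.patient_ids.tolist()) - set(self.patients)
        if unknown:
            raise ValidationError(f"rows reference patients without records: {sorted(unknown)}")
        bad = set(self.labels.tolist()) - set(MERGE_MAP)
        if bad:
            raise ValidationError(f"unknown labels: {sorted(bad)}")

    def __len__(self) -> int:
        return int(self.spectra.shape[0])

    def class_counts(self) -> dict[str, int]:
        labs, counts = np.unique(self.labels.astype(str), return_counts=True)
        return dict(zip(labs.tolist(), counts.tolist()))

    def subset(self, mask: np.ndarray) -> "SpectrumTable":
        return SpectrumTable(self.spectra[mask], self.labels[mask],
                             self.patient_ids[mask], self.grid, dict(self.patients))

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.spectra,
                          columns=[f"{w:g}nm" for w in self.grid.wavelengths])
        df.insert(0, "label", self.labels.astype(str))
        df.insert(0, "patient_id", self.patient_ids.astype(str))
        return df


def extract_spectra(cubes: Sequence[Hypercube] | Mapping[str, Hypercube],
                    rois: Iterable[AnnotationROI],
                    patients: Mapping[str, PatientRecord]) -> SpectrumTable:
    """Pull one table row per in-bounds annotated pixel.

    Same-label overlapping discs contribute their pixel union (no
    duplicates); pixels claimed by discs of *different* labels are label
    conflicts -- excluded and logged rather than resolved by any priority
    rule.  An ROI whose patient has no cube raises a lookup error.
    """
    if not isinstance(cubes, Mapping):
        cube_map = {}
        for c in cubes:
            if c.patient_id in cube_map:
                raise ValidationError(f"duplicate cube for patient {c.patient_id!r}")
            cube_map[c.patient_id] = c
    else:
        cube_map = dict(cubes)

    per_cube: dict[str, dict[tuple[int, int], str]] = {pid: {} for pid in cube_map}
    n_conflicts = 0
    for roi in rois:
        if roi.patient_id not in cube_map:
            raise KeyError(f"ROI references unknown patient {roi.patient_id!r}")
        cube = cube_map[roi.patient_id]
        h, w, _ = cube.shape
        assignment = per_cube[roi.patient_id]
        for pix in roi_pixels(roi, h, w):
            prev = assignment.get(pix)
            if prev is None:
                assignment[pix] = roi.label
            elif prev != roi.label and prev != "__conflict__":
                assignment[pix] = "__conflict__"
                n_conflicts += 1
    if n_conflicts:
        logger.warning("extract_spectra: excluded %d label-conflict pixels", n_conflicts)

    spectra_rows, labels, pids = [], [], []
    grid = None
    for pid in cube_map:
        cube = cube_map[pid]
        grid = cube.grid if grid is None else grid
        if cube.grid != grid:
            raise ValidationError("all cubes must share one wavelength grid")
        for (y, x) in sorted(per_cube[pid]):  # row-major within each cube
            lab = per_cube[pid][(y, x)]
            if lab == "__conflict__":
                continue
            spectra_rows.append(cube.values[y, x, :])
            labels.append(lab)
            pids.append(pid)
    if grid is None:
        raise ValidationError("no cubes supplied")
    spectra = np.array(spectra_rows, dtype=np.float64) if spectra_rows else \
        np.empty((0, grid.n_bands))
    missing = set(pids) - set(patients)
    if missing:
        raise KeyError(f"no PatientRecord for {sorted(missing)}")
    used = {pid: patients[pid] for pid in set(pids)}
    return SpectrumTable(spectra, np.array(labels, dtype=object),
                         np.array(pids, dtype=object), grid, used)


def merge_classes(table: SpectrumTable) -> SpectrumTable:
    """Map EAC/stroma to tumor; row count unchanged; idempotent."""
    merged = np.array([merged_label(str(l)) for l in table.labels], dtype=object)
    return SpectrumTable(table.spectra.copy(), merged, table.patient_ids.copy(),
                         table.grid, dict(table.patients))


# ---------------------------------------------------------------------------
# CSV / container interchange
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = ["patient_id", "cube_file", "center_x", "center_y", "radius", "label"]


def write_annotations(rois: Sequence[AnnotationROI], path: str,
                      cube_files: Mapping[str, str] | None = None) -> None:
    rows = [{"patient_id": r.patient_id,
             "cube_file": (cube_files or {}).get(r.patient_id, ""),
             "center_x": r.center_x, "center_y": r.center_y,
             "radius": r.radius, "label": r.label} for r in rois]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(path, index=False)


def read_annotations(path: str) -> list[AnnotationROI]:
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [AnnotationROI(float(r.center_x), float(r.center_y), float(r.radius),
                          str(r.label), str(r.patient_id))
            for r in df.itertuples()]


def write_patients(patients: Mapping[str, PatientRecord], path: str) -> None:
    rows = [asdict(p) for p in patients.values()]
    pd.DataFrame(rows, columns=["patient_id", "neoadjuvant", "T", "N", "M", "G"]) \
        .to_csv(path, index=False)


def read_patients(path: str) -> dict[str, PatientRecord]:
    df = pd.read_csv(path, keep_default_na=False)
    out = {}
    for r in df.itertuples():
        rec = PatientRecord(str(r.patient_id), str(r.neoadjuvant),
                            str(r.T), str(r.N), str(r.M), str(r.G))
        out[rec.patient_id] = rec
    return out


def save_table(table: SpectrumTable, path: str) -> None:
    """Persist a spectrum table as a single .npz container."""
    np.savez(path,
             spectra=table.spectra,
             labels=table.labels.astype(str),
             patient_ids=table.patient_ids.astype(str),
             grid=json.dumps(table.grid.to_dict()),
             patients=json.dumps({k: asdict(v) for k, v in table.patients.items()}))


def load_table(path: str) -> SpectrumTable:
    with np.load(path, allow_pickle=False) as z:
        grid = WavelengthGrid(**json.loads(str(z["grid"])))
        patients = {k: PatientRecord(**v)
                    for k, v in json.loads(str(z["patients"])).items()}
        return SpectrumTable(z["spectra"], z["labels"].astype(object),
                             z["patient_ids"].astype(object), grid, patients)
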