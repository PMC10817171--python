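"""Image, ROI and measurement-table I/O.

Domain types (:class:`Image2D`, :class:`Polygon`, :class:`MeasurementTable`)
live here together with the readers/writers for the formats the pipeline
touches: single-frame DICOM, 8-bit JPEG exports, ROI coordinate files
(JSON) and two-column measurement tables (csv/xlsx).

Coordinate convention (used throughout the toolkit): 0-based indices,
``x`` = column (horizontal, positive right), ``y`` = row (vertical,
positive down).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image as PILImage

from qt1seg import _dicomlite
from qt1seg.exceptions import FormatError, ValidationError

logger = logging.getLogger(__name__)

MODALITY_IR = "IR"
MODALITY_SPGR = "SPGR"
MODALITY_OTHER = "other"


@dataclass
class Image2D:
    """One MR slice: a pixel matrix plus the acquisition parameters.

    Attributes
    ----------
    pixels : float64 array, shape (rows, cols), signal units
    pixel_spacing : pixel size in mm (isotropic)
    tr, te, fa, ti : acquisition parameters in ms / degrees; ``None`` if absent
    modality : "IR", "SPGR" or "other"
    """

    pixels: np.ndarray
    pixel_spacing: float = 1.0
    tr: Optional[float] = None
    te: Optional[float] = None
    fa: Optional[float] = None
    ti: Optional[float] = None
    modality: str = MODALITY_OTHER

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or min(self.pixels.shape) < 1:
            raise ValidationError("pixels must be a non-empty 2D matrix")
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("pixel values must be finite")
        if self.modality == MODALITY_SPGR and (self.tr is None or self.tr <= 0):
            raise ValidationError("SPGR images require tr > 0")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class Polygon:
    """Closed polygon with real-valued vertices (x=column, y=row)."""

    xy: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=np.float64)
        if self.xy.ndim != 2 or self.xy.shape[1] != 2:
            raise ValidationError("polygon vertices must be an (n, 2) array")
        if self.xy.shape[0] < 3:
            raise ValidationError(
                f"polygon needs >= 3 vertices, got {self.xy.shape[0]}"
            )
        if not np.all(np.isfinite(self.xy)):
            raise ValidationError("polygon vertices must be finite")

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    def check_bounds(self, shape: Tuple[int, int]) -> None:
        rows, cols = shape
        if (
            self.x.min() < -0.5
            or self.y.min() < -0.5
            or self.x.max() > cols - 0.5
            or self.y.max() > rows - 0.5
        ):
            raise ValidationError("polygon vertices fall outside the image bounds")


@dataclass
class MeasurementTable:
    """Per-subject qT1 values from two raters or two sessions."""

    subjects: list
    values: np.ndarray  # shape (n, 2), ms
    labels: Tuple[str, str] = ("first", "second")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[1] != 2:
            raise ValidationError("measurement table must have exactly 2 value columns")
        if len(self.subjects) != self.values.shape[0]:
            raise ValidationError("subject list length must match value rows")
        if np.any(~np.isfinite(self.values)):
            bad = np.nonzero(~np.isfinite(self.values).all(axis=1))[0]
            raise ValidationError(f"missing/non-finite entries in rows {bad.tolist()}")
        if np.any(self.values <= 0):
            bad = np.nonzero((self.values <= 0).any(axis=1))[0]
            raise ValidationError(f"non-positive T1 values in rows {bad.tolist()}")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def col(self, i: int) -> np.ndarray:
        return self.values[:, i]


# ---------------------------------------------------------------------------
# DICOM
# ---------------------------------------------------------------------------

def read_dicom_slice(path) -> Image2D:
    """Read a single-frame DICOM into an :class:`Image2D`.

    Rescale slope/intercept are applied; TR/TE/FA/TI come from the standard
    acquisition tags when present.  The modality tag is taken from the
    series description if it names one of the toolkit's modalities.
    """
    fields = _dicomlite.read_dicom(path)
    desc = (fields["series_description"] or "").upper()
    if desc.startswith(MODALITY_IR):
        modality = MODALITY_IR
    elif desc.startswith(MODALITY_SPGR):
        modality = MODALITY_SPGR
    else:
        modality = MODALITY_OTHER
    return Image2D(
        pixels=fields["pixels"],
        pixel_spacing=fields["pixel_spacing"],
        tr=fields["tr"],
        te=fields["te"],
        fa=fields["fa"],
        ti=fields["ti"],
        modality=modality,
    )


def write_dicom_slice(path, image: Image2D) -> None:
    """Write an :class:`Image2D` as a single-frame DICOM slice."""
    _dicomlite.write_dicom(
        path,
        image.pixels,
        pixel_spacing=image.pixel_spacing,
        tr=image.tr,
        te=image.te,
        ti=image.ti,
        fa=image.fa,
        series_description=image.modality,
    )


def dicom_to_jpeg(path_in, path_out) -> None:
    """Convert a DICOM slice to an 8-bit grayscale JPEG.

    Min-max windowed: the minimum pixel maps to 0 and the maximum to 255,
    linearly in between.  A constant image yields an all-zero JPEG and a
    logged warning.  Written at maximum quality with chroma subsampling
    disabled to minimise drift from the DICOM pixels.
    """
    image = read_dicom_slice(path_in)
    px = image.pixels
    lo, hi = float(px.min()), float(px.max())
    if hi == lo:
        logger.warning("constant image %s: JPEG output is all zero", path_in)
        out = np.zeros(px.shape, dtype=np.uint8)
    else:
        out = np.round((px - lo) / (hi - lo) * 255.0).astype(np.uint8)
    PILImage.fromarray(out, mode="L").save(path_out, format="JPEG", quality=100, subsampling=0)


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

_COLUMN_PATTERNS = (
    ("observer1", "observer2"),
    ("observer 1", "observer 2"),
    ("obs1", "obs2"),
    ("first", "second"),
    ("1st", "2nd"),
    ("session1", "session2"),
    ("session 1", "session 2"),
)

_SUBJECT_NAMES = ("subject", "subject_id", "id", "case", "volunteer")


def read_measurement_table(path) -> MeasurementTable:
    """Read a two-column qT1 table from csv or xlsx.

    Value columns are identified by header name first (observer1/observer2,
    first/second, ... variants); if no headers match, the first two numeric
    columns are used with a logged warning.
    """
    path = Path(path)
    try:
        if path.suffix.lower() in {".xlsx", ".xls"}:
            df = pd.read_excel(path)
        else:
            df = pd.read_csv(path)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValidationError(f"cannot parse measurement table {path}: {exc}") from exc
    if df.empty:
        raise ValidationError(f"measurement table {path} is empty")

    lowered = {str(c).strip().lower(): c for c in df.columns}
    col_a = col_b = None
    for pat_a, pat_b in _COLUMN_PATTERNS:
        hits_a = [orig for low, orig in lowered.items() if pat_a in low]
        hits_b = [orig for low, orig in lowered.items() if pat_b in low]
        if len(hits_a) == 1 and len(hits_b) == 1 and hits_a[0] != hits_b[0]:
            col_a, col_b = hits_a[0], hits_b[0]
            break
    if col_a is None:
        numeric = [c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
        # a numeric id column would be picked up; drop obvious subject columns
        numeric = [c for c in numeric if str(c).strip().lower() not in _SUBJECT_NAMES]
        if len(numeric) < 2:
            raise ValidationError(
                f"{path}: could not identify two numeric value columns"
            )
        col_a, col_b = numeric[0], numeric[1]
        logger.warning(
            "%s: no recognised headers, using columns %r and %r positionally",
            path, col_a, col_b,
        )

    subject_col = next(
        (orig for low, orig in lowered.items() if low in _SUBJECT_NAMES), None
    )
    subjects = (
        df[subject_col].tolist() if subject_col is not None else list(range(1, len(df) + 1))
    )
    values = df[[col_a, col_b]].to_numpy(dtype=np.float64)
    table = MeasurementTable(
        subjects=subjects, values=values, labels=(str(col_a), str(col_b))
    )
    logger.info("%s: %d subjects (%s vs %s)", path, table.n, col_a, col_b)
    return table


# ---------------------------------------------------------------------------
# ROI files
# ---------------------------------------------------------------------------

def read_roi_file(path, shape: Optional[Tuple[int, int]] = None) -> dict:
    """Read seed point and/or named polygons from a JSON ROI file.

    Schema::

        {"seed": [x, y], "polygons": {"name": [[x, y], ...], ...}}

    Coordinates are 0-based, x = column, y = row.  When ``shape`` is given,
    seed and vertices are checked against the image bounds.
    """
    with open(path) as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: ROI file must contain a JSON object")

    out: dict = {"seed": None, "polygons": {}}
    if "seed" in data and data["seed"] is not None:
        seed = data["seed"]
        if not (isinstance(seed, (list, tuple)) and len(seed) == 2):
            raise FormatError(f"{path}: seed must be a 2-element [x, y] list")
        x, y = float(seed[0]), float(seed[1])
        if shape is not None:
            rows, cols = shape
            if not (0 <= x < cols and 0 <= y < rows):
                raise ValidationError(f"{path}: seed ({x}, {y}) outside image bounds")
        out["seed"] = (x, y)
    for name, verts in (data.get("polygons") or {}).items():
        poly = Polygon(np.asarray(verts, dtype=np.float64))
        if shape is not None:
            poly.check_bounds(shape)
        out["polygons"][name] = poly
    return out


def write_roi_file(path, seed=None, polygons: Optional[Dict[str, Polygon]] = None) -> None:
    """Write seed/polygons in the ROI JSON schema (round-trips exactly)."""
    data: dict = {}
    if seed is not None:
        data["seed"] = [float(seed[0]), float(seed[1])]
    if polygons:
        data["polygons"] = {
            name: np.asarray(p.xy, dtype=np.float64).tolist() for name, p in polygons.items()
        }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def write_mask_png(path, mask: np.ndarray) -> None:
    """Write a boolean mask as an 8-bit PNG (True -> 255)."""
    arr = (np.asarray(mask, dtype=bool) * np.uint8(255))
    PILImage.fromarray(arr, mode="L").save(path, format="PNG")
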