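"""Per-pixel T1 estimation from two SPGR flip-angle images.

The two-point linearized solution: with effective flip angles
``a_i = b1 * a_i,nominal``, transform each signal to ``y_i = S_i/sin(a_i)``
and ``x_i = S_i/tan(a_i)``; the line through the two points has slope
``m = E1 = exp(-TR/T1)``, so ``T1 = -TR / ln(m)``.  Slopes outside (0, 1)
or T1 outside the validity window are marked invalid (NaN), not clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple, Union

import numpy as np

from qt1seg.exceptions import ValidationError
from qt1seg.imaging_io import MODALITY_SPGR, Image2D

logger = logging.getLogger(__name__)

T1_MIN = 1.0  # ms; fits at or below are non-physical -> invalid
T1_MAX = 10000.0  # ms
TR_MISMATCH_TOL = 0.01  # the two SPGR acquisitions must agree on TR to 1%


@dataclass
class B1Map:
    """Dimensionless multiplicative flip-angle scale factor per pixel."""

    scale: np.ndarray

    def __post_init__(self) -> None:
        self.scale = np.asarray(self.scale, dtype=np.float64)
        if self.scale.ndim != 2:
            raise ValidationError("B1 map must be 2D")
        if not np.all(np.isfinite(self.scale)) or np.any(self.scale <= 0):
            raise ValidationError("B1 scale must be finite and strictly positive")


@dataclass
class T1Map:
    """Per-pixel quantitative T1 in ms; invalid pixels are NaN."""

    t1: np.ndarray
    fa1: float
    fa2: float
    tr: float
    b1_applied: bool

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=np.float64)
        valid = np.isfinite(self.t1)
        if valid.any() and (np.any(self.t1[valid] <= 0) or np.any(self.t1[valid] > T1_MAX)):
            raise ValidationError(f"valid T1 pixels must lie in (0, {T1_MAX}]")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.t1.shape  # type: ignore[return-value]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.t1)

    @property
    def invalid_fraction(self) -> float:
        return float(np.mean(~self.valid))


def _fit_arrays(s1, s2, fa1: float, fa2: float, tr: float, b1) -> np.ndarray:
    """Vectorized two-point fit; invalid pixels become NaN."""
    s1 = np.asarray(s1, dtype=np.float64)
    s2 = np.asarray(s2, dtype=np.float64)
    a1 = np.deg2rad(fa1) * np.asarray(b1, dtype=np.float64)
    a2 = np.deg2rad(fa2) * np.asarray(b1, dtype=np.float64)
    y1, x1 = s1 / np.sin(a1), s1 / np.tan(a1)
    y2, x2 = s2 / np.sin(a2), s2 / np.tan(a2)
    denom = x2 - x1
    with np.errstate(divide="ignore", invalid="ignore"):
        m = np.where(denom != 0, (y2 - y1) / denom, np.nan)
        t1 = np.where((m > 0) & (m < 1), -tr / np.log(m), np.nan)
    t1 = np.where((t1 > T1_MIN) & (t1 <= T1_MAX), t1, np.nan)
    return t1


def fit_t1_pixel(
    s1: float, s2: float, fa1: float, fa2: float, tr: float, b1: float = 1.0
) -> float:
    """Fit T1 for a single pixel; returns NaN when the fit is invalid.

    ``s1``/``s2`` are the signals at nominal flip angles ``fa1``/``fa2``
    (degrees); ``b1`` scales both flip angles.
    """
    if fa1 == fa2:
        raise ValidationError("the two flip angles must differ")
    if tr <= 0:
        raise ValidationError("tr must be > 0")
    if b1 <= 0:
        raise ValidationError("b1 must be > 0")
    return float(_fit_arrays(s1, s2, fa1, fa2, tr, b1))


def compute_t1_map(
    spgr_lo: Image2D,
    spgr_hi: Image2D,
    b1: Optional[Union[B1Map, np.ndarray]] = None,
) -> T1Map:
    """Pixel-by-pixel T1 map from a low/high flip-angle SPGR pair.

    ``b1`` may be a :class:`B1Map`, a raw array of flip-angle scales, or
    ``None`` (equivalent to all-ones).  The fraction of invalid pixels is
    logged.
    """
    if spgr_lo.shape != spgr_hi.shape:
        raise ValidationError(
            f"SPGR shapes differ: {spgr_lo.shape} vs {spgr_hi.shape}"
        )
    for img, which in ((spgr_lo, "low-FA"), (spgr_hi, "high-FA")):
        if img.modality != MODALITY_SPGR:
            raise ValidationError(f"{which} image is not SPGR (modality={img.modality!r})")
        if img.fa is None or img.fa <= 0:
            raise ValidationError(f"{which} image lacks a positive flip angle")
    if spgr_lo.fa == spgr_hi.fa:
        raise ValidationError("the two SPGR images must have different flip angles")
    tr1, tr2 = float(spgr_lo.tr), float(spgr_hi.tr)
    if abs(tr1 - tr2) > TR_MISMATCH_TOL * max(tr1, tr2):
        raise ValidationError(f"TR mismatch between SPGR images: {tr1} vs {tr2} ms")
    tr = 0.5 * (tr1 + tr2)

    if b1 is None:
        scale: Union[float, np.ndarray] = 1.0
        b1_applied = False
    else:
        b1 = b1 if isinstance(b1, B1Map) else B1Map(np.asarray(b1))
        if b1.scale.shape != spgr_lo.shape:
            raise ValidationError("B1 map shape does not match the SPGR images")
        scale = b1.scale
        b1_applied = True

    t1 = _fit_arrays(spgr_lo.pixels, spgr_hi.pixels, spgr_lo.fa, spgr_hi.fa, tr, scale)
    result = T1Map(t1=t1, fa1=spgr_lo.fa, fa2=spgr_hi.fa, tr=tr, b1_applied=b1_applied)
    logger.info(
        "T1 map %sx%s: %.2f%% invalid pixels",
        *t1.shape, 100.0 * result.invalid_fraction,
    )
    return result
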