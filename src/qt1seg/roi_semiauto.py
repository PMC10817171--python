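"""Semiautomatic myometrial ROI placement.

Pipeline (two user inputs only: an endometrial seed point and a rough
external myometrial contour):

1.  Rasterize the traced contour into an 8-connected one-pixel outline.
2.  Grow the endometrial ROI on the IR image from the seed: intensity
    tolerance starts at +/-3% of the seed intensity and is raised in 1%
    increments for as long as the grown component stays clear of the
    contour; the largest admissible tolerance wins.
3.  Sample the band between the endometrial ROI and the contour.
4.  Keep band pixels within +/-1.96 SD of the band mean -> myometrial ROI.
5.  Place the ROI on the SPGR image and minimise the within-ROI sum of
    squared deviations over integer translations in {-10..10}^2.
6.  Mean qT1 over the optimally shifted ROI on the T1 map.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import draw, measure

from qt1seg.exceptions import StageError, ValidationError
from qt1seg.imaging_io import Image2D, Polygon
from qt1seg.phantom import MAX_SHIFT
from qt1seg.roi_manual import mean_qt1
from qt1seg.t1_mapping import T1Map

logger = logging.getLogger(__name__)

TOLERANCE_INITIAL_PCT = 3  # starting half-width of the intensity window, %
TOLERANCE_STEP_PCT = 1
TOLERANCE_MAX_PCT = 100  # guard against runaway growth on pathological images
SD_FILTER_WIDTH = 1.96

_CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class SemiAutoResult:
    """All intermediates of one semiautomatic placement."""

    seed: Tuple[int, int]  # (x, y)
    contour: Polygon
    tolerance_pct: int
    endo_mask: np.ndarray
    band_mask: np.ndarray
    myo_mask: np.ndarray  # in IR space, before the optimal shift
    optimal_shift: Tuple[int, int]  # (dx, dy)
    ssd_surface: np.ndarray  # (2*MAX_SHIFT+1)^2, NaN where excluded
    mean_qt1: float


def trace_contour_mask(poly: Polygon, shape: Tuple[int, int]) -> np.ndarray:
    """8-connected one-pixel-wide closed outline of the polygon boundary.

    Each edge is rasterized with Bresenham's line between the rounded
    vertex positions; the loop is closed back to the first vertex.
    """
    if not isinstance(poly, Polygon):
        poly = Polygon(np.asarray(poly))
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    rr_v = np.clip(np.round(poly.y).astype(int), 0, rows - 1)
    cc_v = np.clip(np.round(poly.x).astype(int), 0, cols - 1)
    n = len(rr_v)
    for i in range(n):
        rr, cc = draw.line(rr_v[i], cc_v[i], rr_v[(i + 1) % n], cc_v[(i + 1) % n])
        mask[rr, cc] = True
    return mask


def _interior(contour: np.ndarray) -> np.ndarray:
    """Region enclosed by the contour, contour pixels excluded."""
    return ndimage.binary_fill_holes(contour) & ~contour


def grow_endometrial_roi(
    ir: Image2D,
    seed: Tuple[int, int],
    contour: np.ndarray,
    seed_mode: str = "pixel",
) -> Tuple[np.ndarray, int]:
    """Region-grow the endometrial ROI from the seed on the IR image.

    The reference intensity is the IR value at the seed pixel
    (``seed_mode="pixel"``) or the mean of its 3x3 neighbourhood
    (``seed_mode="mean3"``).  A pixel is admissible at tolerance ``t`` (%)
    when ``|I(p) - ref| <= (t/100) * ref``; the grown region is the
    8-connected component of admissible pixels containing the seed.
    Tolerance starts at 3% and increases in 1% steps; the largest tolerance
    whose component contains no contour pixel is kept.

    Returns ``(endo_mask, tolerance_pct)``.
    """
    x, y = seed
    r, c = int(round(y)), int(round(x))
    rows, cols = ir.shape
    if not (0 <= r < rows and 0 <= c < cols):
        raise ValidationError(f"seed ({x}, {y}) outside the image")
    if contour[r, c]:
        raise ValidationError("seed lies on the traced contour")
    interior = _interior(contour)
    if not interior[r, c]:
        raise ValidationError("seed lies outside the region enclosed by the contour")

    img = ir.pixels
    if seed_mode == "pixel":
        ref = float(img[r, c])
    elif seed_mode == "mean3":
        ref = float(img[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2].mean())
    else:
        raise ValidationError(f"unknown seed_mode {seed_mode!r}")
    if ref <= 0:
        raise ValidationError("seed intensity must be positive for a relative tolerance")

    deviation = np.abs(img - ref)
    best_mask: Optional[np.ndarray] = None
    best_t = 0
    for t in range(TOLERANCE_INITIAL_PCT, TOLERANCE_MAX_PCT + 1, TOLERANCE_STEP_PCT):
        admissible = deviation <= (t / 100.0) * ref
        comp_labels = measure.label(admissible, connectivity=2)
        comp = comp_labels == comp_labels[r, c]
        if (comp & contour).any():
            break
        best_mask, best_t = comp, t
    if best_mask is None:
        raise ValidationError(
            f"region already touches the contour at the initial {TOLERANCE_INITIAL_PCT}% "
            "tolerance; check seed placement and contour"
        )
    logger.debug("endometrial growth stopped at tolerance %d%%", best_t)
    return best_mask, best_t


def band_mask(
    endo: np.ndarray, contour: np.ndarray, shape: Tuple[int, int]
) -> np.ndarray:
    """Band between the endometrial ROI and the traced contour.

    mask = (interior fill of contour) AND NOT endo AND NOT contour.
    """
    endo = np.asarray(endo, dtype=bool)
    contour = np.asarray(contour, dtype=bool)
    if endo.shape != shape or contour.shape != shape:
        raise ValidationError("endo/contour masks must match the target shape")
    interior = _interior(contour)
    if (endo & ~(interior | contour)).any():
        raise ValidationError("endometrial ROI extends outside the traced contour")
    band = interior & ~endo
    if not band.any():
        raise ValidationError("band between endometrial ROI and contour is empty")
    return band


def filter_sd(
    ir: Image2D, band: np.ndarray, width: float = SD_FILTER_WIDTH
) -> np.ndarray:
    """Keep band pixels within +/-``width`` sample SDs of the band mean.

    Mean and SD (n-1 denominator) are computed once over the band, not
    iterated; the comparison is boundary-inclusive, so a constant band is
    retained in full.
    """
    band = np.asarray(band, dtype=bool)
    n = int(band.sum())
    if n == 0:
        raise ValidationError("band is empty")
    if n < 2:
        raise ValidationError("band has a single pixel; SD is undefined")
    values = ir.pixels[band]
    mean = values.mean()
    sd = values.std(ddof=1)
    keep = np.zeros_like(band)
    keep[band] = np.abs(values - mean) <= width * sd
    return keep


def _shifted_indices(rows_idx, cols_idx, dx: int, dy: int, shape):
    rr = rows_idx + dy
    cc = cols_idx + dx
    ok = (rr.min() >= 0) and (cc.min() >= 0) and (rr.max() < shape[0]) and (cc.max() < shape[1])
    return rr, cc, ok


def optimize_shift(
    myo: np.ndarray,
    spgr: Image2D,
    ref_mean: str = "own",
    search: int = MAX_SHIFT,
) -> Tuple[int, int, np.ndarray]:
    """Find the integer ROI translation minimising the within-ROI SSD.

    For every admissible ``(dx, dy)`` in ``{-search..search}^2`` the ROI is
    moved by ``(dx, dy)`` on the SPGR image and the sum of squared
    deviations of the covered pixel values is computed about either the
    shifted ROI's own mean (``ref_mean="own"``, default) or the mean of the
    unshifted ROI (``ref_mean="fixed"``).  Shifts that would push any ROI
    pixel off the image are excluded.  Ties are broken by the smallest
    shift magnitude, then row-major (dy, then dx).

    Returns ``(dx, dy, ssd_surface)`` with the surface indexed as
    ``surface[dy + search, dx + search]`` (NaN where excluded).
    """
    myo = np.asarray(myo, dtype=bool)
    if not myo.any():
        raise ValidationError("myometrial ROI is empty")
    if myo.shape != spgr.shape:
        raise ValidationError("ROI and SPGR shapes differ")
    if ref_mean not in ("own", "fixed"):
        raise ValidationError(f"unknown ref_mean mode {ref_mean!r}")

    img = spgr.pixels
    rows_idx, cols_idx = np.nonzero(myo)
    fixed_ref = float(img[rows_idx, cols_idx].mean()) if ref_mean == "fixed" else None

    size = 2 * search + 1
    surface = np.full((size, size), np.nan)
    candidates = []
    for dy in range(-search, search + 1):
        for dx in range(-search, search + 1):
            rr, cc, ok = _shifted_indices(rows_idx, cols_idx, dx, dy, img.shape)
            if not ok:
                continue
            v = img[rr, cc]
            ref = v.mean() if fixed_ref is None else fixed_ref
            ssd = float(((v - ref) ** 2).sum())
            surface[dy + search, dx + search] = ssd
            candidates.append((ssd, dx * dx + dy * dy, dy, dx))
    if not candidates:
        raise ValidationError("every candidate shift pushes the ROI off the image")
    ssd_min = min(c[0] for c in candidates)
    best = min((c for c in candidates if c[0] == ssd_min), key=lambda c: (c[1], c[2], c[3]))
    return best[3], best[2], surface


def shift_mask(mask: np.ndarray, dx: int, dy: int) -> np.ndarray:
    """Translate a boolean mask by (dx, dy); pixels leaving the grid drop out."""
    rows_idx, cols_idx = np.nonzero(mask)
    rr = rows_idx + dy
    cc = cols_idx + dx
    keep = (rr >= 0) & (cc >= 0) & (rr < mask.shape[0]) & (cc < mask.shape[1])
    out = np.zeros_like(mask)
    out[rr[keep], cc[keep]] = True
    return out


def semiauto_qt1(
    ir: Image2D,
    spgr: Image2D,
    t1map: T1Map,
    seed: Tuple[int, int],
    contour_poly: Polygon,
    seed_mode: str = "pixel",
    ref_mean: str = "own",
) -> SemiAutoResult:
    """Run the full semiautomatic placement and return all intermediates."""

    def stage(label, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except ValidationError as exc:
            raise StageError(label, str(exc)) from exc

    if ir.shape != spgr.shape or ir.shape != t1map.shape:
        raise StageError("inputs", "IR, SPGR and T1 map shapes must match")

    contour = stage("trace_contour", trace_contour_mask, contour_poly, ir.shape)
    endo, tolerance = stage(
        "grow_endometrium", grow_endometrial_roi, ir, seed, contour, seed_mode
    )
    band = stage("band", band_mask, endo, contour, ir.shape)
    myo = stage("sd_filter", filter_sd, ir, band)
    dx, dy, surface = stage("optimize_shift", optimize_shift, myo, spgr, ref_mean)
    shifted = shift_mask(myo, dx, dy)
    mean = stage("mean_qt1", mean_qt1, shifted, t1map)
    logger.info(
        "semiauto: tolerance=%d%%, shift=(%d, %d), %d ROI pixels, mean qT1=%.1f ms",
        tolerance, dx, dy, int(myo.sum()), mean,
    )
    return SemiAutoResult(
        seed=(int(round(seed[0])), int(round(seed[1]))),
        contour=contour_poly,
        tolerance_pct=tolerance,
        endo_mask=endo,
        band_mask=band,
        myo_mask=myo,
        optimal_shift=(dx, dy),
        ssd_surface=surface,
        mean_qt1=mean,
    )
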