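"""Manual ROI protocol: myometrial mask = whole-uterus polygon minus
endometrial polygon, then the mean qT1 over that mask.

Rasterization uses the pixel-center even-odd rule: a pixel belongs to the
polygon iff its center (integer x = column, y = row) lies inside under
even-odd ray crossing.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np

from qt1seg.exceptions import ValidationError
from qt1seg.imaging_io import Polygon
from qt1seg.t1_mapping import T1Map

logger = logging.getLogger(__name__)


def rasterize_polygon(poly: Polygon, shape: Tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    Even-odd rule, implemented as a crossing-number test vectorized over
    all pixel centers (an edge is counted when it spans the pixel row's y
    half-open interval and the crossing is to the right of the center).
    """
    if not isinstance(poly, Polygon):
        poly = Polygon(np.asarray(poly))
    rows, cols = shape
    py, px = np.mgrid[0:rows, 0:cols].astype(np.float64)
    inside = np.zeros(shape, dtype=bool)
    xs, ys = poly.x, poly.y
    n = len(xs)
    for i in range(n):
        x1, y1 = xs[i], ys[i]
        x2, y2 = xs[(i + 1) % n], ys[(i + 1) % n]
        if y1 == y2:
            continue  # horizontal edges never cross a scanline half-open in y
        spans = (y1 > py) != (y2 > py)
        with np.errstate(invalid="ignore"):
            x_cross = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
        inside ^= spans & (px < x_cross)
    return inside


def manual_myometrial_mask(
    whole: Polygon, endo: Polygon, shape: Tuple[int, int]
) -> np.ndarray:
    """Myometrial mask: rasterized whole-uterus ROI minus endometrial ROI.

    The junctional zone is part of the remaining ring by construction.
    An empty result signals a contour mix-up and raises.
    """
    mask = rasterize_polygon(whole, shape) & ~rasterize_polygon(endo, shape)
    if not mask.any():
        raise ValidationError(
            "myometrial mask is empty; whole-uterus and endometrial contours "
            "are likely swapped or degenerate"
        )
    return mask


def mean_qt1(mask: np.ndarray, t1map: T1Map) -> float:
    """Arithmetic mean of valid T1 pixels under the mask, in ms.

    Invalid (NaN) fits under the mask are excluded; their count is logged.
    Raises when the mask is empty or covers no valid pixel.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != t1map.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match T1 map {t1map.shape}"
        )
    if not mask.any():
        raise ValidationError("mask is empty")
    values = t1map.t1[mask]
    valid = np.isfinite(values)
    n_excluded = int(np.sum(~valid))
    if n_excluded:
        logger.info("mean_qt1: excluded %d invalid T1 pixels of %d", n_excluded, values.size)
    if not valid.any():
        raise ValidationError("all pixels under the mask have invalid T1 fits")
    return float(values[valid].mean())
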