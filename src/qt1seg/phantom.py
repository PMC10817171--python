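"""Digital uterus phantoms and forward MR signal simulation.

A phantom is one oblique slice: an elliptical myometrial ring enclosing a
bright endometrial core, optional extra-uterine confounders (bladder, bowel,
vessel), a smooth multiplicative B1 field and additive Gaussian noise.
The forward models are the standard SPGR steady-state signal

    S = M0 * sin(a_eff) * (1 - E1) / (1 - E1 * cos(a_eff)),   E1 = exp(-TR/T1)

with effective flip angle ``a_eff = B1 * a_nominal``, and the magnitude
inversion-recovery signal in the long-TR approximation

    S = M0 * |1 - 2 * exp(-TI/T1)|.

Coordinates: x = column, y = row, 0-based (see :mod:`qt1seg.imaging_io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from skimage import measure

from qt1seg.exceptions import InvalidSpecError
from qt1seg.imaging_io import MODALITY_IR, MODALITY_SPGR, Image2D

MAX_SHIFT = 10  # search window half-width of the shift optimizer

LABEL_BACKGROUND = 0
LABEL_MYOMETRIUM = 1
LABEL_ENDOMETRIUM = 2
# confounders get labels 3, 4, ...


@dataclass(frozen=True)
class TissueSpec:
    """T1 (ms) and equilibrium signal M0 of one tissue class."""

    name: str
    t1: float
    m0: float

    def __post_init__(self) -> None:
        if self.t1 <= 0 or self.m0 <= 0:
            raise InvalidSpecError(f"tissue {self.name!r}: t1 and m0 must be > 0")


@dataclass(frozen=True)
class Ellipse:
    """Axis lengths are semi-axes; rotation in degrees, about the center."""

    cx: float
    cy: float
    ax: float  # semi-axis along x before rotation
    ay: float  # semi-axis along y before rotation
    rotation_deg: float = 0.0

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Pixel-center inclusion test, vectorized."""
        theta = math.radians(self.rotation_deg)
        dx, dy = x - self.cx, y - self.cy
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        return (u / self.ax) ** 2 + (v / self.ay) ** 2 <= 1.0

    def polygon(self, n_vertices: int = 32) -> np.ndarray:
        """Sampled boundary as an (n, 2) vertex array (x, y)."""
        t = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
        theta = math.radians(self.rotation_deg)
        u, v = self.ax * np.cos(t), self.ay * np.sin(t)
        x = self.cx + u * math.cos(theta) - v * math.sin(theta)
        y = self.cy + u * math.sin(theta) + v * math.cos(theta)
        return np.column_stack([x, y])


@dataclass(frozen=True)
class Confounder:
    shape: Ellipse
    tissue: TissueSpec


def default_tissues() -> Dict[str, TissueSpec]:
    """Default T1/M0 per tissue class (config values, overridable).

    Myometrial T1 sits inside the observed in vivo range (~1200-2500 ms);
    the endometrium gets a higher M0 so the IR image at TI=200 ms shows it
    bright against the myometrium.
    """
    return {
        "background": TissueSpec("background", t1=300.0, m0=600.0),
        "myometrium": TissueSpec("myometrium", t1=1500.0, m0=1000.0),
        "endometrium": TissueSpec("endometrium", t1=2200.0, m0=1400.0),
    }


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissues, noise and field parameters of one phantom slice."""

    shape: Tuple[int, int] = (128, 128)
    outer: Ellipse = Ellipse(64.0, 64.0, 31.0, 23.0, 0.0)
    inner: Ellipse = Ellipse(64.0, 64.0, 14.0, 10.0, 0.0)
    myometrium: TissueSpec = field(default_factory=lambda: default_tissues()["myometrium"])
    endometrium: TissueSpec = field(default_factory=lambda: default_tissues()["endometrium"])
    background: TissueSpec = field(default_factory=lambda: default_tissues()["background"])
    confounders: Tuple[Confounder, ...] = ()
    noise_sd: float = 0.0
    b1_range: Tuple[float, float] = (1.0, 1.0)
    ir_to_spgr_shift: Tuple[int, int] = (0, 0)  # (dx, dy)

    def __post_init__(self) -> None:
        rows, cols = self.shape
        if rows < 8 or cols < 8:
            raise InvalidSpecError("grid must be at least 8x8")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be >= 0")
        lo, hi = self.b1_range
        if not (0 < lo <= hi):
            raise InvalidSpecError("b1_range must satisfy 0 < lo <= hi")
        dx, dy = self.ir_to_spgr_shift
        if dx != int(dx) or dy != int(dy):
            raise InvalidSpecError("ir_to_spgr_shift must be integer pixels")
        if abs(dx) > MAX_SHIFT or abs(dy) > MAX_SHIFT:
            raise InvalidSpecError(
                f"|shift| components must be <= {MAX_SHIFT} (got {self.ir_to_spgr_shift})"
            )


@dataclass
class PhantomTruth:
    """Ground truth of a generated phantom."""

    t1_map_true: np.ndarray  # ms, > 0 everywhere
    m0_map: np.ndarray
    b1_map: np.ndarray
    labels: np.ndarray  # int label map partitioning the grid
    masks: Dict[str, np.ndarray]  # per-tissue boolean masks
    spec: PhantomSpec
    seed: int


def _pixel_grid(shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
    rows, cols = shape
    y, x = np.mgrid[0:rows, 0:cols].astype(np.float64)
    return x, y


def _b1_field(shape: Tuple[int, int], b1_range: Tuple[float, float]) -> np.ndarray:
    """Smooth radial polynomial scaled into [lo, hi]; hi at center, lo at corners."""
    lo, hi = b1_range
    if lo == hi:
        return np.full(shape, float(lo))
    x, y = _pixel_grid(shape)
    cy, cx = (shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0
    r2 = ((x - cx) ** 2 + (y - cy) ** 2)
    r2 /= r2.max()
    return hi - (hi - lo) * r2


def make_phantom(spec: PhantomSpec, seed: int = 0) -> PhantomTruth:
    """Rasterize the phantom geometry into label/T1/M0/B1 maps.

    Deterministic for fixed ``(spec, seed)``: geometry is fully specified
    and the seed is only recorded for downstream noise generation.
    """
    x, y = _pixel_grid(spec.shape)
    outer_mask = spec.outer.contains(x, y)
    inner_mask = spec.inner.contains(x, y)

    # endometrium must sit strictly inside the myometrial ring
    grown = ndimage.binary_dilation(inner_mask, structure=np.ones((3, 3)))
    if not np.all(outer_mask[grown]):
        raise InvalidSpecError(
            "endometrium (inner ellipse) must lie strictly inside the outer ellipse"
        )
    if not inner_mask.any():
        raise InvalidSpecError("endometrium rasterizes to an empty region")

    labels = np.full(spec.shape, LABEL_BACKGROUND, dtype=np.int32)
    masks: Dict[str, np.ndarray] = {}
    tissue_of_label: Dict[int, TissueSpec] = {LABEL_BACKGROUND: spec.background}

    next_label = LABEL_ENDOMETRIUM + 1
    for conf in spec.confounders:
        cmask = conf.shape.contains(x, y)
        if (cmask & outer_mask).any():
            raise InvalidSpecError(
                f"confounder {conf.tissue.name!r} overlaps the uterus"
            )
        labels[cmask] = next_label
        masks[conf.tissue.name] = cmask
        tissue_of_label[next_label] = conf.tissue
        next_label += 1

    myo_mask = outer_mask & ~inner_mask
    labels[myo_mask] = LABEL_MYOMETRIUM
    labels[inner_mask] = LABEL_ENDOMETRIUM
    masks["myometrium"] = myo_mask
    masks["endometrium"] = inner_mask
    masks["background"] = labels == LABEL_BACKGROUND
    tissue_of_label[LABEL_MYOMETRIUM] = spec.myometrium
    tissue_of_label[LABEL_ENDOMETRIUM] = spec.endometrium

    if measure.label(inner_mask, connectivity=2).max() != 1:
        raise InvalidSpecError("endometrium mask is not a single connected component")

    t1_map = np.empty(spec.shape, dtype=np.float64)
    m0_map = np.empty(spec.shape, dtype=np.float64)
    for lab, tissue in tissue_of_label.items():
        sel = labels == lab
        t1_map[sel] = tissue.t1
        m0_map[sel] = tissue.m0

    return PhantomTruth(
        t1_map_true=t1_map,
        m0_map=m0_map,
        b1_map=_b1_field(spec.shape, spec.b1_range),
        labels=labels,
        masks=masks,
        spec=spec,
        seed=int(seed),
    )


def spgr_signal(t1, m0, fa_deg, tr, b1=1.0) -> np.ndarray:
    """Closed-form SPGR steady-state signal (arrays or scalars)."""
    a = np.deg2rad(fa_deg) * np.asarray(b1, dtype=np.float64)
    e1 = np.exp(-tr / np.asarray(t1, dtype=np.float64))
    return np.asarray(m0) * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def ir_signal(t1, m0, ti) -> np.ndarray:
    """Closed-form magnitude IR signal, long-TR approximation."""
    return np.asarray(m0) * np.abs(1.0 - 2.0 * np.exp(-ti / np.asarray(t1, dtype=np.float64)))


def simulate_spgr(
    truth: PhantomTruth,
    fa_deg: float,
    tr: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    te: float = 2.5,
) -> Image2D:
    """Simulate one SPGR acquisition of the phantom at a nominal flip angle."""
    if fa_deg <= 0:
        raise InvalidSpecError("fa_deg must be > 0")
    if tr <= 0:
        raise InvalidSpecError("tr must be > 0")
    signal = spgr_signal(truth.t1_map_true, truth.m0_map, fa_deg, tr, truth.b1_map)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return Image2D(pixels=signal, tr=tr, te=te, fa=fa_deg, modality=MODALITY_SPGR)


def simulate_ir(
    truth: PhantomTruth,
    ti: float,
    noise_sd: float = 0.0,
    seed: int = 0,
    tr: float = 7800.0,
    te: float = 10.0,
) -> Image2D:
    """Simulate the magnitude IR acquisition used for anatomical contrast."""
    if ti <= 0:
        raise InvalidSpecError("ti must be > 0")
    signal = ir_signal(truth.t1_map_true, truth.m0_map, ti)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return Image2D(pixels=signal, tr=tr, te=te, ti=ti, modality=MODALITY_IR)


def apply_shift(image: Image2D, dx: int, dy: int, fill: float = 0.0) -> Image2D:
    """Translate an image by integer pixels: content moves +dx columns, +dy rows.

    Pixels shifted in from outside the grid take ``fill`` (the background
    value).  ``out[r, c] = in[r - dy, c - dx]``.
    """
    for name, val in (("dx", dx), ("dy", dy)):
        if not float(val).is_integer():
            raise InvalidSpecError(f"{name} must be an integer, got {val}")
    dx, dy = int(dx), int(dy)
    if abs(dx) > MAX_SHIFT or abs(dy) > MAX_SHIFT:
        raise InvalidSpecError(f"|dx|, |dy| must be <= {MAX_SHIFT}")
    out = np.full(image.pixels.shape, float(fill), dtype=np.float64)
    rows, cols = image.pixels.shape
    src_r = slice(max(0, -dy), min(rows, rows - dy))
    src_c = slice(max(0, -dx), min(cols, cols - dx))
    dst_r = slice(max(0, dy), min(rows, rows + dy))
    dst_c = slice(max(0, dx), min(cols, cols + dx))
    out[dst_r, dst_c] = image.pixels[src_r, src_c]
    return replace(image, pixels=out)
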