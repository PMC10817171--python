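"""End-to-end phantom reproducibility study (the `replicate` subcommand).

Generates a cohort of uterus phantoms, simulates two observers (and a
repeat session of observer 1) by jittering the contour/seed inputs, runs
the manual and semiautomatic pipelines on every subject, and computes the
full agreement comparison between the two methods.

Observer simulation: contour vertices are jittered with Gaussian SD 2 px
and seeds are jittered within the endometrium; this emulates inter-rater
tracing variation.  Both pipelines receive equally jittered polygons.
The IR-to-SPGR shift is zero here because subjects with misregistration
would have been excluded from a manual protocol; the shift optimizer is
still exercised (it must find (0, 0)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Tuple

import numpy as np

from qt1seg.imaging_io import MeasurementTable, Polygon
from qt1seg.phantom import (
    Confounder,
    Ellipse,
    PhantomSpec,
    TissueSpec,
    make_phantom,
    simulate_ir,
    simulate_spgr,
    spgr_signal,
    ir_signal,
)
from qt1seg.repro_stats import MethodComparison, compare_methods
from qt1seg.roi_manual import manual_myometrial_mask, mean_qt1
from qt1seg.roi_semiauto import semiauto_qt1
from qt1seg.t1_mapping import compute_t1_map

logger = logging.getLogger(__name__)

FA_LO, FA_HI = 4.0, 18.0
TR_SPGR = 5.3
TI_IR = 200.0
N_VERTICES = 24


@dataclass
class ReplicateResult:
    """Tables and comparisons of one replicate study."""

    tables: Dict[str, MeasurementTable]  # inter/intra x manual/semiauto
    inter: MethodComparison  # manual vs semiauto, interobserver
    intra: MethodComparison  # manual vs semiauto, intraobserver
    seed: int
    n: int

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n": self.n,
            "interobserver": self.inter.to_dict(),
            "intraobserver": self.intra.to_dict(),
        }


def _subject_spec(rng: np.random.Generator) -> PhantomSpec:
    """Randomized subject anatomy with fixed, non-overlapping confounders."""
    myo_t1 = float(rng.uniform(1300.0, 2400.0))
    endo_t1 = min(myo_t1 + 700.0, 3200.0)
    ax = float(rng.uniform(27.0, 33.0))
    ay = float(rng.uniform(20.0, 25.0))
    rot = float(rng.uniform(-25.0, 25.0))
    scale = float(rng.uniform(0.42, 0.48))
    return PhantomSpec(
        shape=(128, 128),
        outer=Ellipse(64.0, 64.0, ax, ay, rot),
        inner=Ellipse(64.0, 64.0, scale * ax, scale * ay, rot),
        myometrium=TissueSpec("myometrium", t1=myo_t1, m0=1000.0),
        endometrium=TissueSpec("endometrium", t1=endo_t1, m0=1400.0),
        background=TissueSpec("background", t1=300.0, m0=600.0),
        confounders=(
            Confounder(Ellipse(64.0, 104.0, 16.0, 11.0), TissueSpec("bladder", 4000.0, 1600.0)),
            Confounder(Ellipse(18.0, 64.0, 8.0, 8.0), TissueSpec("bowel", 900.0, 800.0)),
            Confounder(Ellipse(106.0, 60.0, 4.0, 4.0), TissueSpec("vessel", 1700.0, 900.0)),
        ),
    )


def _jitter_polygon(xy: np.ndarray, rng: np.random.Generator, sd: float) -> Polygon:
    return Polygon(xy + rng.normal(0.0, sd, size=xy.shape))


def run_replicate(
    n: int = 23,
    seed: int = 0,
    noise_frac: float = 0.02,
    jitter_sd: float = 2.0,
) -> ReplicateResult:
    """Run the full phantom study; deterministic for fixed arguments."""
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)

    runs = ("obs1_s1", "obs2_s1", "obs1_s2")
    manual: Dict[str, list] = {r: [] for r in runs}
    semi: Dict[str, list] = {r: [] for r in runs}

    for i in range(n):
        rng = np.random.default_rng(children[i])
        spec = _subject_spec(rng)
        truth = make_phantom(spec, seed=seed)

        myo_spgr = spgr_signal(spec.myometrium.t1, spec.myometrium.m0, FA_LO, TR_SPGR)
        myo_ir = ir_signal(spec.myometrium.t1, spec.myometrium.m0, TI_IR)
        noise_spgr = noise_frac * float(myo_spgr)
        noise_ir = noise_frac * float(myo_ir)

        sub_seed = int(rng.integers(0, 2**31 - 1))
        ir = simulate_ir(truth, ti=TI_IR, noise_sd=noise_ir, seed=sub_seed)
        spgr_lo = simulate_spgr(truth, FA_LO, TR_SPGR, noise_sd=noise_spgr, seed=sub_seed + 1)
        spgr_hi = simulate_spgr(truth, FA_HI, TR_SPGR, noise_sd=noise_spgr, seed=sub_seed + 2)
        t1map = compute_t1_map(spgr_lo, spgr_hi)

        outer_xy = spec.outer.polygon(N_VERTICES)
        inner_xy = spec.inner.polygon(N_VERTICES)
        center = (spec.inner.cx, spec.inner.cy)

        for run in runs:
            whole = _jitter_polygon(outer_xy, rng, jitter_sd)
            endo = _jitter_polygon(inner_xy, rng, jitter_sd)
            mask = manual_myometrial_mask(whole, endo, spec.shape)
            manual[run].append(mean_qt1(mask, t1map))

            seed_pt = (
                center[0] + float(rng.integers(-2, 3)),
                center[1] + float(rng.integers(-2, 3)),
            )
            result = semiauto_qt1(ir, spgr_hi, t1map, seed_pt, whole)
            semi[run].append(result.mean_qt1)
        logger.debug("subject %d/%d done", i + 1, n)

    subjects = list(range(1, n + 1))

    def table(method: Dict[str, list], a: str, b: str, la: str, lb: str) -> MeasurementTable:
        return MeasurementTable(
            subjects=subjects,
            values=np.column_stack([method[a], method[b]]),
            labels=(la, lb),
        )

    tables = {
        "inter_manual": table(manual, "obs1_s1", "obs2_s1", "observer1", "observer2"),
        "inter_semiauto": table(semi, "obs1_s1", "obs2_s1", "observer1", "observer2"),
        "intra_manual": table(manual, "obs1_s1", "obs1_s2", "first", "second"),
        "intra_semiauto": table(semi, "obs1_s1", "obs1_s2", "first", "second"),
    }
    return ReplicateResult(
        tables=tables,
        inter=compare_methods(tables["inter_manual"], tables["inter_semiauto"]),
        intra=compare_methods(tables["intra_manual"], tables["intra_semiauto"]),
        seed=seed,
        n=n,
    )
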