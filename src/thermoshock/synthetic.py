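"""Synthetic pseudo-thermal cohort generator.

Every downstream stage (detection, CPD extraction, shock labeling, mixed
modeling, evaluation) is exercised against data with known ground truth, so
the generator plants exactly the structure those stages are supposed to
recover:

* a warm body silhouette (head / torso / arms / legs / feet ellipse
  composites) on a cooler noisy background, supine, head at the top;
* a warm abdomen and cooler feet whose intensity deficit — the
  center-to-periphery difference (CPD) — is drawn per image from
  state-conditional distributions (shock images have a larger mean deficit);
* a cool transverse "diaper" band across the pelvis producing the
  characteristic U-shaped dip in the abdomen-to-foot midline profile;
* longitudinal vitals sampled every 15 s whose heart rate / systolic blood
  pressure distributions are conditioned on the shock state active at each
  imaging anchor (and at the +3/+6/+12 h horizons).

Default calibration follows the published PICU cohort summary statistics:
51 patients, ~5 images each, non-shock HR 120.75 (24.53) vs shock
136.16 (22.78) beats/min, non-shock SBP 97.55 (21.81) vs shock 88.97 (21.62)
mmHg, abdomen intensity ~163 (19.6), abdomen-minus-foot deficit 19.56 (23.48)
non-shock vs 25.39 (28.88) shock, ages 0.2–144 months.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _ellipse

from .imaging import BBox, save_image

HORIZONS = (0, 3, 6, 12)
VITALS_INTERVAL_S = 15

#: Cohort-level calibration constants (population means used as defaults).
TABLE_CALIBRATION = {
    "hr_nonshock": (120.75, 24.53),
    "hr_shock": (136.16, 22.78),
    "sbp_nonshock": (97.55, 21.81),
    "sbp_shock": (88.97, 21.62),
    "abdomen_nonshock": (164.24, 21.53),
    "abdomen_shock": (161.82, 17.73),
    "foot_nonshock": (144.69, 20.16),
    "foot_shock": (136.43, 24.16),
    "cpd_nonshock": (19.56, 23.48),
    "cpd_shock": (25.39, 28.88),
    "age_nonshock_months": (33.23, 46.76),
    "age_shock_months": (58.33, 53.84),
}


@dataclass
class CohortSpec:
    """Generator configuration; defaults emulate the study cohort scale."""

    n_patients: int = 51
    images_per_patient_mean: float = 5.0
    image_height: int = 320
    image_width: int = 180
    abdomen_intensity_mean: float = 163.0
    abdomen_intensity_sd: float = 19.6
    cpd_nonshock_mean: float = 19.56
    cpd_nonshock_sd: float = 23.48
    cpd_shock_mean: float = 25.39
    cpd_shock_sd: float = 28.88
    background_mean: float = 60.0
    background_sd: float = 8.0
    noise_sd: float = 4.0
    hr_nonshock_mean: float = 120.75
    hr_nonshock_sd: float = 24.53
    hr_shock_mean: float = 136.16
    hr_shock_sd: float = 22.78
    sbp_nonshock_mean: float = 97.55
    sbp_nonshock_sd: float = 21.81
    sbp_shock_mean: float = 88.97
    sbp_shock_sd: float = 21.62
    age_range_months: tuple = (0.2, 144.0)
    shock_prevalence: float = 0.42
    shock_persistence_3h: float = 0.90
    shock_persistence_6h: float = 0.80
    shock_persistence_12h: float = 0.65
    seed: int = 0

    def __post_init__(self):
        for name in ("abdomen_intensity_sd", "cpd_nonshock_sd", "cpd_shock_sd",
                     "background_sd", "noise_sd", "hr_nonshock_sd", "hr_shock_sd",
                     "sbp_nonshock_sd", "sbp_shock_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("shock_prevalence", "shock_persistence_3h",
                     "shock_persistence_6h", "shock_persistence_12h"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("abdomen_intensity_mean", "background_mean"):
            v = getattr(self, name)
            if not 0.0 <= v <= 255.0:
                raise ValueError(f"{name} must be in [0, 255], got {v}")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.images_per_patient_mean <= 0:
            raise ValueError("images_per_patient_mean must be > 0")
        if self.image_height < 40 or self.image_width < 24:
            raise ValueError("image too small to place a body")
        lo, hi = self.age_range_months
        if not (0 < lo < hi):
            raise ValueError(f"invalid age_range_months {self.age_range_months}")

    def persistence(self, horizon: int) -> float:
        return {0: 1.0, 3: self.shock_persistence_3h,
                6: self.shock_persistence_6h,
                12: self.shock_persistence_12h}[horizon]


@dataclass
class SubjectImageState:
    """Everything needed to render one frame and know its ground truth."""

    patient_id: str
    age_months: float
    timestamp: pd.Timestamp
    shock: dict            # horizon (h) -> 0/1
    planted_cpd: float     # abdomen-minus-foot intensity units
    body_scale: float      # body height as a fraction of image height
    abdomen_level: float
    background_level: float


@dataclass
class SyntheticCohort:
    """In-memory dataset: rasters plus tidy ground-truth tables.

    images:  list of HxW uint8 rasters, aligned with ``meta`` rows.
    meta:    one row per image (ids, timestamps, shock states, planted CPD).
    truth:   one row per ground-truth box (abdomen + two feet per image).
    vitals:  15-s interval series per patient (heart rate, pulse rate, SBP).
    """

    spec: CohortSpec
    images: List[np.ndarray]
    meta: pd.DataFrame
    truth: pd.DataFrame
    vitals: pd.DataFrame

    @property
    def n_images(self) -> int:
        return len(self.images)

    def truth_boxes(self, image_id: str, cls: Optional[str] = None) -> List[BBox]:
        rows = self.truth[self.truth.image_id == image_id]
        if cls is not None:
            rows = rows[rows["class"] == cls]
        return [BBox(int(r.x), int(r.y), int(r.w), int(r.h))
                for r in rows.itertuples()]


# ---------------------------------------------------------------------------
# rendering

def _draw(canvas, mask_rr_cc, value):
    rr, cc = mask_rr_cc
    canvas[rr, cc] = value


def render_image(state: SubjectImageState, spec: CohortSpec,
                 rng: Optional[np.random.Generator] = None):
    """Render one frame; returns ``(pixels, truth_boxes)``.

    ``truth_boxes`` is a dict with keys ``abdomen`` (one box) and ``foot``
    (two boxes).  The abdomen truth box is flat at the per-image abdomen
    level and the foot boxes are dominated by foot-blob pixels, so the
    median-intensity difference over the truth boxes recovers the planted
    CPD up to rendering noise.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    H, W = spec.image_height, spec.image_width
    bh = state.body_scale * H          # body height in pixels
    if bh < 40 or 0.46 * bh > W:
        raise ValueError(
            f"image {H}x{W} too small for a body of height {bh:.0f}px")
    y0 = 0.5 * (H - bh * 0.985)        # top of head; feet end near image bottom
    cx = W / 2.0

    abd = float(state.abdomen_level)
    foot_level = abd - float(state.planted_cpd)
    diaper_level = min(abd, foot_level) - 10.0
    leg_top_level, leg_bot_level = abd - 2.0, foot_level

    canvas = np.full((H, W), state.background_level, dtype=np.float64)
    shape = (H, W)

    def E(cy_f, cx_f, ry_f, rx_f):
        return _ellipse(y0 + cy_f * bh, cx + cx_f * bh, ry_f * bh, rx_f * bh,
                        shape=shape)

    # head, torso, arms
    _draw(canvas, E(0.095, 0.0, 0.09, 0.085), abd - 6.0)
    _draw(canvas, E(0.35, 0.0, 0.19, 0.19), abd)
    _draw(canvas, E(0.30, -0.225, 0.11, 0.045), abd - 8.0)
    _draw(canvas, E(0.30, +0.225, 0.11, 0.045), abd - 8.0)

    # legs with a linear proximal-to-distal cool-down (the CPD gradient)
    for sx in (-0.08, +0.08):
        rr, cc = E(0.73, sx, 0.13, 0.05)
        t = np.clip((rr - (y0 + 0.60 * bh)) / (0.26 * bh), 0.0, 1.0)
        canvas[rr, cc] = leg_top_level + t * (leg_bot_level - leg_top_level)

    # diaper band across the pelvis (cool strip -> U-dip in midline profile)
    _draw(canvas, E(0.58, 0.0, 0.06, 0.15), diaper_level)

    # feet (blobs sized so the truth box is ~90% foot pixels: the box median
    # then tracks the planted foot level rather than the background)
    for sx in (-0.09, +0.09):
        _draw(canvas, E(0.91, sx, 0.09, 0.077), foot_level)

    if spec.noise_sd > 0:
        canvas = canvas + rng.normal(0.0, spec.noise_sd, size=canvas.shape)
    pixels = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)

    def square(cy_f, cx_f, side_f) -> BBox:
        side = max(2, int(round(side_f * bh)))
        x = int(round(cx + cx_f * bh - side / 2))
        y = int(round(y0 + cy_f * bh - side / 2))
        x = min(max(x, 0), W - side)
        y = min(max(y, 0), H - side)
        return BBox(x, y, side, side)

    boxes = {
        "abdomen": [square(0.35, 0.0, 0.26)],
        "foot": [square(0.91, -0.09, 0.15), square(0.91, +0.09, 0.15)],
    }
    return pixels, boxes


# ---------------------------------------------------------------------------
# vitals

def _draw_vitals(states: np.ndarray, spec: CohortSpec, rng: np.random.Generator):
    """i.i.d. state-conditional draws; pulse rate = heart rate + small jitter."""
    n = states.shape[0]
    hr_mean = np.where(states == 1, spec.hr_shock_mean, spec.hr_nonshock_mean)
    hr_sd = np.where(states == 1, spec.hr_shock_sd, spec.hr_nonshock_sd)
    sbp_mean = np.where(states == 1, spec.sbp_shock_mean, spec.sbp_nonshock_mean)
    sbp_sd = np.where(states == 1, spec.sbp_shock_sd, spec.sbp_nonshock_sd)
    hr = np.maximum(rng.normal(hr_mean, hr_sd, n), 1.0)
    pulse = np.maximum(hr + rng.normal(0.0, 2.0, n), 1.0)
    sbp = np.maximum(rng.normal(sbp_mean, sbp_sd, n), 1.0)
    return hr, pulse, sbp


def simulate_vitals(shock_state: int, duration: pd.Timedelta, spec: CohortSpec,
                    rng: Optional[np.random.Generator] = None,
                    start: Optional[pd.Timestamp] = None,
                    patient_id: str = "P000") -> pd.DataFrame:
    """Stationary vitals series for a single shock state.

    Samples every 15 s with both endpoints included (a 30-minute duration
    yields 121 samples).  Heart rate and SBP are drawn independently around
    the state-conditional means; the pulse rate tracks the heart rate with a
    small jitter (distinct sensors, same physiology).
    """
    if duration <= pd.Timedelta(0):
        raise ValueError(f"duration must be positive, got {duration}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if start is None:
        start = pd.Timestamp("2016-05-01 00:00:00")
    n = int(duration / pd.Timedelta(seconds=VITALS_INTERVAL_S)) + 1
    ts = start + pd.to_timedelta(np.arange(n) * VITALS_INTERVAL_S, unit="s")
    states = np.full(n, int(shock_state))
    hr, pulse, sbp = _draw_vitals(states, spec, rng)
    return pd.DataFrame({"patient_id": patient_id, "timestamp": ts,
                         "heart_rate": hr, "pulse_rate": pulse, "sbp": sbp})


# ---------------------------------------------------------------------------
# cohort assembly

def _patient_states(spec: CohortSpec, rng: np.random.Generator, age: float,
                    n_images: int):
    """Per-image shock state at 0 h plus horizon states (persistence flips)."""
    # weakly age-increasing shock probability, centred on the prevalence
    lo, hi = spec.age_range_months
    mid = math.sqrt(lo * hi)
    p = spec.shock_prevalence + 0.08 * (math.log(age) - math.log(mid)) / (
        math.log(hi) - math.log(lo))
    p = min(max(p, 0.02), 0.98)
    states = []
    for _ in range(n_images):
        s0 = int(rng.random() < p)
        s = {0: s0}
        for h in HORIZONS[1:]:
            keep = rng.random() < spec.persistence(h)
            s[h] = s0 if keep else 1 - s0
        states.append(s)
    return states


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate the full dataset: frames, ground truth and vitals.

    Deterministic given ``spec`` (one RNG stream per patient, derived from
    the master seed, so the cohort is reproducible patient-by-patient).
    """
    master = np.random.SeedSequence(spec.seed)
    streams = master.spawn(max(spec.n_patients, 1))

    images: List[np.ndarray] = []
    meta_rows, truth_rows, vitals_frames = [], [], []
    t0 = pd.Timestamp("2016-05-01 08:00:00")

    for p in range(spec.n_patients):
        rng = np.random.default_rng(streams[p])
        pid = f"P{p:03d}"
        lo, hi = spec.age_range_months
        age = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        n_img = max(1, int(rng.poisson(spec.images_per_patient_mean)))
        # body size grows weakly with age; detector must be scale-robust
        aget = (math.log(age) - math.log(lo)) / (math.log(hi) - math.log(lo))
        body_scale = 0.72 + 0.18 * aget + rng.normal(0.0, 0.02)
        body_scale = min(max(body_scale, 0.62), 0.93)

        admit = t0 + pd.Timedelta(days=int(p % 7), hours=float(rng.uniform(0, 6)))
        offsets = np.sort(24.0 * np.arange(n_img) + rng.uniform(-4.0, 4.0, n_img))
        stamps = [admit + pd.Timedelta(hours=float(o)) for o in offsets]
        states = _patient_states(spec, rng, age, n_img)

        anchor_times, anchor_states = [], []
        for i in range(n_img):
            st = states[i]
            planted = float(rng.normal(
                spec.cpd_shock_mean if st[0] else spec.cpd_nonshock_mean,
                spec.cpd_shock_sd if st[0] else spec.cpd_nonshock_sd))
            abd_level = float(np.clip(
                rng.normal(spec.abdomen_intensity_mean, spec.abdomen_intensity_sd),
                80.0, 240.0))
            bg_level = float(np.clip(
                rng.normal(spec.background_mean, spec.background_sd), 5.0, 130.0))
            state = SubjectImageState(
                patient_id=pid, age_months=age, timestamp=stamps[i], shock=st,
                planted_cpd=planted, body_scale=body_scale,
                abdomen_level=abd_level, background_level=bg_level)
            pixels, boxes = render_image(state, spec, rng)
            image_id = f"{pid}_I{i:02d}"
            images.append(pixels)
            meta_rows.append({
                "image_id": image_id, "patient_id": pid,
                "timestamp": stamps[i], "age_months": age,
                "planted_cpd": planted, "body_scale": body_scale,
                "shock_0h": st[0], "shock_3h": st[3], "shock_6h": st[6],
                "shock_12h": st[12]})
            for cls, bxs in boxes.items():
                for b in bxs:
                    truth_rows.append({
                        "image_id": image_id, "patient_id": pid,
                        "timestamp": stamps[i], "class": cls,
                        "x": b.x, "y": b.y, "w": b.w, "h": b.h})
            for h in HORIZONS:
                anchor_times.append(stamps[i] + pd.Timedelta(hours=h))
                anchor_states.append(st[h])

        # one continuous vitals record per patient, state given by the
        # nearest imaging/horizon anchor
        order = np.argsort(pd.DatetimeIndex(anchor_times).asi8)
        a_times = pd.DatetimeIndex(anchor_times)[order]
        a_states = np.asarray(anchor_states)[order]
        span_start = a_times[0] - pd.Timedelta(minutes=20)
        span_end = a_times[-1] + pd.Timedelta(minutes=20)
        n_samples = int((span_end - span_start)
                        / pd.Timedelta(seconds=VITALS_INTERVAL_S)) + 1
        ts = span_start + pd.to_timedelta(
            np.arange(n_samples) * VITALS_INTERVAL_S, unit="s")
        mid_anchor = np.searchsorted(a_times.asi8, ts.asi8)
        left = np.clip(mid_anchor - 1, 0, len(a_times) - 1)
        right = np.clip(mid_anchor, 0, len(a_times) - 1)
        use_right = (np.abs(a_times.asi8[right] - ts.asi8)
                     <= np.abs(ts.asi8 - a_times.asi8[left]))
        nearest = np.where(use_right, right, left)
        sample_states = a_states[nearest]
        hr, pulse, sbp = _draw_vitals(sample_states, spec, rng)
        vitals_frames.append(pd.DataFrame({
            "patient_id": pid, "timestamp": ts, "heart_rate": hr,
            "pulse_rate": pulse, "sbp": sbp}))

    meta = pd.DataFrame(meta_rows, columns=[
        "image_id", "patient_id", "timestamp", "age_months", "planted_cpd",
        "body_scale", "shock_0h", "shock_3h", "shock_6h", "shock_12h"])
    truth = pd.DataFrame(truth_rows, columns=[
        "image_id", "patient_id", "timestamp", "class", "x", "y", "w", "h"])
    vitals = (pd.concat(vitals_frames, ignore_index=True) if vitals_frames
              else pd.DataFrame(columns=["patient_id", "timestamp",
                                         "heart_rate", "pulse_rate", "sbp"]))
    return SyntheticCohort(spec=spec, images=images, meta=meta, truth=truth,
                           vitals=vitals)


# ---------------------------------------------------------------------------
# on-disk layout (plain PNG + CSV)

def write_cohort(cohort: SyntheticCohort, outdir) -> None:
    """Write frames as 8-bit grayscale PNGs plus truth/vitals CSVs."""
    outdir = Path(outdir)
    img_dir = outdir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    for raster, row in zip(cohort.images, cohort.meta.itertuples()):
        save_image(img_dir / f"{row.image_id}.png", raster)
    truth = cohort.truth.merge(
        cohort.meta[["image_id", "planted_cpd", "shock_0h", "shock_3h",
                     "shock_6h", "shock_12h"]], on="image_id")
    truth = truth.rename(columns={"timestamp": "timestamp_iso8601"})
    truth["timestamp_iso8601"] = truth["timestamp_iso8601"].map(
        lambda t: t.isoformat())
    truth.to_csv(outdir / "truth.csv", index=False)
    vit = cohort.vitals.rename(columns={"timestamp": "timestamp_iso8601"})
    vit["timestamp_iso8601"] = vit["timestamp_iso8601"].map(
        lambda t: t.isoformat())
    vit.to_csv(outdir / "vitals.csv", index=False)
    meta = cohort.meta.copy()
    meta["timestamp"] = meta["timestamp"].map(lambda t: t.isoformat())
    meta.to_csv(outdir / "images_meta.csv", index=False)
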