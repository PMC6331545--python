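"""Shock-index computation and age-adjusted binary shock labels.

The shock index (SI) is median heart rate divided by median systolic blood
pressure, both medians taken over a 30-minute window straddling the
reference time (±15 min, endpoints inclusive).  SI is binarized with
age-banded cutoffs following the pediatric age-adjusted shock-index (SIPA)
convention; the published bands cover 4–16 years, so the default table
extends the youngest band's cutoff down to birth (with a warning) to keep
the age adjustment monotone — the cutoffs are configurable for cohorts where
a different infant convention is preferred.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import MissingVitalsError

log = logging.getLogger("thermoshock.labeling")

HORIZONS = (0, 3, 6, 12)


@dataclass(frozen=True)
class SipaThresholds:
    """Ordered half-open age bands (months) mapping to SI cutoffs."""

    bands: Tuple[Tuple[float, float, float], ...]  # (age_min, age_max, cutoff)
    warn_below_months: float = 48.0

    def __post_init__(self):
        prev_end = None
        for lo, hi, cut in self.bands:
            if not lo < hi:
                raise ValueError(f"band [{lo}, {hi}) is empty")
            if cut <= 0:
                raise ValueError(f"cutoff must be > 0, got {cut}")
            if prev_end is not None and lo != prev_end:
                raise ValueError("bands must partition the age range")
            prev_end = hi

    def cutoff(self, age_months: float) -> float:
        if age_months < self.warn_below_months:
            warnings.warn(
                f"age {age_months:.1f} months is below the range the SIPA "
                "bands were defined for; extending the youngest cutoff",
                stacklevel=2)
        for lo, hi, cut in self.bands:
            if lo <= age_months < hi:
                return cut
        raise ValueError(f"age {age_months} months outside configured bands")


#: 4–6 y: 1.22 (extended to birth), >6–12 y: 1.0, >12 y: 0.9.
DEFAULT_SIPA = SipaThresholds(bands=((0.0, 84.0, 1.22),
                                     (84.0, 156.0, 1.0),
                                     (156.0, 2400.0, 0.9)))


def straddling_median(vitals: pd.DataFrame, t,
                      width: pd.Timedelta = pd.Timedelta(minutes=30)) -> Dict[str, float]:
    """Vitals medians over ``[t - width/2, t + width/2]`` (inclusive).

    ``vitals`` needs columns timestamp / heart_rate / sbp (pulse_rate
    optional).  NaN samples are excluded per channel.  Raises
    :class:`MissingVitalsError` when no usable sample falls in the window.
    """
    if vitals.empty:
        raise MissingVitalsError("empty vitals series")
    t = pd.Timestamp(t)
    half = width / 2
    ts = pd.to_datetime(vitals["timestamp"])
    sel = vitals[(ts >= t - half) & (ts <= t + half)]
    if sel.empty:
        raise MissingVitalsError(f"no vitals samples within ±{half} of {t}")
    out = {}
    for col in ("heart_rate", "sbp", "pulse_rate"):
        if col not in sel.columns:
            continue
        vals = sel[col].dropna()
        out[col] = float(np.median(vals)) if len(vals) else float("nan")
    if np.isnan(out.get("heart_rate", np.nan)) or np.isnan(out.get("sbp", np.nan)):
        raise MissingVitalsError(f"window at {t} has no usable HR/SBP samples")
    out["n_samples"] = int(len(sel))
    return out


def shock_index(hr_median: float, sbp_median: float) -> float:
    """Heart rate over systolic blood pressure."""
    if sbp_median <= 0:
        raise ValueError(f"sbp_median must be > 0, got {sbp_median}")
    return hr_median / sbp_median


def sipa_label(si: float, age_months: float,
               thresholds: SipaThresholds = DEFAULT_SIPA) -> int:
    """1 iff the shock index strictly exceeds the age band's cutoff."""
    return int(si > thresholds.cutoff(age_months))


def build_shock_labels(vitals: pd.DataFrame, images_meta: pd.DataFrame,
                       horizons: Sequence[int] = HORIZONS,
                       thresholds: SipaThresholds = DEFAULT_SIPA,
                       width: pd.Timedelta = pd.Timedelta(minutes=30)) -> pd.DataFrame:
    """Shock labels for every image at every horizon.

    ``images_meta`` needs image_id / patient_id / timestamp / age_months.
    Rows whose vitals window is empty are skipped with a logged count.  The
    output additionally carries the window's median pulse rate (the
    model's imaging-time covariate).
    """
    rows = []
    n_missing = 0
    vit_by_pat = dict(tuple(vitals.groupby("patient_id")))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # infant-band warning, once per call below
        for img in images_meta.itertuples():
            pv = vit_by_pat.get(img.patient_id)
            for h in horizons:
                t = pd.Timestamp(img.timestamp) + pd.Timedelta(hours=h)
                try:
                    if pv is None:
                        raise MissingVitalsError(f"no vitals for {img.patient_id}")
                    med = straddling_median(pv, t, width=width)
                except MissingVitalsError:
                    n_missing += 1
                    continue
                si = shock_index(med["heart_rate"], med["sbp"])
                rows.append({
                    "image_id": img.image_id, "patient_id": img.patient_id,
                    "reference_time": pd.Timestamp(img.timestamp),
                    "horizon_h": h, "hr_median": med["heart_rate"],
                    "sbp_median": med["sbp"],
                    "pulse_rate_median": med.get("pulse_rate", float("nan")),
                    "shock_index": si,
                    "label": sipa_label(si, img.age_months, thresholds),
                    "age_months": img.age_months})
    if any(images_meta["age_months"] < thresholds.warn_below_months):
        warnings.warn(
            "cohort contains ages below the published SIPA bands; the "
            "youngest cutoff was extended downward", stacklevel=2)
    if n_missing:
        log.warning("shock labeling: %d (image, horizon) windows had no "
                    "usable vitals and were skipped", n_missing)
    return pd.DataFrame(rows, columns=[
        "image_id", "patient_id", "reference_time", "horizon_h", "hr_median",
        "sbp_median", "pulse_rate_median", "shock_index", "label",
        "age_months"])
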