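"""Center-to-periphery difference (CPD) extraction.

The CPD is the abdomen-minus-foot surface-intensity deficit — the imaging
correlate of the cool extremities seen in hemodynamic shock — expressed as a
percentage of the abdomen intensity so it stays invariant to multiplicative
ambient/thermal-gain changes:

    cpd_percent = (abdomen_median - foot_median) / abdomen_median * 100

Medians are taken over the ROI boxes to resist outlier pixels (tubes, probes)
and are computed on the RAW grayscale raster: median thresholding zeroes
background inside a loose box and CLAHE distorts absolute levels, either of
which would corrupt the physical gradient the statistic measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .detection import ForestModel, detect_roi, estimate_silhouette
from .errors import StageError, UndefinedCPDError
from .imaging import BBox, ThermalImage, preprocess, to_grayscale

log = logging.getLogger("thermoshock.cpd")


@dataclass
class CPDRecord:
    image_id: str
    patient_id: str
    timestamp: object
    abdomen_median: float
    foot_median: float
    cpd_percent: float
    source: str  # "manual_box" | "detected"
    abdomen_box: Optional[BBox] = None
    foot_box: Optional[BBox] = None
    abdomen_score: float = float("nan")
    foot_score: float = float("nan")


def median_intensity(gray: np.ndarray, box: BBox) -> float:
    """Median raw-grayscale intensity inside a box (even count: mean of the
    two central order statistics)."""
    px = np.asarray(gray)
    if not box.within(px.shape):
        raise ValueError(f"box {box} outside image of shape {px.shape}")
    return float(np.median(px[box.y:box.y2, box.x:box.x2]))


def intensity_difference(abdomen_median: float, foot_median: float) -> float:
    """Abdomen-minus-foot intensity deficit in raw 8-bit units."""
    return float(abdomen_median) - float(foot_median)


def cpd_percent(abdomen_median: float, foot_median: float) -> float:
    """CPD as a percentage of the abdomen median.

    Undefined (raises :class:`UndefinedCPDError`) when the abdomen median is
    not positive.
    """
    if abdomen_median <= 0:
        raise UndefinedCPDError(
            f"abdomen median must be > 0, got {abdomen_median}")
    return intensity_difference(abdomen_median, foot_median) / abdomen_median * 100.0


def _record(img: ThermalImage, gray, abd_box, foot_box, source,
            abd_score=float("nan"), foot_score=float("nan")) -> CPDRecord:
    abd_med = median_intensity(gray, abd_box)
    foot_med = median_intensity(gray, foot_box)
    return CPDRecord(image_id=img.image_id, patient_id=img.patient_id,
                     timestamp=img.timestamp, abdomen_median=abd_med,
                     foot_median=foot_med,
                     cpd_percent=cpd_percent(abd_med, foot_med), source=source,
                     abdomen_box=abd_box, foot_box=foot_box,
                     abdomen_score=abd_score, foot_score=foot_score)


def extract_cpd(img: ThermalImage, abd_model: ForestModel,
                foot_model: ForestModel, use_prior_band: bool = True) -> CPDRecord:
    """Full automated chain: grayscale -> threshold -> CLAHE -> silhouette ->
    detect both ROIs -> medians on the raw grayscale -> CPD percent.

    Any stage failure is re-raised as :class:`StageError` carrying the stage
    name so batch callers can flag the record unusable.
    """
    def stage(name, fn):
        try:
            return fn()
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate with stage name
            raise StageError(name, str(exc)) from exc

    gray = stage("grayscale", lambda: to_grayscale(img))
    thresholded, enhanced = stage("preprocess", lambda: preprocess(gray))
    silhouette = stage("silhouette", lambda: estimate_silhouette(thresholded))
    det_abd = stage("detect_abdomen", lambda: detect_roi(
        enhanced, abd_model, silhouette, use_prior_band=use_prior_band))
    det_foot = stage("detect_foot", lambda: detect_roi(
        enhanced, foot_model, silhouette, use_prior_band=use_prior_band))
    return stage("cpd", lambda: _record(
        img, gray, det_abd.box, det_foot.box, "detected",
        det_abd.score, det_foot.score))


def extract_cpd_manual(img: ThermalImage, abdomen_box: BBox,
                       foot_box: BBox) -> CPDRecord:
    """Manual-box variant: same medians and formula, boxes supplied."""
    gray = to_grayscale(img)
    return _record(img, gray, abdomen_box, foot_box, "manual_box")


def records_to_frame(records) -> pd.DataFrame:
    """Tidy CPD table (one row per image) for persistence / modeling."""
    rows = []
    for r in records:
        rows.append({"image_id": r.image_id, "patient_id": r.patient_id,
                     "timestamp": r.timestamp,
                     "abdomen_median": r.abdomen_median,
                     "foot_median": r.foot_median,
                     "cpd_percent": r.cpd_percent, "source": r.source})
    return pd.DataFrame(rows, columns=["image_id", "patient_id", "timestamp",
                                       "abdomen_median", "foot_median",
                                       "cpd_percent", "source"])


def extract_cpd_batch(images, abd_model: ForestModel, foot_model: ForestModel,
                      use_prior_band: bool = True) -> pd.DataFrame:
    """Run :func:`extract_cpd` over many images; failures are logged and the
    row is flagged unusable (NaN CPD) rather than aborting the batch."""
    rows = []
    n_failed = 0
    for img in images:
        try:
            r = extract_cpd(img, abd_model, foot_model,
                            use_prior_band=use_prior_band)
            rows.append({"image_id": r.image_id, "patient_id": r.patient_id,
                         "timestamp": r.timestamp,
                         "abdomen_median": r.abdomen_median,
                         "foot_median": r.foot_median,
                         "cpd_percent": r.cpd_percent, "source": r.source,
                         "usable": True, "failed_stage": ""})
        except StageError as exc:
            n_failed += 1
            log.warning("CPD extraction failed for %s at stage %s: %s",
                        img.image_id, exc.stage, exc)
            rows.append({"image_id": img.image_id, "patient_id": img.patient_id,
                         "timestamp": img.timestamp,
                         "abdomen_median": np.nan, "foot_median": np.nan,
                         "cpd_percent": np.nan, "source": "detected",
                         "usable": False, "failed_stage": exc.stage})
    if n_failed:
        log.warning("CPD batch: %d/%d images unusable", n_failed, len(rows))
    return pd.DataFrame(rows)
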