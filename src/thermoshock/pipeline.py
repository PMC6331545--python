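"""End-to-end orchestration: simulate -> train -> detect -> extract -> label
-> fit -> evaluate.

These helpers wire the individual modules into the experiments the package
is validated on; they are also what ``scripts/acceptance.py`` and the CLI
drive.  Problem sizes default to the desk-scale study conditions (51
patients, ~5 frames each, 320x180 frames).
"""

from __future__ import annotations

import logging
from dataclasses import replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cpd import extract_cpd_batch, extract_cpd_manual, records_to_frame
from .detection import (DEFAULT_PATCH_SIDE, ForestModel, detect_roi,
                        estimate_silhouette, sample_negative_boxes,
                        train_classifier)
from .evaluation import EvalReport, repeated_evaluation, roc_auc
from .glmm import assemble_records
from .hog import hog_matrix
from .imaging import BBox, ThermalImage, extract_patch, iou, preprocess
from .labeling import DEFAULT_SIPA, build_shock_labels
from .synthetic import CohortSpec, SyntheticCohort, generate_cohort

log = logging.getLogger("thermoshock.pipeline")


def cohort_thermal_images(cohort: SyntheticCohort) -> List[ThermalImage]:
    return [ThermalImage(px, image_id=row.image_id, patient_id=row.patient_id,
                         timestamp=row.timestamp)
            for px, row in zip(cohort.images, cohort.meta.itertuples())]


def build_patch_dataset(cohort: SyntheticCohort, target_class: str,
                        seed: int = 0, neg_per_pos: int = 3,
                        patch_side: Optional[int] = None):
    """Positive truth-box crops + random negatives (IoU < 0.2 vs any truth).

    Patches are cropped from the preprocessed (threshold + CLAHE) raster,
    identically to how detection windows are scored.  Returns
    ``(patches, labels, image_ids)``.
    """
    if patch_side is None:
        patch_side = DEFAULT_PATCH_SIDE.get(target_class, 50)
    rng = np.random.default_rng(seed)
    patches, labels, image_ids = [], [], []
    for px, row in zip(cohort.images, cohort.meta.itertuples()):
        _, enhanced = preprocess(px)
        pos_boxes = cohort.truth_boxes(row.image_id, target_class)
        all_boxes = cohort.truth_boxes(row.image_id)
        for b in pos_boxes:
            patches.append(extract_patch(enhanced, b, patch_side))
            labels.append(1)
            image_ids.append(row.image_id)
        sides = [b.w for b in pos_boxes] or [patch_side]
        lo = max(8, int(0.7 * min(sides)))
        hi = max(lo + 1, int(1.3 * max(sides)))
        for b in sample_negative_boxes(px.shape, all_boxes,
                                       neg_per_pos * len(pos_boxes), rng,
                                       side_range=(lo, hi)):
            patches.append(extract_patch(enhanced, b, patch_side))
            labels.append(0)
            image_ids.append(row.image_id)
    return patches, np.asarray(labels), image_ids


def train_detectors(cohort: SyntheticCohort, seed: int = 0,
                    trees: Optional[Dict[str, int]] = None
                    ) -> Dict[str, ForestModel]:
    """Train abdomen and foot forests on a (training) cohort's patches."""
    models = {}
    for cls in ("abdomen", "foot"):
        patches, labels, _ = build_patch_dataset(cohort, cls, seed=seed)
        n_trees = (trees or {}).get(cls)
        models[cls] = train_classifier(patches, labels, target_class=cls,
                                       n_trees=n_trees, seed=seed)
    return models


def detect_cohort(cohort: SyntheticCohort, models: Dict[str, ForestModel],
                  use_prior_band: bool = True) -> pd.DataFrame:
    """Run both detectors over every frame; one row per (image, class)."""
    rows = []
    for px, row in zip(cohort.images, cohort.meta.itertuples()):
        thresholded, enhanced = preprocess(px)
        sil = estimate_silhouette(thresholded)
        for cls, model in models.items():
            det = detect_roi(enhanced, model, sil, use_prior_band=use_prior_band)
            truths = cohort.truth_boxes(row.image_id, cls)
            best_iou = max((iou(det.box, t) for t in truths), default=np.nan)
            rows.append({"image_id": row.image_id, "class": cls,
                         "x": det.box.x, "y": det.box.y, "w": det.box.w,
                         "h": det.box.h, "score": det.score,
                         "iou_truth": best_iou})
    return pd.DataFrame(rows)


def run_detection_experiment(seed: int = 0, n_train_patients: int = 12,
                             n_eval_patients: int = 10,
                             spec: Optional[CohortSpec] = None) -> dict:
    """Detector validation: held-out patch AUC and detection IoU.

    Trains on one synthetic cohort (patch-level 70/30 image-wise split for
    the held-out AUC), then localizes ROIs on a fresh cohort and scores
    IoU against planted truth.  Returns the metrics plus the final models.
    """
    base = spec or CohortSpec()
    train_spec = replace(base, n_patients=n_train_patients, seed=seed)
    eval_spec = replace(base, n_patients=n_eval_patients, seed=seed + 1)
    train_cohort = generate_cohort(train_spec)
    eval_cohort = generate_cohort(eval_spec)

    out = {"seed": seed}
    models = {}
    rng = np.random.default_rng(seed)
    for cls in ("abdomen", "foot"):
        patches, labels, image_ids = build_patch_dataset(train_cohort, cls,
                                                         seed=seed)
        uniq = sorted(set(image_ids))
        perm = rng.permutation(len(uniq))
        heldout = {uniq[i] for i in perm[:max(1, int(0.3 * len(uniq)))]}
        tr = [i for i, im in enumerate(image_ids) if im not in heldout]
        te = [i for i, im in enumerate(image_ids) if im in heldout]
        m = train_classifier([patches[i] for i in tr], labels[tr],
                             target_class=cls, seed=seed)
        out[f"patch_auc_{cls}"] = roc_auc(
            m.score_patches([patches[i] for i in te]), labels[te])
        out[f"n_patches_{cls}"] = len(patches)
        # final model for localization uses every patch
        models[cls] = train_classifier(patches, labels, target_class=cls,
                                       seed=seed)
    det = detect_cohort(eval_cohort, models)
    for cls in ("abdomen", "foot"):
        out[f"median_iou_{cls}"] = float(
            det[det["class"] == cls]["iou_truth"].median())
    out["n_eval_images"] = eval_cohort.n_images
    out["models"] = models
    out["detections"] = det
    return out


def extract_cohort_cpd(cohort: SyntheticCohort,
                       models: Optional[Dict[str, ForestModel]] = None
                       ) -> pd.DataFrame:
    """CPD table for a cohort: detected path if models given, else truth-box
    (manual) path."""
    if models is not None:
        return extract_cpd_batch(cohort_thermal_images(cohort),
                                 models["abdomen"], models["foot"])
    records = []
    for img, row in zip(cohort_thermal_images(cohort), cohort.meta.itertuples()):
        abd = cohort.truth_boxes(row.image_id, "abdomen")[0]
        foot = cohort.truth_boxes(row.image_id, "foot")[0]
        records.append(extract_cpd_manual(img, abd, foot))
    df = records_to_frame(records)
    df["usable"] = True
    return df


def run_end_to_end(seed: int = 0, spec: Optional[CohortSpec] = None,
                   horizons: Sequence[int] = (0, 3, 6, 12),
                   n_rep: int = 10,
                   models: Optional[Dict[str, ForestModel]] = None) -> dict:
    """The full synthetic experiment, mirroring the study design.

    Detectors are trained on a disjoint synthetic training cohort, applied
    to the study-scale cohort; CPD + imaging-time pulse rate + age feed the
    mixed model; performance is summarized over patient-wise partitions.
    """
    study_spec = replace(spec or CohortSpec(), seed=seed)
    cohort = generate_cohort(study_spec)
    if models is None:
        train_cohort = generate_cohort(
            replace(study_spec, n_patients=12, seed=seed + 1000))
        models = train_detectors(train_cohort, seed=seed)
    cpd_df = extract_cohort_cpd(cohort, models)
    labels = build_shock_labels(cohort.vitals, cohort.meta)
    reports: Dict[int, EvalReport] = {}
    for h in horizons:
        records = assemble_records(cpd_df, labels, horizon=h)
        reports[h] = repeated_evaluation(records, n_rep=n_rep, seed=seed)
    return {"cohort": cohort, "models": models, "cpd": cpd_df,
            "labels": labels, "reports": reports}


def run_null_experiment(seed: int = 0, n_patients: int = 51,
                        n_rep: int = 10) -> EvalReport:
    """Negative control: no planted CPD effect, no vitals-outcome link.

    CPD means are equalized across states, vitals are drawn from the
    non-shock distribution regardless of state, and the outcome is the
    planted (now information-free) shock state itself — so every covariate
    is independent of the outcome and the evaluated AUC should sit at 0.5.
    Truth-box CPD is used: the control targets the modeling chain.
    """
    spec = CohortSpec(n_patients=n_patients, seed=seed,
                      cpd_shock_mean=19.56, cpd_shock_sd=23.48,
                      hr_shock_mean=120.75, hr_shock_sd=24.53,
                      sbp_shock_mean=97.55, sbp_shock_sd=21.81)
    cohort = generate_cohort(spec)
    cpd_df = extract_cohort_cpd(cohort, models=None)
    labels = build_shock_labels(cohort.vitals, cohort.meta)
    pulse0 = labels[labels.horizon_h == 0][["image_id", "pulse_rate_median"]]
    records = cpd_df.merge(cohort.meta[["image_id", "age_months", "shock_0h"]],
                           on="image_id")
    records = records.merge(pulse0, on="image_id")
    records = records.rename(columns={"shock_0h": "outcome",
                                      "pulse_rate_median": "pulse_rate"})
    records["horizon"] = 0
    return repeated_evaluation(records, n_rep=n_rep, seed=seed)
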