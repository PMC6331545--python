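"""Patient-wise repeated-partition evaluation.

Repeated images from one child must never straddle the train/test boundary,
so partitions are drawn over patient IDs (70/30 by default, ten replicates).
Each replicate fits the mixed model on the training patients, freezes the
operating cutoff at the training-set Youden point (no test-set leakage), and
reports AUROC, accuracy, sensitivity, specificity, PPV and NPV on the test
patients.  The report carries per-replicate values plus mean and standard
error (sd / sqrt(effective replicates)) per metric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .glmm import fit_glmm, predict_risk

log = logging.getLogger("thermoshock.evaluation")

METRICS = ("auc", "accuracy", "sensitivity", "specificity", "ppv", "npv")


@dataclass(frozen=True)
class Partition:
    """One patient-disjoint train/test split."""

    replicate: int
    train_patients: frozenset
    test_patients: frozenset
    seed: int

    def __post_init__(self):
        if self.train_patients & self.test_patients:
            raise ValueError(
                "contaminated partition: patients "
                f"{sorted(self.train_patients & self.test_patients)} appear "
                "in both train and test sets")
        if not self.train_patients or not self.test_patients:
            raise ValueError("both sides of a partition must be nonempty")


def patientwise_partitions(patient_ids: Sequence, train_frac: float = 0.7,
                           n_rep: int = 10, seed: int = 0) -> List[Partition]:
    """``n_rep`` random patient-level splits, deterministic given ``seed``."""
    ids = sorted(set(patient_ids))
    if len(ids) < 2:
        raise ValueError("need >= 2 patients to partition")
    n_train = int(np.ceil(train_frac * len(ids)))
    n_train = min(n_train, len(ids) - 1)  # keep the test side nonempty
    rng = np.random.default_rng(seed)
    parts = []
    for r in range(n_rep):
        perm = rng.permutation(len(ids))
        train = frozenset(ids[i] for i in perm[:n_train])
        test = frozenset(ids[i] for i in perm[n_train:])
        parts.append(Partition(replicate=r, train_patients=train,
                               test_patients=test, seed=seed))
    return parts


def roc_auc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties ½)."""
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("roc_auc needs both classes present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    s = np.unique(scores)
    mids = (s[:-1] + s[1:]) / 2.0 if len(s) > 1 else np.empty(0)
    return np.concatenate(([-np.inf], mids, [np.inf]))


def youden_threshold(scores, labels) -> float:
    """Cutoff maximizing J = Se(c) + Sp(c) - 1 (prediction: score >= c).

    Candidates are midpoints between adjacent distinct scores plus ±inf;
    ties in J break to the smallest cutoff.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("youden_threshold needs both classes present")
    pos, neg = s[y == 1], s[y == 0]
    best_c, best_j = None, -np.inf
    for c in _candidate_cutoffs(s):
        se = np.mean(pos >= c)
        sp = np.mean(neg < c)
        j = se + sp - 1.0
        if j > best_j:  # strict: equal J keeps the smaller cutoff
            best_c, best_j = c, j
    return float(best_c)


def metrics_at_threshold(scores, labels, cutoff: float) -> Dict[str, float]:
    """Confusion-matrix rates at ``score >= cutoff``; undefined ratios are NaN."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.size == 0:
        raise ValueError("empty inputs")
    pred = s >= cutoff
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    return {"accuracy": ratio(tp + tn, tp + fp + fn + tn),
            "sensitivity": ratio(tp, tp + fn),
            "specificity": ratio(tn, tn + fp),
            "ppv": ratio(tp, tp + fp),
            "npv": ratio(tn, tn + fn)}


@dataclass
class EvalReport:
    """Repeated-partition performance summary (one horizon)."""

    horizon: int
    n_nonshock: int
    n_shock: int
    n_replicates: int
    n_effective: int
    per_replicate: pd.DataFrame  # columns: replicate, cutoff, coeff_cpd, metrics
    mean: Dict[str, float]
    se: Dict[str, float]
    mean_cutoff: float
    mean_coeff_cpd: float

    def to_row(self) -> Dict[str, object]:
        row = {"horizon_h": self.horizon, "n_nonshock": self.n_nonshock,
               "n_shock": self.n_shock, "coeff": self.mean_coeff_cpd,
               "cutoff": self.mean_cutoff, "n_effective": self.n_effective}
        for m in METRICS:
            row[f"{m}_mean"] = self.mean[m]
            row[f"{m}_se"] = self.se[m]
        return row

    def to_json(self, path=None) -> str:
        payload = {k: (v if not isinstance(v, float) or np.isfinite(v) else None)
                   for k, v in self.to_row().items()}
        payload["per_replicate"] = self.per_replicate.to_dict(orient="records")
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def repeated_evaluation(records: pd.DataFrame, n_rep: int = 10,
                        train_frac: float = 0.7, seed: int = 0,
                        n_quad: int = 15,
                        partitions: Optional[List[Partition]] = None) -> EvalReport:
    """Fit/score the mixed model over repeated patient-wise partitions.

    Every partition is re-validated for patient disjointness before use.  A
    replicate whose training side has a single outcome class (or whose fit
    does not converge) is skipped with a logged warning; the report states
    the effective replicate count.
    """
    horizon = int(records["horizon"].iloc[0]) if "horizon" in records.columns else -1
    if partitions is None:
        partitions = patientwise_partitions(records["patient_id"],
                                            train_frac=train_frac,
                                            n_rep=n_rep, seed=seed)
    all_patients = set(records["patient_id"])
    rows = []
    for part in partitions:
        # leakage guard: disjointness is re-asserted on every run
        overlap = part.train_patients & part.test_patients
        if overlap:
            raise ValueError(f"contaminated partition: {sorted(overlap)}")
        train = records[records.patient_id.isin(part.train_patients)]
        test = records[records.patient_id.isin(part.test_patients)]
        assert not (set(train.patient_id) & set(test.patient_id))
        if part.train_patients | part.test_patients != all_patients:
            log.warning("replicate %d: partition does not cover all patients",
                        part.replicate)
        if train["outcome"].nunique() < 2:
            log.warning("replicate %d skipped: single-class training set",
                        part.replicate)
            continue
        if test["outcome"].nunique() < 2:
            log.warning("replicate %d skipped: single-class test set "
                        "(AUC undefined)", part.replicate)
            continue
        fit = fit_glmm(train, horizon=horizon, n_quad=n_quad)
        if not fit.converged:
            log.warning("replicate %d skipped: %s", part.replicate, fit.message)
            continue
        train_scores = predict_risk(fit, train)
        cutoff = youden_threshold(train_scores, train["outcome"])
        test_scores = predict_risk(fit, test)
        m = metrics_at_threshold(test_scores, test["outcome"], cutoff)
        m["auc"] = roc_auc(test_scores, test["outcome"])
        rows.append({"replicate": part.replicate, "cutoff": cutoff,
                     "coeff_cpd": fit.coef("cpd_percent"), **m})

    per_rep = pd.DataFrame(rows)
    n_eff = len(per_rep)
    if n_eff == 0:
        raise ValueError("no usable replicate (all skipped)")
    mean = {m: float(np.nanmean(per_rep[m])) for m in METRICS}
    se = {m: (float(np.nanstd(per_rep[m], ddof=1) / np.sqrt(n_eff))
              if n_eff > 1 else float("nan")) for m in METRICS}
    n_shock = int((records["outcome"] == 1).sum())
    return EvalReport(horizon=horizon, n_nonshock=len(records) - n_shock,
                      n_shock=n_shock, n_replicates=len(partitions),
                      n_effective=n_eff, per_replicate=per_rep, mean=mean,
                      se=se, mean_cutoff=float(np.mean(per_rep["cutoff"])),
                      mean_coeff_cpd=float(np.mean(per_rep["coeff_cpd"])))
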