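"""Abdomen / foot ROI detection: forest patch classifiers + adaptive windows.

A random forest scores HOG descriptors of candidate windows; window size is
set proportional to the body-silhouette height so detection is
scale-invariant, and the search is restricted to anatomically plausible
bands (upper silhouette half for the abdomen, lower third for the feet —
both configurable, matching the supine, head-up framing).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence

import joblib
import numpy as np
from skimage.measure import label as _cc_label, regionprops
from sklearn.ensemble import RandomForestClassifier

from .errors import EmptySilhouetteError
from .hog import HOGParams, compute_hog, hog_matrix
from .imaging import BBox, extract_patch, iou

log = logging.getLogger("thermoshock.detection")

#: tree counts tuned by out-of-bag error in the original pipeline
DEFAULT_TREES: Dict[str, int] = {"abdomen": 310, "foot": 160}
#: classifier input patch side per class (pad-to-square then resize)
DEFAULT_PATCH_SIDE: Dict[str, int] = {"abdomen": 50, "foot": 100}
#: window side as a fraction of silhouette height
DEFAULT_WINDOW_FACTOR: Dict[str, float] = {"abdomen": 0.30, "foot": 0.18}
#: vertical search band within the silhouette, as (top, bottom) fractions
DEFAULT_SEARCH_BAND: Dict[str, tuple] = {"abdomen": (0.0, 0.5),
                                         "foot": (2.0 / 3.0, 1.0)}
DEFAULT_SCALES = (0.8, 1.0, 1.2)

MODEL_FORMAT_VERSION = 1


@dataclass
class ForestModel:
    """A trained patch classifier plus its feature recipe."""

    target_class: str
    clf: RandomForestClassifier
    patch_side: int
    hog_params: HOGParams
    n_trees: int
    seed: int
    oob_error: float
    window_factor: float

    def score_patches(self, patches: Sequence[np.ndarray]) -> np.ndarray:
        """Probability of the target class for each patch."""
        X = hog_matrix(patches, self.hog_params)
        proba = self.clf.predict_proba(X)
        pos = list(self.clf.classes_).index(1)
        return proba[:, pos]

    def save(self, path) -> None:
        joblib.dump({"format_version": MODEL_FORMAT_VERSION,
                     "target_class": self.target_class, "clf": self.clf,
                     "patch_side": self.patch_side, "hog_params": self.hog_params,
                     "n_trees": self.n_trees, "seed": self.seed,
                     "oob_error": self.oob_error,
                     "window_factor": self.window_factor}, path)

    @classmethod
    def load(cls, path) -> "ForestModel":
        d = joblib.load(path)
        if d.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format in {path}")
        d.pop("format_version")
        return cls(**d)


@dataclass(frozen=True)
class Detection:
    target_class: str
    box: BBox
    score: float


def train_classifier(patches: Sequence[np.ndarray], labels: Sequence[int],
                     target_class: str, n_trees: Optional[int] = None,
                     seed: int = 0, hog_params: HOGParams = HOGParams(),
                     patch_side: Optional[int] = None,
                     window_factor: Optional[float] = None) -> ForestModel:
    """Fit a random-forest patch classifier on HOG features.

    ``labels`` are 1 for the target class, 0 otherwise; both classes must be
    present.  The out-of-bag error is recorded for tuning/inspection.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    if n_trees is None:
        n_trees = DEFAULT_TREES.get(target_class, 300)
    if patch_side is None:
        patch_side = DEFAULT_PATCH_SIDE.get(target_class, 50)
    if window_factor is None:
        window_factor = DEFAULT_WINDOW_FACTOR.get(target_class, 0.25)
    sides = {p.shape for p in patches}
    if len(sides) != 1:
        raise ValueError(f"patches must share one size, got {sides}")
    X = hog_matrix(patches, hog_params)
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed,
                                 oob_score=True, n_jobs=1)
    clf.fit(X, y)
    oob_error = 1.0 - float(clf.oob_score_)
    log.info("trained %s forest: %d trees, %d patches, OOB error %.4f",
             target_class, n_trees, len(y), oob_error)
    return ForestModel(target_class=target_class, clf=clf,
                       patch_side=int(patches[0].shape[0]),
                       hog_params=hog_params, n_trees=n_trees, seed=seed,
                       oob_error=oob_error, window_factor=window_factor)


def tune_forest(patches: Sequence[np.ndarray], labels: Sequence[int],
                tree_grid: Sequence[int], seed: int = 0,
                hog_params: HOGParams = HOGParams()) -> int:
    """Pick the tree count minimizing out-of-bag error (ties -> smallest)."""
    grid = sorted(set(int(n) for n in tree_grid))
    if not grid:
        raise ValueError("tree_grid must be nonempty")
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = hog_matrix(patches, hog_params)
    best_n, best_err = None, np.inf
    for n in grid:
        clf = RandomForestClassifier(n_estimators=n, random_state=seed,
                                     oob_score=True, n_jobs=1)
        clf.fit(X, y)
        err = 1.0 - float(clf.oob_score_)
        log.debug("tune_forest: %d trees -> OOB error %.4f", n, err)
        if err < best_err:  # strict: equal error keeps the smaller grid member
            best_n, best_err = n, err
    return best_n


def estimate_silhouette(thresholded: np.ndarray) -> BBox:
    """Bounding box of the largest 8-connected nonzero component.

    Input must already be median-thresholded (background mostly zeroed).
    Area ties break to the topmost-leftmost component.
    """
    mask = np.asarray(thresholded) > 0
    if not mask.any():
        raise EmptySilhouetteError("no nonzero pixels in thresholded image")
    lab = _cc_label(mask, connectivity=2)
    props = regionprops(lab)
    best = max(props, key=lambda p: (p.area, -p.bbox[0], -p.bbox[1]))
    y1, x1, y2, x2 = best.bbox
    return BBox(int(x1), int(y1), int(x2 - x1), int(y2 - y1))


def candidate_windows(silhouette: BBox, image_shape, window_factor: float,
                      band: tuple, scales: Sequence[float] = DEFAULT_SCALES,
                      stride_frac: float = 0.25) -> List[BBox]:
    """Silhouette-proportional sliding windows inside a vertical band."""
    H, W = image_shape[:2]
    base = window_factor * silhouette.h
    out: List[BBox] = []
    y_lo = silhouette.y + band[0] * silhouette.h
    y_hi = silhouette.y + band[1] * silhouette.h
    for s in scales:
        side = int(round(base * s))
        if side < 2 or side > min(H, W):
            continue
        stride = max(1, int(round(side * stride_frac)))
        ys = np.arange(int(round(y_lo)), int(round(y_hi)) - side + 1, stride)
        if ys.size == 0:  # band shorter than the window: center it
            yc = int(round((y_lo + y_hi) / 2 - side / 2))
            ys = np.array([min(max(yc, 0), H - side)])
        xs = np.arange(silhouette.x, silhouette.x2 - side + 1, stride)
        if xs.size == 0:
            xc = int(round(silhouette.x + silhouette.w / 2 - side / 2))
            xs = np.array([min(max(xc, 0), W - side)])
        for y in ys:
            y = min(max(int(y), 0), H - side)
            for x in xs:
                x = min(max(int(x), 0), W - side)
                out.append(BBox(x, y, side, side))
    # dedupe while preserving sweep order (clamping can create repeats)
    seen, uniq = set(), []
    for b in out:
        key = (b.x, b.y, b.w)
        if key not in seen:
            seen.add(key)
            uniq.append(b)
    return uniq


def detect_roi(enhanced: np.ndarray, model: ForestModel, silhouette: BBox,
               scales: Sequence[float] = DEFAULT_SCALES,
               use_prior_band: bool = True) -> Detection:
    """Best-scoring adaptive window for the model's target class.

    ``enhanced`` is the thresholded+CLAHE raster from
    :func:`thermoshock.imaging.preprocess`; every candidate window is
    pad/resized to the model's patch side and scored by the forest.  Returns
    the argmax window (no non-maximum suppression: one ROI per image).
    """
    if not silhouette.within(enhanced.shape):
        raise ValueError("silhouette box extends outside the image")
    band = (DEFAULT_SEARCH_BAND[model.target_class]
            if use_prior_band and model.target_class in DEFAULT_SEARCH_BAND
            else (0.0, 1.0))
    wins = candidate_windows(silhouette, enhanced.shape, model.window_factor,
                             band, scales)
    min_side = model.hog_params.cell_side * model.hog_params.block_cells
    wins = [b for b in wins if min(b.w, b.h) >= 4]
    if not wins:
        raise EmptySilhouetteError(
            f"silhouette {silhouette} too small to host a "
            f"{model.target_class} window (needs >= {min_side}px after resize)")
    patches = [extract_patch(enhanced, b, model.patch_side) for b in wins]
    scores = model.score_patches(patches)
    k = int(np.argmax(scores))
    return Detection(model.target_class, wins[k], float(scores[k]))


def sample_negative_boxes(image_shape, truth_boxes: Sequence[BBox],
                          n: int, rng: np.random.Generator,
                          side_range: tuple, max_iou: float = 0.2,
                          max_tries: int = 2000) -> List[BBox]:
    """Random crops overlapping every truth box by IoU < ``max_iou``."""
    H, W = image_shape[:2]
    out: List[BBox] = []
    tries = 0
    while len(out) < n and tries < max_tries:
        tries += 1
        side = int(rng.integers(side_range[0], side_range[1] + 1))
        side = min(side, H - 1, W - 1)
        if side < 8:
            continue
        x = int(rng.integers(0, W - side + 1))
        y = int(rng.integers(0, H - side + 1))
        b = BBox(x, y, side, side)
        if all(iou(b, t) < max_iou for t in truth_boxes):
            out.append(b)
    return out
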