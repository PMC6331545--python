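import numpy as np
import pytest

from thermoshock.detection import (Detection, ForestModel,
                                   estimate_silhouette, sample_negative_boxes,
                                   train_classifier, tune_forest)
from thermoshock.errors import EmptySilhouetteError
from thermoshock.hog import HOGParams, hog_matrix
from thermoshock.imaging import BBox, iou
from sklearn.ensemble import RandomForestClassifier


def blob_patches(rng, n, side=32, positive=True):
    """Synthetic patches: bright centered disc (positive) vs random speckle."""
    out = []
    yy, xx = np.mgrid[0:side, 0:side]
    for _ in range(n):
        if positive:
            r = rng.uniform(side * 0.25, side * 0.4)
            img = np.where((yy - side / 2) ** 2 + (xx - side / 2) ** 2 < r * r,
                           200.0, 30.0)
        else:
            img = rng.uniform(20, 210, size=(side, side))
        img += rng.normal(0, 6, size=(side, side))
        out.append(np.clip(img, 0, 255).astype(np.uint8))
    return out


class TestTrainClassifier:
    def test_default_tree_counts_per_class(self, rng):
        pos, neg = blob_patches(rng, 8), blob_patches(rng, 8, positive=False)
        m_abd = train_classifier(pos + neg, [1] * 8 + [0] * 8, "abdomen", seed=0)
        m_foot = train_classifier(pos + neg, [1] * 8 + [0] * 8, "foot", seed=0)
        assert m_abd.n_trees == 310
        assert m_foot.n_trees == 160

    def test_separable_patches_perfect_training_auc(self, rng):
        pos, neg = blob_patches(rng, 15), blob_patches(rng, 15, positive=False)
        m = train_classifier(pos + neg, [1] * 15 + [0] * 15, "abdomen",
                             n_trees=60, seed=0)
        scores = m.score_patches(pos + neg)
        assert (scores[:15].min() > scores[15:].max())

    def test_single_class_rejected(self, rng):
        pos = blob_patches(rng, 6)
        with pytest.raises(ValueError, match="both classes"):
            train_classifier(pos, [1] * 6, "abdomen")

    def test_permuted_labels_oob_near_chance(self, rng):
        """Permutation null: shuffled labels leave nothing to learn, so OOB
        accuracy hovers at the class-prior frequency."""
        pos, neg = blob_patches(rng, 30), blob_patches(rng, 30, positive=False)
        accs = []
        for rep in range(20):
            labels = np.array([1] * 30 + [0] * 30)
            rng.shuffle(labels)
            m = train_classifier(pos + neg, labels, "abdomen", n_trees=60,
                                 seed=rep)
            accs.append(1.0 - m.oob_error)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_deterministic_given_seed(self, rng):
        pos, neg = blob_patches(rng, 10), blob_patches(rng, 10, positive=False)
        labels = [1] * 10 + [0] * 10
        m1 = train_classifier(pos + neg, labels, "foot", n_trees=50, seed=3)
        m2 = train_classifier(pos + neg, labels, "foot", n_trees=50, seed=3)
        np.testing.assert_array_equal(m1.score_patches(pos),
                                      m2.score_patches(pos))


class TestTuneForest:
    def test_result_in_grid_and_singleton(self, rng):
        pos, neg = blob_patches(rng, 12), blob_patches(rng, 12, positive=False)
        labels = [1] * 12 + [0] * 12
        assert tune_forest(pos + neg, labels, [40], seed=0) == 40
        assert tune_forest(pos + neg, labels, [20, 40, 80], seed=0) in (20, 40, 80)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="nonempty"):
            tune_forest(blob_patches(rng, 2) * 2, [1, 1, 0, 0], [])

    def test_selection_matches_direct_oob_scan_with_tie_rule(self, rng):
        """Oracle: recompute OOB error per grid member directly; the tuner
        must return the smallest member attaining the minimum."""
        pos = blob_patches(rng, 20)
        neg = blob_patches(rng, 20, positive=False)
        noisy = pos + neg
        labels = np.array([1] * 20 + [0] * 20)
        flip = rng.random(40) < 0.25  # noise -> OOB error plateaus
        labels[flip] = 1 - labels[flip]
        grid = [30, 60, 120]
        X = hog_matrix(noisy, HOGParams())
        errs = {}
        for n in grid:
            clf = RandomForestClassifier(n_estimators=n, random_state=0,
                                         oob_score=True, n_jobs=1)
            clf.fit(X, labels)
            errs[n] = 1.0 - clf.oob_score_
        expected = min(grid, key=lambda n: (errs[n], n))
        assert tune_forest(noisy, labels, grid, seed=0) == expected


class TestSilhouette:
    def test_single_rectangle_exact_bounds(self):
        img = np.zeros((40, 60), dtype=np.uint8)
        img[5:25, 10:30] = 200
        assert estimate_silhouette(img) == BBox(10, 5, 20, 20)

    def test_larger_of_two_components_wins(self):
        img = np.zeros((40, 60), dtype=np.uint8)
        img[2:12, 2:12] = 100       # area 100
        img[20:24, 40:45] = 100     # area 20
        assert estimate_silhouette(img) == BBox(2, 2, 10, 10)

    def test_all_zero_raises(self):
        with pytest.raises(EmptySilhouetteError):
            estimate_silhouette(np.zeros((10, 10), dtype=np.uint8))


class TestDetectROI:
    def test_oracle_model_returns_planted_box(self, small_cohort, trained_models):
        """Consistency: the detection score is the forest probability of the
        returned patch, and a well-trained model localizes the truth region."""
        from thermoshock.detection import detect_roi
        from thermoshock.imaging import preprocess
        px = small_cohort.images[0]
        row = small_cohort.meta.iloc[0]
        thresholded, enhanced = preprocess(px)
        sil = estimate_silhouette(thresholded)
        det = detect_roi(enhanced, trained_models["abdomen"], sil)
        assert 0.0 <= det.score <= 1.0
        from thermoshock.imaging import extract_patch
        patch = extract_patch(enhanced, det.box,
                              trained_models["abdomen"].patch_side)
        re_score = trained_models["abdomen"].score_patches([patch])[0]
        assert det.score == pytest.approx(re_score)

    def test_detection_quality_on_fresh_images(self, detection_experiment):
        """Held-out patch AUC and median IoU on a fresh synthetic cohort."""
        exp = detection_experiment
        assert exp["patch_auc_abdomen"] >= 0.9
        assert exp["patch_auc_foot"] >= 0.9
        assert exp["median_iou_abdomen"] >= 0.5
        assert exp["median_iou_foot"] >= 0.5

    def test_scale_robustness(self, trained_models):
        """Same subject rendered at 1x and 1.5x: detection IoU against the
        (scaled) truth must agree within 0.15."""
        import pandas as pd
        from thermoshock.detection import detect_roi
        from thermoshock.imaging import preprocess
        from thermoshock.synthetic import (CohortSpec, SubjectImageState,
                                           render_image)
        diffs = []
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            ious = {}
            for scale, size in ((1.0, (320, 180)), (1.5, (480, 270))):
                spec = CohortSpec(image_height=size[0], image_width=size[1],
                                  seed=0)
                state = SubjectImageState(
                    patient_id="P0", age_months=30.0,
                    timestamp=pd.Timestamp("2016-05-01"),
                    shock={0: 0, 3: 0, 6: 0, 12: 0}, planted_cpd=22.0,
                    body_scale=0.85, abdomen_level=165.0,
                    background_level=60.0)
                px, boxes = render_image(state, spec,
                                         np.random.default_rng(seed))
                thresholded, enhanced = preprocess(px)
                sil = estimate_silhouette(thresholded)
                det = detect_roi(enhanced, trained_models["abdomen"], sil)
                ious[scale] = max(iou(det.box, t) for t in boxes["abdomen"])
            diffs.append(abs(ious[1.0] - ious[1.5]))
        assert np.median(diffs) <= 0.15

    def test_model_round_trip(self, tmp_path, trained_models, small_cohort):
        from thermoshock.imaging import preprocess
        from thermoshock.detection import detect_roi
        path = tmp_path / "abd.joblib"
        trained_models["abdomen"].save(path)
        loaded = ForestModel.load(path)
        px = small_cohort.images[1]
        thresholded, enhanced = preprocess(px)
        sil = estimate_silhouette(thresholded)
        d1 = detect_roi(enhanced, trained_models["abdomen"], sil)
        d2 = detect_roi(enhanced, loaded, sil)
        assert d1.box == d2.box and d1.score == pytest.approx(d2.score)


class TestNegativeSampling:
    def test_negatives_respect_iou_ceiling(self, rng):
        truth = [BBox(40, 40, 30, 30)]
        boxes = sample_negative_boxes((120, 120), truth, 25, rng, (20, 40))
        assert len(boxes) == 25
        assert all(iou(b, truth[0]) < 0.2 for b in boxes)
        assert all(b.within((120, 120)) for b in boxes)
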