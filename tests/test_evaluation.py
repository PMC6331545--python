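import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from thermoshock.evaluation import (Partition, metrics_at_threshold,
                                    patientwise_partitions,
                                    repeated_evaluation, roc_auc,
                                    youden_threshold)


def pair_count_auc(scores, labels):
    """Brute-force oracle: fraction of positive-negative pairs correctly
    ordered, ties counted one half."""
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    pos, neg = s[y == 1], s[y == 0]
    total, wins = 0, 0.0
    for p, n in itertools.product(pos, neg):
        total += 1
        wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / total


def exhaustive_youden(scores, labels):
    s = np.asarray(scores, float)
    y = np.asarray(labels)
    uniq = np.unique(s)
    cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2, [np.inf]))
    best_c, best_j = None, -np.inf
    for c in cands:
        se = np.mean(s[y == 1] >= c)
        sp = np.mean(s[y == 0] < c)
        if se + sp - 1 > best_j:
            best_c, best_j = c, se + sp - 1
    return best_c, best_j


class TestPartitions:
    def test_seventy_thirty_split_of_ten(self):
        parts = patientwise_partitions([f"P{i}" for i in range(10)], seed=0)
        assert len(parts) == 10
        for p in parts:
            assert len(p.train_patients) == 7 and len(p.test_patients) == 3
            assert not p.train_patients & p.test_patients
            assert p.train_patients | p.test_patients == {
                f"P{i}" for i in range(10)}

    def test_deterministic_given_seed(self):
        ids = [f"P{i}" for i in range(17)]
        a = patientwise_partitions(ids, seed=5)
        b = patientwise_partitions(ids, seed=5)
        assert [(p.train_patients, p.test_patients) for p in a] == \
               [(p.train_patients, p.test_patients) for p in b]

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            patientwise_partitions(["P0"], seed=0)

    def test_contaminated_partition_raises(self):
        """Leakage guard: overlapping train/test patient sets are an error."""
        with pytest.raises(ValueError, match="contaminated"):
            Partition(replicate=0, train_patients=frozenset({"A", "B"}),
                      test_patients=frozenset({"B", "C"}), seed=0)

    def test_contaminated_partition_rejected_by_evaluation(self):
        rng = np.random.default_rng(0)
        records = pd.DataFrame({
            "patient_id": np.repeat([f"P{i}" for i in range(6)], 4),
            "cpd_percent": rng.normal(15, 10, 24),
            "age_months": rng.uniform(1, 100, 24),
            "pulse_rate": rng.normal(120, 15, 24),
            "outcome": rng.integers(0, 2, 24), "horizon": 0})
        # bypass the Partition validator to simulate a corrupted split
        bad = Partition.__new__(Partition)
        object.__setattr__(bad, "replicate", 0)
        object.__setattr__(bad, "train_patients", frozenset({"P0", "P1", "P2", "P3"}))
        object.__setattr__(bad, "test_patients", frozenset({"P3", "P4", "P5"}))
        object.__setattr__(bad, "seed", 0)
        with pytest.raises(ValueError, match="contaminated"):
            repeated_evaluation(records, partitions=[bad])


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert roc_auc([0.5] * 6, [1, 0, 1, 0, 1, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.integers(2, 12), st.integers(0, 10_000))
    def test_equals_pair_count_oracle(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(n), 2)  # coarse grid induces ties
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            return
        assert roc_auc(scores, labels) == pytest.approx(
            pair_count_auc(scores, labels))


class TestYouden:
    def test_separable_scores_midpoint(self):
        scores = [0.1, 0.2, 0.3, 0.7, 0.8, 0.9]
        labels = [0, 0, 0, 1, 1, 1]
        assert youden_threshold(scores, labels) == pytest.approx(0.5)

    @given(st.integers(3, 14), st.integers(0, 10_000))
    def test_matches_exhaustive_scan(self, n, seed):
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(n), 2)
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            return
        c = youden_threshold(scores, labels)
        c_ref, j_ref = exhaustive_youden(scores, labels)
        s, y = np.asarray(scores), np.asarray(labels)
        j_at_c = np.mean(s[y == 1] >= c) + np.mean(s[y == 0] < c) - 1
        assert j_at_c == pytest.approx(j_ref)
        assert c == pytest.approx(c_ref) or j_at_c == pytest.approx(j_ref)

    def test_anti_informative_scores_j_near_zero(self, rng):
        scores = rng.random(60)
        labels = (scores < np.median(scores)).astype(int)  # inverted
        c = youden_threshold(scores, labels)
        s, y = scores, labels
        j = np.mean(s[y == 1] >= c) + np.mean(s[y == 0] < c) - 1
        assert j <= 0.25  # no informative cutoff exists


class TestMetricsAtThreshold:
    def test_perfect_classifier_all_ones(self):
        m = metrics_at_threshold([0.9, 0.8, 0.1], [1, 1, 0], 0.5)
        assert all(m[k] == 1.0 for k in m)

    def test_hand_confusion_matrix(self):
        # TP=3, FP=1, FN=1, TN=5
        scores = [0.9, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.15, 0.1, 0.05]
        labels = [1, 1, 1, 0, 1, 0, 0, 0, 0, 0]
        m = metrics_at_threshold(scores, labels, 0.5)
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["sensitivity"] == pytest.approx(0.75)
        assert m["specificity"] == pytest.approx(0.8333, abs=1e-4)
        assert m["ppv"] == pytest.approx(0.75)
        assert m["npv"] == pytest.approx(0.8333, abs=1e-4)

    def test_cutoff_above_all_scores(self):
        m = metrics_at_threshold([0.3, 0.2], [1, 0], 0.9)
        assert m["sensitivity"] == 0.0
        assert m["specificity"] == 1.0
        assert np.isnan(m["ppv"])  # undefined, not zero


class TestRepeatedEvaluation:
    def test_report_structure_and_determinism(self, end_to_end):
        from thermoshock.glmm import assemble_records
        from thermoshock.evaluation import repeated_evaluation
        rep0 = end_to_end["reports"][0]
        assert rep0.n_effective >= 8
        assert all(0 <= rep0.mean[m] <= 1 for m in rep0.mean)
        # same seed -> identical report
        records = assemble_records(end_to_end["cpd"], end_to_end["labels"],
                                   horizon=0)
        again = repeated_evaluation(records, n_rep=10, seed=5)
        assert again.mean["auc"] == pytest.approx(rep0.mean["auc"])
        pd.testing.assert_frame_equal(again.per_replicate, rep0.per_replicate)

    def test_information_decays_with_horizon(self, end_to_end):
        """Shock persistence decays with horizon, so imaging-time features
        must predict the 12 h outcome no better than the 0 h outcome."""
        reports = end_to_end["reports"]
        assert reports[0].mean["auc"] >= reports[12].mean["auc"]

    def test_report_json_round_trip(self, end_to_end, tmp_path):
        import json
        rep = end_to_end["reports"][0]
        text = rep.to_json(tmp_path / "rep.json")
        payload = json.loads(text)
        assert payload["horizon_h"] == 0
        assert len(payload["per_replicate"]) == rep.n_effective
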