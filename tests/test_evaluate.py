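"""LOSO splitting, classifier scoring, ROC/EER/AUC, end-to-end evaluation."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from oracles import brute_force_roc
from zratio import (
    ClassifierSpec,
    CohortConfig,
    ScoredPrediction,
    evaluate,
    finger_pair_classification,
    fit_predict,
    generate_dataset,
    loso_split,
    roc_from_scores,
)


def pooled_roc(genuine, impostor):
    """roc_from_scores on exactly the given genuine/impostor pools.

    Each score is wrapped as a one-class prediction: records whose true
    label is the scored class contribute genuine scores, others impostor.
    """
    preds = [ScoredPrediction("A", ("A",), (float(g),)) for g in genuine] + [
        ScoredPrediction("B", ("A",), (float(s),)) for s in impostor
    ]
    return roc_from_scores(preds)


class TestLosoSplit:
    def test_fold_count_and_partition(self, small_dataset):
        folds = loso_split(small_dataset)
        assert len(folds) == 4 * 2  # one per (subject, session)
        n = len(small_dataset)
        seen_val = set()
        for train, val in folds:
            assert len(train) + len(val) == n
            keys = {(r.subject_id, r.session_id, r.repeat_index) for r in val.records}
            train_keys = {
                (r.subject_id, r.session_id, r.repeat_index) for r in train.records
            }
            assert not keys & train_keys
            assert len({(r.subject_id, r.session_id) for r in val.records}) == 1
            seen_val |= keys
        assert len(seen_val) == n  # validation sets cover the dataset

    def test_single_session_subject_is_named(self, small_dataset):
        pruned = small_dataset.subset(
            lambda r: not (r.subject_id == "S2" and r.session_id == "D2")
        )
        with pytest.raises(ValueError, match="S2"):
            loso_split(pruned)


class TestFitPredict:
    @pytest.mark.parametrize(
        "family", ["linear-svm", "quadratic-svm", "knn", "bagged-trees"]
    )
    def test_separable_clouds_are_classified(self, family):
        rng = np.random.default_rng(0)
        x0 = rng.normal(0.0, 0.5, size=(20, 4))
        x1 = rng.normal(8.0, 0.5, size=(20, 4))
        x_train = np.vstack([x0, x1])
        y_train = ["a"] * 20 + ["b"] * 20
        x_val = np.vstack(
            [rng.normal(0.0, 0.5, size=(5, 4)), rng.normal(8.0, 0.5, size=(5, 4))]
        )
        y_val = ["a"] * 5 + ["b"] * 5
        preds = fit_predict(
            ClassifierSpec(family=family), x_train, y_train, x_val, y_val, seed=1
        )
        assert all(p.top_label == p.true_label for p in preds)
        for p in preds:
            assert sum(p.scores) == pytest.approx(1.0)

    def test_knn_identity_point_wins(self):
        x_train = np.array([[0.0, 0.0], [5.0, 5.0], [9.0, 0.0]])
        y_train = ["a", "b", "c"]
        preds = fit_predict(
            ClassifierSpec(family="knn"), x_train, y_train,
            np.array([[5.0, 5.0]]), ["b"],
        )
        assert preds[0].top_label == "b"

    def test_bagged_trees_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(40, 6))
        y = (x[:, 0] > 0).astype(str)
        xv = rng.normal(size=(10, 6))
        yv = (xv[:, 0] > 0).astype(str)
        spec = ClassifierSpec(family="bagged-trees")
        p1 = fit_predict(spec, x, y, xv, yv, seed=5)
        p2 = fit_predict(spec, x, y, xv, yv, seed=5)
        assert p1 == p2

    def test_single_class_training_rejected(self):
        with pytest.raises(ValueError):
            fit_predict(
                ClassifierSpec(family="knn"),
                np.zeros((4, 3)), ["a"] * 4, np.zeros((1, 3)), ["a"],
            )

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            ClassifierSpec(family="perceptron")


class TestRoc:
    def test_perfect_separation(self):
        roc = pooled_roc([0.9, 0.8, 0.7], [0.3, 0.2, 0.1])
        assert roc.eer == pytest.approx(0.0)
        assert roc.auc == pytest.approx(1.0)

    def test_hand_enumerated_example(self):
        # genuine {0.9, 0.8, 0.3} vs impostor {0.7, 0.2, 0.1}: the FAR/FRR
        # curves cross at 1/3; AUC = P(genuine > impostor) = 8/9.
        roc = pooled_roc([0.9, 0.8, 0.3], [0.7, 0.2, 0.1])
        assert roc.eer == pytest.approx(100.0 / 3.0, abs=1e-9)
        assert roc.auc == pytest.approx(8.0 / 9.0, abs=1e-9)

    def test_far_monotone_down_frr_monotone_up(self):
        rng = np.random.default_rng(6)
        roc = pooled_roc(rng.normal(1, 1, 40), rng.normal(0, 1, 60))
        assert np.all(np.diff(roc.far) <= 0)
        assert np.all(np.diff(roc.frr) >= 0)
        assert 0.0 <= roc.auc <= 1.0

    def test_chance_level_scores(self):
        rng = np.random.default_rng(7)
        roc = pooled_roc(rng.uniform(size=500), rng.uniform(size=500))
        assert roc.auc == pytest.approx(0.5, abs=0.06)
        assert roc.eer == pytest.approx(50.0, abs=6.0)

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n_g = int(rng.integers(5, 100))
            n_i = int(rng.integers(5, 100))
            genuine = rng.normal(0.6, 0.2, n_g)
            impostor = rng.normal(0.4, 0.2, n_i)
            roc = pooled_roc(genuine, impostor)
            eer, auc = brute_force_roc(list(genuine), list(impostor))
            assert roc.eer == pytest.approx(100 * eer, abs=1e-9)
            assert roc.auc == pytest.approx(auc, abs=1e-9)
            sk = roc_auc_score(
                [1] * n_g + [0] * n_i, np.concatenate([genuine, impostor])
            )
            assert roc.auc == pytest.approx(sk, abs=1e-9)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            roc_from_scores([ScoredPrediction("A", ("A",), (0.5,))])


class TestThresholdSemantics:
    def test_accepted_set_shrinks_as_threshold_rises(self):
        rng = np.random.default_rng(9)
        preds = [
            ScoredPrediction(
                "A", ("A", "B", "C"), tuple(np.sort(rng.uniform(size=3))[::-1])
            )
            for _ in range(30)
        ]
        sizes = [
            sum(p.accepted_label(t) != "reject" for p in preds)
            for t in np.linspace(0.0, 1.0, 21)
        ]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_zero_threshold_never_rejects(self):
        p = ScoredPrediction("A", ("A", "B"), (0.7, 0.3))
        assert p.accepted_label(0.0) == p.top_label == "A"


class TestEvaluate:
    def test_drift_invariant_features_reach_perfect_accuracy(self):
        """Session drift but no noise: ratiometric features are constant
        per subject, so 1-NN identification is exact."""
        config = CohortConfig(drift_sigma=0.3, noise_sigma=0.0)
        ds = generate_dataset(4, 2, 2, seed=31, config=config)
        res = evaluate(ds, "ratiometric", ClassifierSpec(family="knn"), seed=0)
        assert res.accuracy == 100.0
        assert res.eer == pytest.approx(0.0, abs=1e-9)

    def test_raw_features_suffer_under_strong_drift(self):
        config = CohortConfig(drift_sigma=0.4, noise_sigma=0.0)
        ds = generate_dataset(6, 3, 3, seed=31, config=config)
        raw = evaluate(ds, "raw", ClassifierSpec(family="knn"), seed=0)
        ratio = evaluate(ds, "ratiometric", ClassifierSpec(family="knn"), seed=0)
        assert ratio.accuracy > raw.accuracy

    def test_every_family_improves_with_ratiometric_features(self):
        """Under session drift, each classifier family shows lower EER and
        higher AUC with ratio features than with raw spectra."""
        config = CohortConfig(drift_sigma=0.2, noise_sigma=0.02)
        ds = generate_dataset(6, 3, 3, seed=2, config=config)
        for family in ("linear-svm", "quadratic-svm", "knn", "bagged-trees"):
            spec = ClassifierSpec(family=family)
            raw = evaluate(ds, "raw", spec, seed=2)
            ratio = evaluate(ds, "ratiometric", spec, seed=2)
            assert ratio.eer < raw.eer, family
            assert ratio.auc > raw.auc, family

    def test_unknown_attacker_probes_enlarge_the_impostor_pool(self):
        config = CohortConfig(drift_sigma=0.2, noise_sigma=0.02)
        ds = generate_dataset(4, 2, 2, seed=12, config=config)
        spec = ClassifierSpec(family="knn")
        closed = evaluate(ds, "ratiometric", spec, seed=0)
        open_set = evaluate(
            ds, "ratiometric", spec, seed=0, unknown_attacker=True
        )
        # unenrolled probes add impostor scores only: same closed-set
        # accuracy, more ROC points
        assert open_set.accuracy == closed.accuracy
        n_closed = sum(np.array(closed.roc.far) >= 0)
        assert len(open_set.roc.thresholds) >= n_closed
        assert open_set.eer >= 0.0

    def test_confusion_matrix_bookkeeping(self, small_dataset):
        res = evaluate(small_dataset, "ratiometric", ClassifierSpec(family="knn"))
        counts = {s: 0 for s in small_dataset.subject_ids}
        for r in small_dataset.records:
            counts[r.subject_id] += 1
        np.testing.assert_array_equal(
            res.confusion.sum(axis=1), [counts[c] for c in res.classes]
        )
        assert res.confusion.sum() == res.n_records == len(small_dataset)


class TestFingerPairMode:
    def test_multi_subject_input_rejected(self, small_dataset):
        with pytest.raises(ValueError):
            finger_pair_classification(small_dataset)

    def test_separable_pairs_classified_perfectly(self):
        config = CohortConfig(drift_sigma=0.2, noise_sigma=0.0)
        ds = generate_dataset(2, 3, 3, seed=41, config=config)
        one = ds.subset(lambda r: r.subject_id == "S1")
        acc = finger_pair_classification(one, "ratiometric",
                                         ClassifierSpec(family="knn"))
        assert acc == 100.0

    def test_ratiometric_not_worse_than_raw_under_drift(self):
        config = CohortConfig(drift_sigma=0.25, noise_sigma=0.01)
        wins = 0
        for seed in range(3):
            ds = generate_dataset(2, 3, 3, seed=50 + seed, config=config)
            one = ds.subset(lambda r: r.subject_id == "S1")
            raw = finger_pair_classification(one, "raw", ClassifierSpec(family="knn"))
            ratio = finger_pair_classification(
                one, "ratiometric", ClassifierSpec(family="knn")
            )
            wins += ratio >= raw
        assert wins >= 2
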