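"""Linear-SVM classifier: training determinism, calibration, thresholding,
evaluation metrics against a brute-force AUC oracle, serialization."""

import dataclasses

import numpy as np
import pytest

from hrdsense.features import FeatureVector
from hrdsense.model import (
    TrainedModel,
    classify,
    decision_values,
    evaluate,
    fit,
    predict_proba,
)
from hrdsense.schemas import FEATURE_ORDER

from oracles import oracle_auc


def _vector(sample_id, values, assay="WGS"):
    return FeatureVector(
        sample_id=sample_id,
        assay=assay,
        **dict(zip(FEATURE_ORDER, values)),
    )


@pytest.fixture(scope="module")
def trained(wgs_train_features):
    vectors, labels = wgs_train_features
    return fit(vectors, labels, seed=7)


class TestFit:
    def test_separable_cohort_training_auc_one(self, trained):
        assert trained.training_auc == pytest.approx(1.0, abs=1e-6)

    def test_training_auc_reproducible_from_stored_model(
        self, trained, wgs_train_features
    ):
        from sklearn.metrics import roc_auc_score

        vectors, labels = wgs_train_features
        probs = predict_proba(trained, vectors)
        y = [1 if labels[v.sample_id] == "HRD" else 0 for v in vectors]
        assert roc_auc_score(y, probs) == pytest.approx(trained.training_auc, abs=1e-9)

    def test_weight_signs_match_hrd_biology(self, trained):
        signs = dict(zip(trained.feature_order, np.sign(trained.cv_mean_weights)))
        assert signs["loh_1_40"] > 0
        assert signs["del5_mh"] > 0
        assert signs["het3_9_10_40"] > 0
        assert signs["n_cg_t"] > 0
        assert signs["n_ct_g"] < 0
        assert signs["het2_4_gt40"] < 0

    def test_permuted_labels_give_chance_auc(self, wgs_train_features):
        """Destroying the label-feature association drops held-out CV AUC
        into the chance band."""
        vectors, labels = wgs_train_features
        rng = np.random.default_rng(123)
        ids = [v.sample_id for v in vectors]
        permuted = dict(zip(ids, rng.permutation([labels[i] for i in ids])))
        model = fit(vectors, permuted, seed=3)
        assert 0.35 <= model.cv_mean_auc <= 0.65

    def test_single_class_errors(self, wgs_train_features):
        vectors, _ = wgs_train_features
        labels = {v.sample_id: "HRD" for v in vectors}
        with pytest.raises(ValueError):
            fit(vectors, labels)

    def test_mixed_assays_error(self, wgs_train_features):
        vectors, labels = wgs_train_features
        mixed = list(vectors[:10]) + [
            dataclasses.replace(vectors[10], assay="WES")
        ]
        with pytest.raises(ValueError):
            fit(mixed, labels)

    def test_fold_reduction_with_few_samples(self):
        rng = np.random.default_rng(9)
        vectors = [
            _vector(f"s{i}", rng.uniform(0, 1, 6) + (2 if i < 4 else 0))
            for i in range(10)
        ]
        labels = {f"s{i}": "HRD" if i < 4 else "HRP" for i in range(10)}
        model = fit(vectors, labels, n_folds=10, seed=1)
        assert model.training_auc == pytest.approx(1.0)

    def test_deterministic_given_seed(self, wgs_train_features):
        vectors, labels = wgs_train_features
        m1 = fit(vectors, labels, seed=11)
        m2 = fit(vectors, labels, seed=11)
        assert m1.to_json() == m2.to_json()


class TestPredict:
    def test_feature_at_scaler_mean_gives_bias_probability(self, trained):
        means = _vector("m", trained.scaler_means)
        f = decision_values(trained, [means])[0]
        assert f == pytest.approx(trained.svm_bias)
        p = predict_proba(trained, [means])[0]
        expected = 1.0 / (
            1.0
            + np.exp(
                trained.calibration_slope * trained.svm_bias
                + trained.calibration_intercept
            )
        )
        assert p == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_positive_weight_feature(self, trained):
        """Raising a positively weighted feature alone never lowers the
        HRD probability."""
        rng = np.random.default_rng(5)
        idx = trained.feature_order.index("del5_mh")
        assert trained.svm_weights[idx] > 0
        for _ in range(50):
            base = rng.uniform(0, 0.3, 6)
            base[idx] = rng.uniform(0, 20)
            raised = base.copy()
            raised[idx] += rng.uniform(0.1, 10)
            p_lo, p_hi = predict_proba(
                trained, [_vector("a", base), _vector("b", raised)]
            )
            assert p_hi >= p_lo

    def test_duplicate_samples_identical(self, trained, wgs_train_features):
        vectors, _ = wgs_train_features
        probs = predict_proba(trained, [vectors[0], vectors[0]])
        assert probs[0] == probs[1]

    def test_assay_mismatch_rejected(self, trained):
        wes = _vector("w", [0.1] * 6, assay="WES")
        with pytest.raises(ValueError):
            predict_proba(trained, [wes])
        predict_proba(trained, [wes], check_assay=False)  # explicit override


class TestClassify:
    def test_threshold_inclusive(self):
        assert classify([0.50, 0.4999, 0.9]) == ["HRD", "HRP", "HRD"]

    def test_custom_threshold(self):
        assert classify([0.6], threshold=0.7) == ["HRP"]


class TestEvaluate:
    def test_perfect_ranking(self):
        probs = [0.9, 0.8, 0.7, 0.6, 0.55, 0.4, 0.3, 0.2, 0.1, 0.05]
        truth = ["HRD"] * 5 + ["HRP"] * 5
        report = evaluate(classify(probs), probs, truth)
        assert report.auc == 1.0
        assert report.sensitivity == report.precision == report.f1 == 1.0

    def test_partial_ranking_matches_pairwise_oracle(self):
        probs = [0.9, 0.8, 0.7]
        truth = ["HRD", "HRP", "HRD"]
        report = evaluate(classify(probs), probs, truth)
        assert report.auc == pytest.approx(0.5)
        y = [1 if t == "HRD" else 0 for t in truth]
        assert report.auc == pytest.approx(oracle_auc(probs, y))

    def test_auc_equals_oracle_on_random_scores(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(5, 60))
            probs = np.round(rng.uniform(0, 1, n), 2)  # ties likely
            y = rng.integers(0, 2, n)
            if len(np.unique(y)) < 2:
                continue
            truth = ["HRD" if v else "HRP" for v in y]
            report = evaluate(classify(probs), list(probs), truth)
            assert report.auc == pytest.approx(oracle_auc(probs, y), abs=1e-12)

    def test_single_class_truth_auc_missing(self):
        report = evaluate(["HRD", "HRP"], [0.9, 0.1], ["HRD", "HRD"])
        assert report.auc is None
        assert report.sensitivity == 0.5

    def test_confusion_counts(self):
        report = evaluate(
            ["HRD", "HRD", "HRP", "HRP"],
            [0.9, 0.8, 0.2, 0.1],
            ["HRD", "HRP", "HRD", "HRP"],
        )
        assert (report.tp, report.fp, report.fn, report.tn) == (1, 1, 1, 1)
        assert report.f1 == pytest.approx(0.5)


class TestSerialization:
    def test_json_round_trip_bit_exact(self, trained, tmp_path):
        path = tmp_path / "model.json"
        trained.save(path)
        loaded = TrainedModel.load(path)
        assert loaded == trained
        loaded.save(tmp_path / "model2.json")
        assert (tmp_path / "model.json").read_bytes() == (
            tmp_path / "model2.json"
        ).read_bytes()

    def test_version_guard(self, trained):
        import json

        payload = json.loads(trained.to_json())
        payload["format_version"] = 99
        with pytest.raises(ValueError):
            TrainedModel.from_json(json.dumps(payload))


def test_scale_invariance_after_refit(wgs_train_features, wgs_test_features):
    """Affine rescaling of a raw feature is absorbed by the scaler: refitting
    on rescaled features yields identical probabilities."""
    vectors, labels = wgs_train_features
    test_vectors, _ = wgs_test_features

    def rescale(v):
        values = np.array(v.as_array())
        values[2] = values[2] * 7.0 + 3.0  # del5_mh count -> affine image
        return _vector(v.sample_id, values, v.assay)

    m_raw = fit(vectors, labels, seed=7)
    m_scaled = fit([rescale(v) for v in vectors], labels, seed=7)
    p_raw = predict_proba(m_raw, test_vectors)
    p_scaled = predict_proba(m_scaled, [rescale(v) for v in test_vectors])
    np.testing.assert_allclose(p_raw, p_scaled, atol=1e-8)
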