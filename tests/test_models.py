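"""Model statistics, RF training, RFE, cross-validation and the
applicability domain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from catscreen.dataset import QsarDataset
from catscreen.descriptors import DescriptorMatrix
from catscreen.errors import (
    ConfigurationError,
    UndefinedMetricError,
    ValidationError,
)
from catscreen.models import (
    applicability_domain,
    classification_metrics,
    cross_validate_classifier,
    cross_validate_regressor,
    regression_metrics,
    rfe_select,
    roc_auc,
    train_rf_classifier,
    train_rf_regressor,
)

FAST = {"n_estimators": 100}


class TestClassificationMetrics:
    @pytest.mark.parametrize(
        "counts, se, sp, q",
        [
            # fold-averaged confusion counts of the three published
            # classifier benchmarks (fractional counts are legal)
            ((141.2, 10.5, 87.6, 12.7), 91.7, None, 90.8),
            ((144.6, 11.2, 85.5, 10.7), 93.1, 88.4, 91.3),
            ((140.6, 12.6, 87.4, 11.5), None, 87.4, None),
            ((1, 0, 1, 0), 100.0, 100.0, 100.0),
        ],
    )
    def test_worked_examples(self, counts, se, sp, q):
        got_se, got_sp, got_q = classification_metrics(*counts)
        if se is not None:
            assert round(got_se, 1) == se
        if sp is not None:
            assert round(got_sp, 1) == sp
        if q is not None:
            assert round(got_q, 1) == q

    def test_zero_denominator_names_metric(self):
        with pytest.raises(UndefinedMetricError, match="SE"):
            classification_metrics(0, 1, 1, 0)
        with pytest.raises(UndefinedMetricError, match="SP"):
            classification_metrics(1, 0, 0, 1)

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            classification_metrics(-1, 1, 1, 1)

    @given(
        tp=st.floats(0.1, 1e3), fp=st.floats(0, 1e3),
        tn=st.floats(0.1, 1e3), fn=st.floats(0, 1e3),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounds_property(self, tp, fp, tn, fn):
        se, sp, q = classification_metrics(tp, fp, tn, fn)
        assert 0 <= se <= 100 and 0 <= sp <= 100
        assert min(se, sp) - 1e-9 <= q <= max(se, sp) + 1e-9


def _auc_oracle(scores, labels):
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return 100.0 * wins / (len(pos) * len(neg))


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, labels, auc",
        [
            ((0.9, 0.1), (1, 0), 100.0),
            ((0.1, 0.9), (1, 0), 0.0),
            ((0.5, 0.5, 0.5, 0.5), (1, 0, 1, 0), 50.0),
        ],
    )
    def test_examples(self, scores, labels, auc):
        assert roc_auc(scores, labels) == pytest.approx(auc)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            roc_auc([0.1, 0.2], [1, 1])

    @given(st.data())
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_matches_all_pairs_oracle(self, data):
        n = data.draw(st.integers(2, 50))
        scores = data.draw(
            st.lists(st.integers(0, 10), min_size=n, max_size=n)
        )
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).filter(
                lambda ls: 0 < sum(ls) < len(ls)
            )
        )
        assert roc_auc(scores, labels) == pytest.approx(_auc_oracle(scores, labels))


class TestRegressionMetrics:
    def test_perfect_fit(self):
        r2, rmse = regression_metrics([1, 2, 3], [1, 2, 3])
        assert (r2, rmse) == (1.0, 0.0)

    def test_mean_predictor_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0])
        r2, _ = regression_metrics(y, np.full(3, y.mean()))
        assert r2 == pytest.approx(0.0)

    def test_worked_example(self):
        r2, rmse = regression_metrics([1, 2, 3], [1, 2, 4])
        assert r2 == pytest.approx(0.5)
        assert rmse == pytest.approx(0.5774, abs=1e-4)

    def test_constant_y_rejected(self):
        with pytest.raises(UndefinedMetricError):
            regression_metrics([2, 2, 2], [1, 2, 3])


def _cls_dataset(rng, n=120, k=12, sep=4.0, block="PHYS2D"):
    half = n // 2
    X = np.vstack(
        [rng.normal(0, 1, size=(half, k)), rng.normal(sep, 1, size=(n - half, k))]
    )
    y = np.array([0] * half + [1] * (n - half))
    ids = [f"m{i}" for i in range(n)]
    mat = DescriptorMatrix(
        ids=ids, feature_names=[f"f{j}" for j in range(k)], block=block, values=X
    )
    return QsarDataset(ids=ids, X=mat, y_class=y)


class TestRandomForests:
    def test_separable_data_high_training_accuracy(self, rng):
        ds = _cls_dataset(rng)
        model = train_rf_classifier(ds, hyperparams=FAST, seed=0)
        acc = (model.predict(ds.X) == ds.y_class).mean()
        assert acc >= 0.95

    def test_noise_labels_give_chance_auc(self, rng):
        ds = _cls_dataset(rng, n=200, sep=0.0)
        report = cross_validate_classifier(ds, hyperparams=FAST, k_folds=5, seed=1)
        assert 40 <= report.AUC <= 60

    def test_separable_data_perfect_cv(self, rng):
        ds = _cls_dataset(rng, sep=8.0)
        report = cross_validate_classifier(ds, hyperparams=FAST, k_folds=5, seed=0)
        assert report.Q == pytest.approx(100.0)
        assert report.mean_sd["Q"][1] == pytest.approx(0.0)
        # fold confusion counts conserve the fold sizes
        total = sum(f.TP + f.FP + f.TN + f.FN for f in report.per_fold)
        assert total == len(ds)

    def test_deterministic_given_seed(self, rng):
        ds = _cls_dataset(rng)
        m1 = train_rf_classifier(ds, hyperparams=FAST, seed=5)
        m2 = train_rf_classifier(ds, hyperparams=FAST, seed=5)
        np.testing.assert_array_equal(
            m1.predict_score(ds.X), m2.predict_score(ds.X)
        )

    def test_single_class_rejected(self, rng):
        ds = _cls_dataset(rng)
        ds.y_class[:] = 1
        with pytest.raises(ValidationError):
            train_rf_classifier(ds, hyperparams=FAST)

    def test_persistence_round_trip(self, rng, tmp_path):
        ds = _cls_dataset(rng)
        model = train_rf_classifier(ds, hyperparams=FAST, seed=3)
        model.save(tmp_path / "bundle")
        from catscreen.models import TrainedModel

        loaded = TrainedModel.load(tmp_path / "bundle")
        np.testing.assert_array_equal(
            model.predict_score(ds.X), loaded.predict_score(ds.X)
        )
        assert loaded.selected_features == model.selected_features

    def test_regressor_identity_q2(self, rng):
        n, k = 100, 8
        X = rng.normal(size=(n, k))
        y = X[:, 0] * 2.0
        ids = [f"m{i}" for i in range(n)]
        ds = QsarDataset(
            ids=ids,
            X=DescriptorMatrix(
                ids=ids, feature_names=[f"f{j}" for j in range(k)],
                block="PHYS2D", values=X,
            ),
            y_reg=y,
        )
        report = cross_validate_regressor(ds, hyperparams=FAST, seed=0)
        assert report.R2_F > 0.9
        assert report.Q2 > 0.7


class TestRfe:
    def test_identity_when_all_features_requested(self, rng):
        ds = _cls_dataset(rng, k=10)
        selected, profile = rfe_select(ds, 10, hyperparams=FAST, seed=0)
        assert set(selected) == set(ds.X.feature_names)
        assert len(profile) == 1

    def test_profile_length_is_steps_plus_one(self, rng):
        ds = _cls_dataset(rng, k=20)
        selected, profile = rfe_select(ds, 15, hyperparams=FAST, seed=0)
        assert len(selected) == 15
        ks = [k for k, _ in profile]
        assert ks[0] == 20 and ks[-1] == 15
        assert len(profile) == len(ks)
        assert all(a > b for a, b in zip(ks, ks[1:]))

    def test_bad_k_rejected(self, rng):
        ds = _cls_dataset(rng, k=10)
        with pytest.raises(ConfigurationError):
            rfe_select(ds, 0, hyperparams=FAST)
        with pytest.raises(ConfigurationError):
            rfe_select(ds, 11, hyperparams=FAST)


class TestApplicabilityDomain:
    def test_query_at_mean_is_inside(self, rng):
        train = rng.normal(size=(50, 5))
        report = applicability_domain(train, train.mean(0, keepdims=True))
        assert report.verdicts == ["inside"]
        assert np.all(report.s < 1)

    def test_far_query_is_outside(self, rng):
        train = rng.normal(size=(50, 5))
        q = train.mean(0, keepdims=True) + 10 * train.std(0, ddof=1, keepdims=True)
        assert applicability_domain(train, q).verdicts == ["outside"]

    def test_borderline_rule_worked_example(self):
        """S = (4, 0): S_new = 2 + 1.28 * 2.828 = 5.62 > 3 -> outside."""
        a = 1 / np.sqrt(2)  # two points at +/-a: mean 0, sample SD 1
        train = np.array([[-a, -a], [a, a]])
        q = np.array([[4.0, 0.0]])
        report = applicability_domain(train, q)
        np.testing.assert_allclose(report.s, [[4.0, 0.0]], atol=1e-12)
        assert report.verdicts == ["outside"]

    def test_borderline_inside_case(self):
        a = 1 / np.sqrt(2)
        train = np.array([[-a, -a, -a], [a, a, a]])
        # max 3.2 > 3 but min 0; borderline formula decides
        q = np.array([[3.2, 0.0, 0.0]])
        s = np.array([3.2, 0.0, 0.0])
        expected = s.mean() + 1.28 * s.std(ddof=1)
        report = applicability_domain(train, q)
        assert (expected <= 3) == (report.verdicts[0] == "inside")

    def test_zero_variance_descriptor_excluded(self, rng):
        train = rng.normal(size=(30, 3))
        train[:, 1] = 7.0
        report = applicability_domain(train, train[:2])
        assert report.excluded_features == [1]
        assert report.s.shape == (2, 2)
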