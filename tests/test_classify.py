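import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from aggropig.classify import (
    ClassMetrics,
    KernelSpec,
    STAGE1_KERNEL,
    STAGE2_KERNEL,
    classification_metrics,
    cross_validate,
    detection_metrics,
    display_round,
    gram_matrix,
    kernel_eval,
    predict_hierarchical,
    train_svm,
)

RBF = KernelSpec(kind="rbf", C=4.5, gamma=3.5)
POLY = KernelSpec(kind="polynomial", C=4.5, degree=3, coef0=1.0)
VEC = st.lists(st.floats(-3, 3), min_size=5, max_size=5).map(np.array)


class TestKernel:
    def test_rbf_self_similarity_is_one(self, rng):
        for _ in range(5):
            x = rng.normal(size=5)
            assert kernel_eval(RBF, x, x) == pytest.approx(1.0)

    def test_rbf_unit_distance_spot_value(self):
        x = np.zeros(5)
        y = np.array([1.0, 0, 0, 0, 0])  # ||x-y||^2 = 1
        assert kernel_eval(RBF, x, y) == pytest.approx(math.exp(-3.5), abs=1e-9)
        assert kernel_eval(RBF, x, y) == pytest.approx(0.0301974, abs=1e-6)

    def test_polynomial_identity_case(self):
        x = np.array([1.0, 0, 0, 0, 0])
        y = np.array([0, 1.0, 0, 0, 0])  # x.y = 0
        assert kernel_eval(POLY, x, y) == pytest.approx(1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(VEC, VEC)
    def test_rbf_symmetric_and_bounded(self, x, y):
        kxy = kernel_eval(RBF, x, y)
        assert kxy == pytest.approx(kernel_eval(RBF, y, x))
        assert 0 < kxy <= 1

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            kernel_eval(RBF, np.zeros(5), np.zeros(4))

    def test_gram_matches_pairwise_eval(self, rng):
        X = rng.normal(size=(4, 5))
        Y = rng.normal(size=(3, 5))
        for spec in (RBF, POLY):
            G = gram_matrix(spec, X, Y)
            for i in range(4):
                for j in range(3):
                    assert G[i, j] == pytest.approx(kernel_eval(spec, X[i], Y[j]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "rbf", "C": 4.5},  # missing gamma
            {"kind": "rbf", "C": 4.5, "gamma": -1},
            {"kind": "polynomial", "C": 0},
            {"kind": "sigmoid", "C": 1},
        ],
    )
    def test_spec_validation(self, kwargs):
        with pytest.raises(ValueError):
            KernelSpec(**kwargs)


class TestTrainSvm:
    def test_separable_1d(self):
        X = np.array([[0.0], [0.5], [10.0], [9.5]])
        y = np.array([-1, -1, 1, 1])
        model = train_svm(X, y, KernelSpec(kind="polynomial", C=100, degree=1, coef0=1))
        np.testing.assert_array_equal(model.predict(X), y)

    def test_xor_with_rbf(self):
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]], dtype=float)
        y = np.array([-1, -1, 1, 1])
        model = train_svm(X, y, KernelSpec(kind="rbf", C=100, gamma=3.5))
        np.testing.assert_array_equal(model.predict(X), y)
        # decision surface agrees in sign with training labels on a grid
        # near each training point (brute-force check of non-linearity)
        for xi, yi in zip(X, y):
            for d in np.array([[0.05, 0], [0, 0.05], [-0.05, 0], [0, -0.05]]):
                assert model.predict((xi + d)[None, :])[0] == yi

    def test_single_class_error(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((4, 2)), np.ones(4), POLY)

    def test_standardization_makes_units_irrelevant(self, rng):
        X = rng.normal(size=(40, 5)) + np.where(
            (np.arange(40) < 20)[:, None], 0.0, 3.0
        )
        y = np.where(np.arange(40) < 20, -1, 1)
        m1 = train_svm(X, y, RBF)
        m2 = train_svm(X * 100.0, y, RBF)  # e.g. px -> different unit
        Xt = rng.normal(size=(10, 5)) + 1.5
        np.testing.assert_array_equal(m1.predict(Xt), m2.predict(Xt * 100.0))


class TestHierarchy:
    @pytest.fixture(scope="class")
    def toy_models(self):
        # 3 separable clusters in 2-D: normal near (0,0),
        # knocking near (5,0), chasing near (0,5)
        r = np.random.default_rng(7)
        Xn = r.normal(0, 0.3, (20, 2))
        Xk = r.normal(0, 0.3, (20, 2)) + [5, 0]
        Xc = r.normal(0, 0.3, (20, 2)) + [0, 5]
        X = np.vstack([Xn, Xk, Xc])
        labels = np.array(["normal"] * 20 + ["knocking"] * 20 + ["chasing"] * 20)
        stage1 = train_svm(X, np.where(labels == "normal", -1, 1), POLY)
        agg = labels != "normal"
        stage2 = train_svm(
            X[agg], np.where(labels[agg] == "knocking", 1, -1), RBF
        )
        return stage1, stage2, X, labels

    def test_normal_short_circuits_stage2(self, toy_models):
        stage1, stage2, X, labels = toy_models
        x = X[labels == "normal"][:1]
        assert predict_hierarchical(stage1, stage2, x)[0] == "normal"
        # stage2 alone would call this point knocking or chasing
        assert stage2.predict(x)[0] in (-1, 1)

    def test_rule_chain_aggressive(self, toy_models):
        stage1, stage2, X, labels = toy_models
        x = X[labels == "knocking"][:1]
        assert stage1.predict(x)[0] == 1
        assert predict_hierarchical(stage1, stage2, x)[0] == "knocking"

    def test_matches_two_step_table_lookup(self, toy_models):
        """Hierarchical output equals explicit per-point cascade."""
        stage1, stage2, X, labels = toy_models
        got = predict_hierarchical(stage1, stage2, X)
        for xi, gi in zip(X, got):
            if stage1.predict(xi[None])[0] == -1:
                want = "normal"
            elif stage2.predict(xi[None])[0] == 1:
                want = "knocking"
            else:
                want = "chasing"
            assert gi == want
        assert list(got) == list(labels)  # separable toy set: exact


class TestDetectionMetrics:
    def test_perfect_detector_at_corpus_sizes(self):
        m = detection_metrics(TP=115, FP=0, TN=215, FN=0)
        assert (m.ADR, m.FPR, m.FNR) == (100.0, 0.0, 0.0)

    def test_derived_confusion_arithmetic(self):
        # counts consistent with the headline rates at 115/215 episodes
        m = detection_metrics(TP=110, FP=9, TN=206, FN=5)
        assert m.ADR == pytest.approx(95.652, abs=1e-3)
        assert m.display() == {"ADR": 95.7, "FPR": 4.2, "FNR": 4.3}

    def test_total_miss(self):
        m = detection_metrics(TP=0, FP=0, TN=10, FN=10)
        assert (m.ADR, m.FNR) == (0.0, 100.0)

    def test_undefined_rates(self):
        with pytest.raises(ValueError):
            detection_metrics(TP=0, FP=1, TN=1, FN=0)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 500), st.integers(0, 500), st.integers(0, 500), st.integers(1, 500))
    def test_adr_fnr_complementary(self, tp, fp, tn, fn):
        m = detection_metrics(TP=tp + 1, FP=fp, TN=tn + 1, FN=fn)
        assert m.ADR + m.FNR == pytest.approx(100.0)
        for rate in (m.ADR, m.FPR, m.FNR):
            assert 0 <= rate <= 100


class TestClassificationMetrics:
    def test_macro_average_rounding_convention(self):
        # macro averages of the published per-class values, and the
        # half-up display convention that turns 90.05 into 90.1
        assert display_round((88.9 + 91.5) / 2) == 90.2
        assert (92.3 + 87.8) / 2 == pytest.approx(90.05)
        assert display_round((92.3 + 87.8) / 2) == 90.1

    def test_perfect_diagonal(self):
        m = classification_metrics(np.array([[10, 0], [0, 10]]))
        assert m.macro_precision == 100.0 and m.macro_recall == 100.0
        assert all(v == 100.0 for v in m.precision.values())

    def test_known_confusion(self):
        # knocking: 12 correct, 1 -> chasing; chasing: 9 correct, 2 -> knocking
        m = classification_metrics(np.array([[12, 1], [2, 9]]))
        assert m.precision["knocking"] == pytest.approx(12 / 14 * 100)
        assert m.recall["knocking"] == pytest.approx(12 / 13 * 100)
        assert m.macro_precision == pytest.approx(
            (12 / 14 + 9 / 10) / 2 * 100
        )

    def test_never_predicted_class_warns(self):
        with pytest.warns(UserWarning, match="never predicted"):
            m = classification_metrics(np.array([[0, 5], [0, 5]]))
        assert m.precision["knocking"] == 0.0


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def separable(self):
        r = np.random.default_rng(3)
        X = np.vstack(
            [r.normal(0, 0.4, (30, 5)), r.normal(4, 0.4, (30, 5))]
        )
        labels = np.array(["normal"] * 30 + ["knocking"] * 15 + ["chasing"] * 15)
        return X, labels

    def test_separable_limit(self, separable):
        X, labels = separable
        m = cross_validate(X, labels, stage=1, k=10, seed=0)
        assert (m.ADR, m.FPR, m.FNR) == (100.0, 0.0, 0.0)

    def test_deterministic(self, separable):
        X, labels = separable
        a = cross_validate(X, labels, stage=1, k=10, seed=5)
        b = cross_validate(X, labels, stage=1, k=10, seed=5)
        assert a == b

    def test_seed_changes_folds_not_contract(self, separable):
        X, labels = separable
        for seed in (1, 2):
            m = cross_validate(X, labels, stage=1, k=10, seed=seed)
            assert m.TP + m.FN == 30

    def test_small_class_falls_back_to_loo(self, rng):
        X = np.vstack([rng.normal(0, 1, (4, 5)), rng.normal(5, 1, (12, 5))])
        labels = np.array(["knocking"] * 4 + ["chasing"] * 12)
        with pytest.warns(UserWarning, match="leave-one-out"):
            m = cross_validate(X, labels, stage=2, k=10, seed=0)
        assert isinstance(m, ClassMetrics)

    def test_stage2_on_stage1_labels_rejected(self, separable):
        X, labels = separable
        with pytest.raises(ValueError):
            cross_validate(X, labels, stage=2, k=10, seed=0)

    def test_default_kernels_are_published_settings(self):
        assert STAGE1_KERNEL.kind == "polynomial" and STAGE1_KERNEL.C == 4.5
        assert STAGE2_KERNEL.kind == "rbf"
        assert STAGE2_KERNEL.C == 4.5 and STAGE2_KERNEL.gamma == 3.5
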