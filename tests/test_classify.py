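"""Bootstrap/split mechanics, kernel values, search, and evaluation metrics."""

import numpy as np
import pytest

from toothmark import (
    SVMConfig,
    ValidationError,
    benchmark_training,
    evaluate,
    random_search_svm,
    rbf_kernel,
    run_svm_protocol,
    stratified_bootstrap,
    train_svm,
    train_test_split,
)
from toothmark.classify import ProtocolParams, _metrics_from_confusion


def _blobs(rng, n_per=30, shift=4.0):
    X = np.vstack(
        [rng.normal([i * shift, 0], 1.0, size=(n_per, 2)) for i in range(3)]
    )
    y = np.repeat(["dog", "fox", "wolf"], n_per)
    return X, y


class TestResampling:
    def test_bootstrap_closure_and_proportions(self, rng):
        X, y = _blobs(rng, n_per=20)
        Xb, yb = stratified_bootstrap(X, y, n_out=100, seed=3)
        assert Xb.shape == (100, 2)
        rows = {tuple(r) for r in X}
        assert all(tuple(r) in rows for r in Xb)  # multiset drawn from input
        _, counts = np.unique(yb, return_counts=True)
        expected = 100 / 3
        assert all(abs(c - expected) <= 1 for c in counts)

    def test_bootstrap_determinism_and_indices(self, rng):
        X, y = _blobs(rng)
        a = stratified_bootstrap(X, y, 50, seed=9)
        b = stratified_bootstrap(X, y, 50, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])
        Xb, yb, idx = stratified_bootstrap(X, y, 50, seed=9, return_indices=True)
        assert np.array_equal(X[idx], Xb) and np.array_equal(y[idx], yb)

    def test_bootstrap_empty_class_error(self):
        with pytest.raises(ValidationError):
            stratified_bootstrap(np.empty((0, 2)), np.array([]), 10)

    def test_split_sizes_and_disjointness(self, rng):
        X = rng.normal(size=(100, 3))
        y = np.array(["a"] * 40 + ["b"] * 35 + ["c"] * 25)
        X_tr, X_te, y_tr, y_te = train_test_split(X, y, 0.70, seed=1)
        assert len(y_tr) == 70 and len(y_te) == 30
        tr = {tuple(r) for r in X_tr}
        te = {tuple(r) for r in X_te}
        assert not tr & te and len(tr | te) == 100
        for cls in "abc":
            frac = (y_tr == cls).sum() / (y == cls).sum()
            n_cls = (y == cls).sum()
            assert abs(frac * n_cls - 0.70 * n_cls) <= 1.0

    def test_split_singleton_class_error(self, rng):
        X = rng.normal(size=(5, 2))
        with pytest.raises(ValidationError, match="single member"):
            train_test_split(X, np.array(["a", "a", "a", "a", "b"]))


class TestKernelAndTraining:
    def test_rbf_values(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], 3.0) == 1.0
        assert rbf_kernel([0.0, 0.0], [1.0, 1.0], 0.5) == pytest.approx(
            np.exp(-1.0), abs=1e-12
        )
        assert rbf_kernel([0.0], [5.0], 1e-12) == pytest.approx(1.0, abs=1e-9)
        with pytest.raises(ValidationError, match="mismatch"):
            rbf_kernel([1.0], [1.0, 2.0], 1.0)

    def test_separable_blobs_perfect_training(self, rng):
        X, y = _blobs(rng, shift=8.0)
        model = train_svm(X, y, SVMConfig(cost=1000.0, gamma=0.5))
        assert (model.predict(X) == y).mean() == 1.0

    def test_duplicating_rows_leaves_predictions_invariant(self, rng):
        X, y = _blobs(rng, shift=8.0)
        config = SVMConfig(cost=1000.0, gamma=0.5)
        grid = rng.uniform(-3, 19, size=(200, 2))
        base = train_svm(X, y, config).predict(grid)
        doubled = train_svm(np.vstack([X, X]), np.concatenate([y, y]), config)
        assert np.array_equal(doubled.predict(grid), base)

    def test_xor_needs_nonlinear_boundary(self):
        X = np.array([[0.0, 0], [1, 1], [0, 1], [1, 0]] * 5)
        X = X + np.random.default_rng(0).normal(0, 0.05, X.shape)
        y = np.array(["a", "a", "b", "b"] * 5)
        model = train_svm(X, y, SVMConfig(cost=1000.0, gamma=5.0))
        assert (model.predict(X) == y).mean() == 1.0

    def test_single_class_error(self, rng):
        with pytest.raises(ValidationError, match="two classes"):
            train_svm(rng.normal(size=(10, 2)), np.array(["a"] * 10),
                      SVMConfig(cost=1.0, gamma=1.0))

    def test_config_validation(self):
        with pytest.raises(ValidationError):
            SVMConfig(cost=-1.0, gamma=1.0)


class TestRandomSearch:
    def test_determinism_and_degenerate_search(self, rng):
        X, y = _blobs(rng)
        a, _ = random_search_svm(X, y, n_iter=5, k=3, seed=7)
        b, _ = random_search_svm(X, y, n_iter=5, k=3, seed=7)
        assert (a.cost, a.gamma) == (b.cost, b.gamma)
        single, score = random_search_svm(X, y, n_iter=1, k=3, seed=7)
        assert single.cost > 0 and 0 <= score <= 1

    def test_k_exceeding_class_count_error(self, rng):
        X, y = _blobs(rng, n_per=5)
        with pytest.raises(ValidationError, match="smallest class"):
            random_search_svm(X, y, n_iter=2, k=10)

    def test_separable_data_reaches_perfect_cv(self, rng):
        X, y = _blobs(rng, shift=8.0)
        _, score = random_search_svm(X, y, n_iter=10, k=5, seed=0)
        assert score == pytest.approx(1.0)


class TestEvaluate:
    def test_perfect_predictions_metrics(self, rng):
        X, y = _blobs(rng, shift=8.0)
        model = train_svm(X, y, SVMConfig(cost=100.0, gamma=0.1))
        report = evaluate(model, X, y)
        assert report.kappa == 1.0
        assert report.sensitivity == 1.0 and report.specificity == 1.0
        assert report.balanced_accuracy == 1.0 and report.mse == 0.0
        assert report.confusion.sum() == report.n_test
        assert report.kappa_powerful

    def test_kappa_hand_value_on_binary_confusion(self):
        """Confusion [[45,5],[10,40]]: p_o=0.85, p_e=0.50, kappa=0.70."""
        sens, spec = _metrics_from_confusion(np.array([[45, 5], [10, 40]]))
        assert sens == pytest.approx((45 / 50 + 40 / 50) / 2)
        from sklearn.metrics import cohen_kappa_score

        y_true = ["a"] * 50 + ["b"] * 50
        y_pred = ["a"] * 45 + ["b"] * 5 + ["a"] * 10 + ["b"] * 40
        assert cohen_kappa_score(y_true, y_pred) == pytest.approx(0.70, abs=1e-12)

    def test_mse_hand_value(self, rng):
        """True codes (0,1,2), predicted (0,1,0): E=(0,0,2), MSE=4/3."""
        X = np.array([[0.0], [10.0], [20.0]])
        y = np.array(["dog", "fox", "wolf"])
        model = train_svm(
            np.array([[0.0], [10.0], [20.0], [0.1], [10.1], [19.9]]),
            np.array(["dog", "fox", "wolf", "dog", "fox", "wolf"]),
            SVMConfig(cost=100.0, gamma=0.05),
        )

        class Rigged:
            classes_ = model.classes_

            def predict(self, X):
                return np.array(["dog", "fox", "dog"])

        report = evaluate(Rigged(), X, y)
        assert report.mse == pytest.approx(4 / 3, abs=1e-12)
        assert report.confusion[2, 0] == 1  # wolf misread as dog

    def test_unseen_label_error(self, rng):
        X, y = _blobs(rng)
        model = train_svm(X, y, SVMConfig(cost=1.0, gamma=0.5))
        with pytest.raises(ValidationError, match="never seen"):
            evaluate(model, X[:2], np.array(["bear", "bear"]))

    def test_clopper_pearson_bounds(self, rng):
        X, y = _blobs(rng, shift=8.0)
        model = train_svm(X, y, SVMConfig(cost=100.0, gamma=0.1))
        report = evaluate(model, X, y)
        # exact binomial CI for 90/90 successes: [ (alpha/2)^(1/n), 1 ]
        assert report.ci_high == 1.0
        assert report.ci_low == pytest.approx(0.025 ** (1 / 90), abs=1e-9)


class TestBenchmarkAndProtocol:
    def test_benchmark_basic_properties(self, rng):
        X, y = _blobs(rng, n_per=10)
        config = SVMConfig(cost=10.0, gamma=0.5)
        mean_ms, times = benchmark_training(X, y, config, n_rep=5)
        assert mean_ms > 0 and len(times) == 5
        assert mean_ms <= times.max()
        single, times1 = benchmark_training(X, y, config, n_rep=1)
        assert single == times1[0]

    def test_protocol_end_to_end_separable(self, rng):
        X, y = _blobs(rng, shift=8.0)
        params = ProtocolParams(folds=5, n_iter=5, bootstrap_n=200)
        report = run_svm_protocol(X, y, seed=2, params=params)
        assert report.balanced_accuracy == 1.0 and report.kappa == 1.0
        assert report.config is not None and report.cv_score is not None

    def test_bootstrap_first_runs_and_is_flagged_risky(self, rng):
        X, y = _blobs(rng, shift=8.0)
        params = ProtocolParams(folds=5, n_iter=3, bootstrap_n=150, bootstrap_first=True)
        report = run_svm_protocol(X, y, seed=2, params=params)
        # bootstrapped-then-split test partition is large (30% of n_out)
        assert report.n_test == 45
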