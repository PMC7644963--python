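"""AUC oracle, PCA contracts, repeated-CV behavior, LASSO selection, suite."""

import numpy as np
import pytest

from histomics.prediction import (
    _lambda_path,
    _lasso_logistic_path,
    auc,
    classifier_suite,
    combined_glm_predict,
    fit_full_logistic,
    lasso_cv_predict,
    pca_reduce,
    repeated_cv_logistic,
)


def auc_bruteforce(score, label):
    """O(n^2) concordant-pair count with ties worth 1/2."""
    pos = [s for s, l in zip(score, label) if l == 1]
    neg = [s for s, l in zip(score, label) if l == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_separation(self):
        v, _ = auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert v == 1.0

    def test_hand_counted_example(self):
        v, _ = auc([0.9, 0.4, 0.6, 0.2], [1, 1, 0, 0])
        assert v == pytest.approx(0.75)

    def test_matches_bruteforce_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(6, 40))
            score = rng.integers(0, 6, n).astype(float)  # heavy ties
            label = rng.integers(0, 2, n)
            if label.min() == label.max():
                continue
            v, roc = auc(score, label)
            assert v == pytest.approx(auc_bruteforce(score, label), abs=1e-12)
            assert tuple(roc[0]) == (0.0, 0.0) and tuple(roc[-1]) == (1.0, 1.0)
            assert (np.diff(roc[:, 0]) >= 0).all() and (np.diff(roc[:, 1]) >= 0).all()

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc([0.1, 0.2], [1, 1])


class TestPCA:
    def test_line_data_single_component(self):
        t = np.linspace(0, 1, 30)
        M = np.outer(t, [1.0, 2.0, -1.0])
        pc = pca_reduce(M, 2)
        assert pc.explained_variance[0] / pc.explained_variance.sum() > 1 - 1e-10

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(1)
        M = rng.random((15, 6))
        pc = pca_reduce(M, 6)
        recon = pc.scores @ pc.loadings.T + pc.mean
        np.testing.assert_allclose(recon, M, atol=1e-8)

    def test_score_orthogonality(self):
        rng = np.random.default_rng(2)
        pc = pca_reduce(rng.random((20, 117)), 10)
        gram = pc.scores.T @ pc.scores
        np.testing.assert_allclose(gram, np.diag(np.diag(gram)), atol=1e-8)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            pca_reduce(np.random.default_rng(0).random((5, 3)), 5)


class TestRepeatedCV:
    def _data(self, seed=0, n=80, signal=True):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 5))
        if signal:
            X[:, 0] += 1.5 * y
        return X, y

    def test_deterministic_under_seed(self):
        X, y = self._data()
        a = repeated_cv_logistic(X, y, n_repeats=3, seed=5)
        b = repeated_cv_logistic(X, y, n_repeats=3, seed=5)
        np.testing.assert_array_equal(a.prob, b.prob)

    def test_leakage_sanity_label_as_column(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 40)
        X = np.column_stack([y.astype(float), rng.standard_normal(80)])
        cv = repeated_cv_logistic(X, y, n_repeats=2, seed=1)
        assert cv.auc >= 0.99

    def test_probabilities_in_unit_interval(self):
        X, y = self._data()
        cv = repeated_cv_logistic(X, y, n_repeats=2, seed=2)
        assert ((cv.prob >= 0) & (cv.prob <= 1)).all()

    def test_in_sample_fit_is_optimistic(self):
        """Full-data fit AUC >= repeated-CV AUC on average (overfitting direction)."""
        diffs = []
        for seed in range(10):
            X, y = self._data(seed=seed, signal=False)
            full = fit_full_logistic(X, y)
            cv = repeated_cv_logistic(X, y, n_repeats=2, seed=seed)
            diffs.append(full.auc - cv.auc)
        assert np.mean(diffs) > 0
        assert full.in_sample

    def test_stratified_fold_counts(self):
        from sklearn.model_selection import StratifiedKFold

        y = np.array([0] * 33 + [1] * 17)
        skf = StratifiedKFold(5, shuffle=True, random_state=0)
        case_counts = [y[te].sum() for _, te in skf.split(np.zeros((50, 1)), y)]
        assert max(case_counts) - min(case_counts) <= 1


class TestLasso:
    def test_infinite_penalty_zeroes_all_genes(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 30))
        y = rng.integers(0, 2, 50).astype(float)
        lam = _lambda_path(X, y, None, n_lambdas=5)
        B, b0, _ = _lasso_logistic_path(X, y, None, np.array([lam[0] * 10]))
        assert (B == 0).all()

    def test_path_solution_matches_liblinear_objective(self):
        """Same optimum as an independent solver at matched penalties."""
        from sklearn.linear_model import LogisticRegression

        rng = np.random.default_rng(1)
        n, p = 80, 40
        X = rng.standard_normal((n, p))
        beta = np.zeros(p)
        beta[:5] = 1.0
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta))).astype(float)
        lam = _lambda_path(X, y, None, n_lambdas=20)
        B, b0, _ = _lasso_logistic_path(X, y, None, lam)

        def objective(bet, intercept, lam_v):
            eta = intercept + X @ bet
            nll = np.mean(np.log1p(np.exp(-np.where(y > 0, eta, -eta))))
            return nll + lam_v * np.abs(bet).sum()

        import warnings

        for li in (5, 10, 15):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                sk = LogisticRegression(penalty="l1", solver="liblinear",
                                        C=1.0 / (n * lam[li]), max_iter=5000,
                                        tol=1e-10, intercept_scaling=100.0)
                sk.fit(X, y)
            mine = objective(B[li], b0[li], lam[li])
            theirs = objective(sk.coef_[0], sk.intercept_[0], lam[li])
            assert mine <= theirs + 1e-5

    def test_recovers_planted_genes(self, signal_expression, signal_expression_std):
        cv, sel = lasso_cv_predict(signal_expression_std, signal_expression.phenotype,
                                   n_repeats=1, seed=0)
        planted = set(signal_expression.de_genes.tolist())
        hit = len(set(sel.consensus.tolist()) & planted)
        assert hit / len(planted) >= 0.6
        assert cv.auc >= 0.85
        for s, c in zip(sel.fold_sets, sel.fold_coefs):
            assert len(s) == len(c) and (np.abs(c) > 0).all()

    def test_deterministic(self, signal_expression, signal_expression_std):
        a, _ = lasso_cv_predict(signal_expression_std[:, :100],
                                signal_expression.phenotype, n_repeats=1, seed=3)
        b, _ = lasso_cv_predict(signal_expression_std[:, :100],
                                signal_expression.phenotype, n_repeats=1, seed=3)
        np.testing.assert_array_equal(a.prob, b.prob)


class TestCombined:
    def _modalities(self, seed, img_signal=1.0, expr_signal=1.0, n=100, p=150):
        rng = np.random.default_rng(seed)
        y = np.repeat([0, 1], n // 2)
        pcs = rng.standard_normal((n, 10))
        pcs[:, 0] += img_signal * y
        X = rng.standard_normal((n, p))
        X[:, :10] += expr_signal * y[:, None]
        return pcs, X, y

    def test_combined_tracks_expression_when_image_is_null(self):
        gaps = []
        for seed in range(3):
            pcs, X, y = self._modalities(seed, img_signal=0.0, expr_signal=1.2)
            comb = combined_glm_predict(pcs, X, y, n_repeats=1, seed=seed)
            expr_only, _ = lasso_cv_predict(X, y, n_repeats=1, seed=seed)
            gaps.append(comb.auc - expr_only.auc)
        assert abs(np.mean(gaps)) < 0.05

    def test_combined_not_worse_than_best_single(self):
        gaps = []
        for seed in range(3):
            pcs, X, y = self._modalities(seed + 10)
            comb = combined_glm_predict(pcs, X, y, n_repeats=1, seed=seed)
            img = repeated_cv_logistic(pcs, y, n_repeats=1, seed=seed)
            expr, _ = lasso_cv_predict(X, y, n_repeats=1, seed=seed)
            gaps.append(comb.auc - max(img.auc, expr.auc))
        assert np.mean(gaps) >= -0.05

    def test_deterministic(self):
        pcs, X, y = self._modalities(1)
        a = combined_glm_predict(pcs, X, y, n_repeats=1, seed=2)
        b = combined_glm_predict(pcs, X, y, n_repeats=1, seed=2)
        np.testing.assert_array_equal(a.prob, b.prob)


class TestClassifierSuite:
    def test_separable_data_all_methods_excellent(self):
        rng = np.random.default_rng(0)
        y = np.repeat([0, 1], 50)
        X = rng.standard_normal((100, 2)) + 4.0 * y[:, None]
        res = classifier_suite(X, y, seed=0, rf_trees=100)
        for m in ("RF", "SVM", "NB", "LD", "QD", "LR"):
            assert res[m] >= 0.95, m

    def test_lda_matches_gaussian_closed_form(self):
        """Equal-covariance Gaussian classes at Mahalanobis separation Delta:
        the optimal discriminant score differs between classes by Delta with
        variance 1 each, so AUC = P(S1 > S0) = Phi(Delta / sqrt(2))."""
        from scipy.stats import norm

        rng = np.random.default_rng(7)
        delta = 1.6
        n = 2000
        y = np.repeat([0, 1], n // 2)
        X = rng.standard_normal((n, 4))
        X[:, 0] += delta * y
        res = classifier_suite(X, y, seed=1, rf_trees=50)
        assert res["LD"] == pytest.approx(norm.cdf(delta / np.sqrt(2)), abs=0.03)

    def test_reports_best(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 30)
        X = rng.standard_normal((60, 3)) + y[:, None]
        res = classifier_suite(X, y, seed=0, rf_trees=50)
        name, val = res["best"]
        assert val == max(res[m] for m in ("RF", "SVM", "NB", "LD", "QD", "LR"))
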