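"""Prediction of binary pathology from image PCs and/or expression.

The core analyses: principal-component reduction of the feature blocks,
repeated stratified cross-validated logistic regression with per-sample
probabilities averaged over repeats, L1-penalized (LASSO) logistic gene
selection at the penalty minimizing inner-CV deviance, a combined
image-PC + selected-gene generalized linear model, and a suite of six
off-the-shelf classifiers.  Performance is summarized by the area under the
ROC curve, computed by the Mann-Whitney pair statistic (ties count 1/2).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import rankdata
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "PCModel",
    "CVPrediction",
    "LassoSelection",
    "pca_reduce",
    "auc",
    "repeated_cv_logistic",
    "fit_full_logistic",
    "lasso_cv_predict",
    "combined_glm_predict",
    "classifier_suite",
]


@dataclass
class PCModel:
    loadings: np.ndarray  # features x k, orthonormal columns
    scores: np.ndarray  # samples x k
    explained_variance: np.ndarray
    mean: np.ndarray


@dataclass
class CVPrediction:
    prob: np.ndarray  # per-sample probability averaged over repeats
    n_repeats: int
    n_folds: int
    auc: float
    roc_points: np.ndarray  # (FPR, TPR) pairs
    in_sample: bool = False


@dataclass
class LassoSelection:
    fold_sets: list  # selected gene-index arrays, one per (repeat, fold)
    fold_coefs: list  # matching nonzero coefficient arrays
    consensus: np.ndarray  # genes selected in >= 50% of folds

    @property
    def n_folds_total(self) -> int:
        return len(self.fold_sets)


def pca_reduce(M: np.ndarray, k: int) -> PCModel:
    """SVD-based PCA with a deterministic sign convention.

    Columns are centered; each component's sign is fixed so its
    largest-magnitude loading is positive.
    """
    M = np.asarray(M, dtype=float)
    n, p = M.shape
    if k > min(n - 1, p):
        raise ValueError(f"k={k} exceeds min(samples-1, features)={min(n - 1, p)}")
    mean = M.mean(axis=0)
    X = M - mean
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    for j in range(k):
        lead = np.argmax(np.abs(Vt[j]))
        if Vt[j, lead] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return PCModel(
        loadings=Vt[:k].T,
        scores=U[:, :k] * S[:k],
        explained_variance=(S[:k] ** 2) / max(n - 1, 1),
        mean=mean,
    )


def auc(score: np.ndarray, label: np.ndarray):
    """Mann-Whitney AUC (ties = 1/2) plus ROC points.

    Returns ``(auc_value, roc_points)`` where roc_points is an array of
    (FPR, TPR) pairs from (0,0) to (1,1).
    """
    score = np.asarray(score, dtype=float)
    label = np.asarray(label, dtype=int)
    n1 = int((label == 1).sum())
    n0 = int((label == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(score)
    value = (ranks[label == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    fpr, tpr, _ = roc_curve(label, score)
    return float(value), np.column_stack([fpr, tpr])


def _fit_logistic(X, y, ridge_fallback_c: float = 1e6) -> LogisticRegression:
    """Unpenalized logistic fit with a small-ridge fallback on non-convergence."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model = LogisticRegression(C=np.inf, max_iter=500)
            model.fit(X, y)
            return model
        except ConvergenceWarning:
            logger.warning("logistic fit did not converge; ridge-stabilized refit")
    model = LogisticRegression(C=ridge_fallback_c, max_iter=2000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X, y)
    return model


def _with_cov(X, covariates):
    if covariates is None:
        return np.asarray(X, dtype=float)
    return np.column_stack([np.asarray(X, dtype=float), np.asarray(covariates, dtype=float)])


def repeated_cv_logistic(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_folds: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
) -> CVPrediction:
    """Repeated stratified-CV logistic regression, probabilities averaged.

    Per repeat, a seeded stratified fold assignment is drawn; held-out
    probabilities are recorded, and the final per-sample probability is the
    mean over repeats.  The AUC is computed once on the averaged
    probabilities.
    """
    y = np.asarray(y, dtype=int)
    Z = _with_cov(X, covariates)
    if min((y == 1).sum(), (y == 0).sum()) < n_folds:
        raise ValueError("need at least n_folds samples of each class for stratified CV")
    acc = np.zeros(len(y))
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=(seed * 10_007 + rep) % (2**32 - 1))
        for tr, te in skf.split(Z, y):
            model = _fit_logistic(Z[tr], y[tr])
            acc[te] += model.predict_proba(Z[te])[:, 1]
    prob = acc / n_repeats
    value, roc = auc(prob, y)
    return CVPrediction(prob=prob, n_repeats=n_repeats, n_folds=n_folds, auc=value, roc_points=roc)


def fit_full_logistic(X, y, covariates=None) -> CVPrediction:
    """Single all-observations fit; in-sample probabilities (optimistic)."""
    y = np.asarray(y, dtype=int)
    Z = _with_cov(X, covariates)
    model = _fit_logistic(Z, y)
    prob = model.predict_proba(Z)[:, 1]
    value, roc = auc(prob, y)
    return CVPrediction(
        prob=prob, n_repeats=1, n_folds=1, auc=value, roc_points=roc, in_sample=True
    )


# ---------------------------------------------------------------------------
# L1-penalized logistic path (FISTA, warm-started), with unpenalized covariates


def _fista_subproblem(Zw, y, theta0, n_unpen, lam, tol, max_iter):
    """FISTA on a working set; the first ``n_unpen`` columns are unpenalized."""
    n = Zw.shape[0]
    # Lipschitz constant of the smooth part: ||Zw||_2^2 / (4n), power iteration
    v = np.ones(Zw.shape[1]) / np.sqrt(Zw.shape[1])
    for _ in range(12):
        v = Zw.T @ (Zw @ v)
        nv = np.linalg.norm(v)
        if nv < 1e-30:
            break
        v /= nv
    L = float(v @ (Zw.T @ (Zw @ v))) / (4.0 * n)
    step = 1.0 / max(L, 1e-12)
    thr = step * lam
    zk = theta0.copy()
    prev = theta0.copy()
    t_mom = 1.0
    for _ in range(max_iter):
        grad = Zw.T @ (expit(Zw @ zk) - y) / n
        new = zk - step * grad
        pen = new[n_unpen:]
        new[n_unpen:] = np.sign(pen) * np.maximum(np.abs(pen) - thr, 0.0)
        t_next = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t_mom**2))
        zk = new + ((t_mom - 1.0) / t_next) * (new - prev)
        t_mom = t_next
        delta = np.max(np.abs(new - prev))
        prev = new
        if delta < tol * (1.0 + np.max(np.abs(new))):
            break
    return prev


def _lasso_logistic_path(X, y, cov, lambdas, tol=1e-6, max_iter=300, dfmax=None):
    """Coefficient path of L1-penalized logistic regression.

    Minimizes (1/n) * logistic deviance/2 + lambda * ||beta||_1 over a
    decreasing penalty sequence with warm starts.  Each penalty is solved by
    FISTA on a working set built from the strong screening rule, with KKT
    checks over the full gene set; intercept and covariates are unpenalized.
    The path stops once more than ``dfmax`` genes are active (remaining
    entries repeat the last solution).

    Returns (betas [L x p], intercepts [L], gammas [L x c]).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    C = np.zeros((n, 0)) if cov is None else np.asarray(cov, dtype=float)
    c = C.shape[1]
    if dfmax is None:
        dfmax = min(n, 200)
    base = np.column_stack([np.ones(n), C])
    ab = np.zeros(1 + c)
    ab[0] = np.log(max(y.mean(), 1e-9) / max(1 - y.mean(), 1e-9))
    beta = np.zeros(p)
    betas = np.zeros((len(lambdas), p))
    intercepts = np.zeros(len(lambdas))
    gammas = np.zeros((len(lambdas), c))
    prev_lam = float(lambdas[0])
    for li, lam in enumerate(lambdas):
        resid = expit(base @ ab + X @ beta) - y
        g = np.abs(X.T @ resid) / n
        work = (np.abs(beta) > 0) | (g >= 2.0 * lam - prev_lam)
        for _ in range(20):
            idx = np.flatnonzero(work)
            Zw = np.column_stack([base, X[:, idx]])
            theta0 = np.concatenate([ab, beta[idx]])
            theta = _fista_subproblem(Zw, y, theta0, 1 + c, lam, tol, max_iter)
            ab = theta[: 1 + c]
            beta[:] = 0.0
            beta[idx] = theta[1 + c:]
            resid = expit(base @ ab + X @ beta) - y
            g = np.abs(X.T @ resid) / n
            viol = (~work) & (g > lam * (1.0 + 1e-4))
            if not viol.any():
                break
            work |= viol
        intercepts[li] = ab[0]
        gammas[li] = ab[1:]
        betas[li] = beta
        prev_lam = float(lam)
        if (np.abs(beta) > 0).sum() > dfmax:
            betas[li + 1:] = beta
            intercepts[li + 1:] = ab[0]
            gammas[li + 1:] = ab[1:]
            break
    return betas, intercepts, gammas


def _lambda_path(X, y, cov, n_lambdas=100, ratio=1e-4):
    """Log-spaced penalty path from the all-zero penalty downward."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)
    resid = y - y.mean()
    if cov is not None:
        # account for unpenalized covariates: residualize y's linear signal
        C1 = np.column_stack([np.ones(n), cov])
        beta, *_ = np.linalg.lstsq(C1, y, rcond=None)
        resid = y - C1 @ beta
    lam_max = np.max(np.abs(X.T @ resid)) / n
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * ratio, n_lambdas)


def _deviance(prob, y):
    p = np.clip(prob, 1e-12, 1 - 1e-12)
    return -2.0 * float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _lasso_select_on_fold(Xtr, ytr, covtr, n_lambdas, inner_folds, rng_seed):
    """Inner-CV penalty choice and refit on one training fold.

    Returns (selected indices, coefficients at the chosen penalty, predictor).
    """
    lambdas = _lambda_path(Xtr, ytr, covtr, n_lambdas=n_lambdas)
    skf = StratifiedKFold(n_splits=inner_folds, shuffle=True, random_state=rng_seed)
    dev = np.zeros(len(lambdas))
    for itr, ite in skf.split(Xtr, ytr):
        ctr = None if covtr is None else covtr[itr]
        cte = None if covtr is None else covtr[ite]
        B, b0, G = _lasso_logistic_path(Xtr[itr], ytr[itr], ctr, lambdas)
        eta = Xtr[ite] @ B.T + b0[None, :]
        if cte is not None:
            eta += cte @ G.T
        probs = expit(eta)
        for li in range(len(lambdas)):
            dev[li] += _deviance(probs[:, li], ytr[ite])
    best = int(np.argmin(dev))
    B, b0, G = _lasso_logistic_path(Xtr, ytr, covtr, lambdas[: best + 1])
    beta = B[-1]
    selected = np.flatnonzero(np.abs(beta) > 1e-10)

    def predictor(Xte, covte=None):
        eta = Xte @ beta + b0[-1]
        if covte is not None and covtr is not None:
            eta = eta + covte @ G[-1]
        return expit(eta)

    return selected, beta[selected], predictor


def lasso_cv_predict(
    expr: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_folds: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
    n_lambdas: int = 100,
    inner_folds: int = 5,
):
    """Repeated-CV LASSO logistic gene prediction with per-fold selection.

    ``expr`` is samples x genes, standardized per gene.  Within each outer
    training fold an inner CV over a log-spaced penalty path picks the
    deviance-minimizing penalty; genes with nonzero coefficients there are
    that fold's selection.  Held-out probabilities are averaged over repeats.

    Returns ``(CVPrediction, LassoSelection)``.
    """
    X = np.asarray(expr, dtype=float)
    y = np.asarray(y, dtype=int)
    acc = np.zeros(len(y))
    fold_sets, fold_coefs = [], []
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=(seed * 10_007 + rep) % (2**32 - 1))
        for fi, (tr, te) in enumerate(skf.split(X, y)):
            covtr = None if covariates is None else np.asarray(covariates)[tr]
            covte = None if covariates is None else np.asarray(covariates)[te]
            sel, coefs, predict = _lasso_select_on_fold(
                X[tr], y[tr], covtr, n_lambdas, inner_folds, rng_seed=(seed * 65_537 + rep * 7 + fi) % (2**32 - 1)
            )
            if len(sel) == 0:
                logger.info("repeat %d fold %d: no genes selected; intercept-only", rep, fi)
            fold_sets.append(sel)
            fold_coefs.append(coefs)
            acc[te] += predict(X[te], covte)
    prob = acc / n_repeats
    value, roc = auc(prob, y)
    n_total = len(fold_sets)
    counts = np.zeros(X.shape[1], dtype=int)
    for s in fold_sets:
        counts[s] += 1
    consensus = np.flatnonzero(counts >= 0.5 * n_total)
    return (
        CVPrediction(prob=prob, n_repeats=n_repeats, n_folds=n_folds, auc=value, roc_points=roc),
        LassoSelection(fold_sets=fold_sets, fold_coefs=fold_coefs, consensus=consensus),
    )


def combined_glm_predict(
    image_pcs: np.ndarray,
    expr: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    n_folds: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
    n_lambdas: int = 100,
) -> CVPrediction:
    """Combined image-PC + LASSO-selected-gene logistic model, repeated CV.

    Gene selection is redone inside every outer training fold (no test-fold
    leakage); the final per-fold model is an unpenalized logistic regression
    on [image PCs, selected genes, covariates], ridge-stabilized when the
    predictor count approaches the training size.
    """
    P = np.asarray(image_pcs, dtype=float)
    X = np.asarray(expr, dtype=float)
    y = np.asarray(y, dtype=int)
    acc = np.zeros(len(y))
    for rep in range(n_repeats):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=(seed * 10_007 + rep) % (2**32 - 1))
        for fi, (tr, te) in enumerate(skf.split(X, y)):
            covtr = None if covariates is None else np.asarray(covariates)[tr]
            covte = None if covariates is None else np.asarray(covariates)[te]
            sel, _, _ = _lasso_select_on_fold(
                X[tr], y[tr], covtr, n_lambdas, 5, rng_seed=(seed * 65_537 + rep * 7 + fi) % (2**32 - 1)
            )
            Ztr = _with_cov(np.column_stack([P[tr], X[tr][:, sel]]), covtr)
            Zte = _with_cov(np.column_stack([P[te], X[te][:, sel]]), covte)
            if Ztr.shape[1] >= len(tr):
                logger.warning("more predictors than training samples; ridge-stabilized fit")
                model = LogisticRegression(C=1.0, max_iter=2000)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    model.fit(Ztr, y[tr])
            else:
                model = _fit_logistic(Ztr, y[tr])
            acc[te] += model.predict_proba(Zte)[:, 1]
    prob = acc / n_repeats
    value, roc = auc(prob, y)
    return CVPrediction(prob=prob, n_repeats=n_repeats, n_folds=n_folds, auc=value, roc_points=roc)


def classifier_suite(
    X: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    rf_trees: int = 500,
) -> dict:
    """Six-classifier comparison on a PC representation.

    RF, SVM (RBF, decision values as scores), Gaussian NB, linear and
    quadratic discriminants, and unpenalized logistic regression, each scored
    by stratified ``n_folds``-fold CV AUC on pooled held-out scores.  Returns
    a dict of per-method AUCs plus ``best`` (name, auc).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    k = X.shape[1]

    def make_models():
        return {
            "RF": RandomForestClassifier(
                n_estimators=rf_trees, max_features="sqrt", random_state=seed
            ),
            "SVM": SVC(C=1.0, kernel="rbf", gamma=1.0 / k),
            "NB": GaussianNB(),
            "LD": LinearDiscriminantAnalysis(),
            "QD": QuadraticDiscriminantAnalysis(reg_param=1e-3),
            "LR": LogisticRegression(C=np.inf, max_iter=1000),
        }

    scores = {name: np.zeros(len(y)) for name in make_models()}
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        models = make_models()
        for name, model in models.items():
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            if name == "SVM":
                scores[name][te] = model.decision_function(X[te])
            else:
                scores[name][te] = model.predict_proba(X[te])[:, 1]
    result = {name: auc(s, y)[0] for name, s in scores.items()}
    best_name = max(result, key=result.get)
    return {**result, "best": (best_name, result[best_name])}
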