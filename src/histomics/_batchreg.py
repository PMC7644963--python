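"""Vectorized per-gene association tests.

Fitting thousands of tiny regressions one statsmodels call at a time is the
bottleneck of gene-wise screens, so the logistic case runs a Newton solver
batched across genes (each design is [covariates..., gene], differing only in
the gene column) and the linear case uses closed-form partial t-tests after
residualizing against the shared covariates.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = ["batch_logistic_pvalues", "batch_ols_pvalues"]


def batch_logistic_pvalues(
    X: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-8,
    ridge: float = 1e-8,
    separation_ridge: float = 1e-4,
):
    """Wald p-value of the gene term in logit(y) ~ covariates + gene, per gene.

    ``X`` is samples x genes.  Genes with zero variance get p = 1 and a flag;
    apparent separation (runaway coefficients) triggers a ridge-stabilized
    (penalty ``separation_ridge``) likelihood-ratio fallback and a flag.

    Returns ``(pvalues, flags)`` with flags True where a fallback applied.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, G = X.shape
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    c = C.shape[1]
    k = c + 1

    sd = X.std(axis=0)
    degenerate = sd < 1e-12

    def _newton(ridge_now, genes):
        Xg = X[:, genes]
        g = Xg.shape[1]
        theta = np.zeros((g, k))
        theta[:, 0] = np.log(max(y.mean(), 1e-9) / max(1.0 - y.mean(), 1e-9))
        H = np.empty((g, k, k))
        grad = np.empty((g, k))
        for _ in range(max_iter):
            eta = C @ theta[:, :c].T + Xg * theta[:, c]
            p = expit(eta)
            w = np.clip(p * (1.0 - p), 1e-10, None)
            r = (y[:, None] - p)
            grad[:, :c] = np.einsum("ni,ng->gi", C, r)
            grad[:, c] = (Xg * r).sum(axis=0)
            H[:, :c, :c] = np.einsum("ni,ng,nj->gij", C, w, C)
            hx = np.einsum("ni,ng->gi", C, w * Xg)
            H[:, :c, c] = hx
            H[:, c, :c] = hx
            H[:, c, c] = (w * Xg**2).sum(axis=0)
            Hreg = H + ridge_now * np.eye(k)[None]
            # ridge penalty also contributes to the gradient when active
            step = np.linalg.solve(Hreg, (grad - ridge_now * theta)[..., None])[..., 0]
            theta += step
            if np.max(np.abs(step)) < tol * (1.0 + np.max(np.abs(theta))):
                break
        cov = np.linalg.inv(H + ridge_now * np.eye(k)[None])
        se = np.sqrt(np.maximum(cov[:, c, c], 1e-300))
        z = theta[:, c] / se
        return theta, 2.0 * stats.norm.sf(np.abs(z))

    def _llf(eta):
        # Bernoulli log-likelihood, numerically safe log(1 + e^eta)
        return float(np.sum(y * eta - np.logaddexp(0.0, eta)))

    pvals = np.ones(G)
    flags = degenerate.copy()
    ok = np.flatnonzero(~degenerate)
    if len(ok):
        theta, p0 = _newton(ridge, ok)
        beta = theta[:, c]
        runaway = ~np.isfinite(beta) | (np.abs(beta) > 15.0) | ~np.isfinite(p0)
        pvals[ok] = np.where(runaway, 1.0, p0)
        if runaway.any():
            # separation: the Wald statistic degenerates, so fall back to a
            # ridge-stabilized likelihood-ratio test against the gene-free model
            bad = ok[runaway]
            theta_bad, _ = _newton(separation_ridge, bad)

            from scipy.optimize import minimize

            null_fit = minimize(
                lambda par: -_llf(C @ par), np.zeros(c), method="BFGS"
            )
            llf0 = -float(null_fit.fun)
            for i, g in enumerate(bad):
                eta = C @ theta_bad[i, :c] + X[:, g] * theta_bad[i, c]
                lr = max(0.0, 2.0 * (_llf(eta) - llf0))
                pvals[g] = stats.chi2.sf(lr, df=1)
            flags[bad] = True
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return pvals, flags


def batch_ols_pvalues(
    X: np.ndarray,
    response: np.ndarray,
    covariates: np.ndarray | None = None,
):
    """t-test p-value of the gene term in response ~ covariates + gene, per gene.

    Computed as the partial correlation t-statistic after projecting out the
    covariates (plus intercept).  Degenerate genes get p = 1 and a flag.
    """
    X = np.asarray(X, dtype=float)
    v = np.asarray(response, dtype=float)
    n, G = X.shape
    C = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), np.asarray(covariates, dtype=float)]
    )
    c = C.shape[1]
    Q, _ = np.linalg.qr(C)
    Xr = X - Q @ (Q.T @ X)
    vr = v - Q @ (Q.T @ v)
    sx2 = (Xr**2).sum(axis=0)
    degenerate = sx2 < 1e-24
    sxy = Xr.T @ vr
    beta = np.where(degenerate, 0.0, sxy / np.where(degenerate, 1.0, sx2))
    rss = (vr**2).sum() - beta * sxy
    df = n - c - 1
    sigma2 = np.maximum(rss, 0.0) / df
    se = np.sqrt(np.where(degenerate, np.inf, sigma2 / np.where(degenerate, 1.0, sx2)))
    t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.where(degenerate, 1.0, pvals)
    return np.clip(pvals, np.finfo(float).tiny, 1.0), degenerate
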