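"""Cross-tissue expression-association strength via Storey's pi1 = 1 - pi0.

For each gene and tissue, four regressions are run with sex as covariate:
binary pathology phenotype (logistic, Wald p for the gene term) and each of
the first three image PCs (ordinary least squares, t-test p).  The fraction
of non-null p-values pi1 = 1 - pi0 is estimated by the q-value machinery:
pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda)) over a lambda grid, with a
cubic smoother evaluated at the largest lambda.  Because pi1 is a proportion,
it compares association strength across tissues with very different sample
sizes.  A QQ utility provides the observed-vs-expected -log10 quantiles and
the median (genomic-control style) inflation ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from ._batchreg import batch_logistic_pvalues, batch_ols_pvalues

__all__ = [
    "Pi1Estimate",
    "gene_wise_regression",
    "estimate_pi0",
    "pi1_profile",
    "qq_plot_data",
]


@dataclass
class Pi1Estimate:
    pi0: float
    lambda_grid: np.ndarray
    method: str  # smoother | fixed
    raw_curve: np.ndarray  # pi0_hat(lambda) on the grid

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0


def gene_wise_regression(
    expr: np.ndarray,
    response: np.ndarray,
    sex: np.ndarray | None = None,
):
    """Per-gene p-values for association of a response with expression.

    ``expr`` is samples x genes.  A binary response uses logistic regression
    of response on gene + sex (Wald p for the gene term); a continuous one
    uses ordinary least squares (partial t-test).  Degenerate genes (zero
    variance) or separation fallbacks are flagged.

    Returns ``(pvalues, flags)``.
    """
    response = np.asarray(response)
    vals = np.unique(response[~np.isnan(np.asarray(response, dtype=float))])
    is_binary = set(vals.tolist()) <= {0, 1, 0.0, 1.0}
    if is_binary:
        return batch_logistic_pvalues(expr, response.astype(float), covariates=sex)
    return batch_ols_pvalues(expr, response.astype(float), covariates=sex)


def estimate_pi0(
    pvalues: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    method: str = "smoother",
    fixed_lambda: float = 0.5,
) -> Pi1Estimate:
    """Storey pi0 estimate from a p-value collection.

    ``pi0_hat(lambda) = #{p > lambda} / (m (1 - lambda))``; the smoother
    method fits a cubic smoothing spline to the curve over the grid and reads
    it off at the largest lambda; the fixed method evaluates the counting
    formula at ``fixed_lambda``.  The estimate is clipped to [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    if m == 0:
        raise ValueError("empty p-value collection")
    if m < 100:
        import warnings

        warnings.warn("fewer than 100 p-values: pi0 estimate will be noisy")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.951, 0.05)
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    curve = np.array([(p > lam).sum() / (m * (1.0 - lam)) for lam in lambda_grid])
    if (p >= 1.0).all():
        return Pi1Estimate(pi0=1.0, lambda_grid=lambda_grid, method=method, raw_curve=curve)
    if method == "fixed":
        pi0 = (p > fixed_lambda).sum() / (m * (1.0 - fixed_lambda))
    elif method == "smoother":
        # low-df cubic smoother of pi0_hat(lambda), read off at the largest lambda
        coef = np.polyfit(lambda_grid, curve, deg=3)
        pi0 = float(np.polyval(coef, lambda_grid.max()))
    else:
        raise ValueError(f"unknown method {method!r}")
    return Pi1Estimate(
        pi0=float(np.clip(pi0, 0.0, 1.0)),
        lambda_grid=lambda_grid,
        method=method,
        raw_curve=curve,
    )


def pi1_profile(
    tissues: dict,
    phenotype: np.ndarray,
    image_pcs: np.ndarray,
    sex: np.ndarray | None = None,
    method: str = "smoother",
):
    """pi1 per tissue per model, plus the argmax tissue per model.

    ``tissues`` maps tissue label -> log-CPM DataFrame (genes x samples,
    samples aligned with ``phenotype``).  Models: binary phenotype and image
    PCs 1-3 (columns of ``image_pcs``).  Tissues with differing gene universes
    are reduced to the intersection.

    Returns ``(long_table: DataFrame, argmax: dict model -> tissue,
    pvalues: dict (tissue, model) -> array)``.
    """
    labels = list(tissues)
    universes = [set(tissues[t].index) for t in labels]
    common = set.intersection(*universes)
    if any(len(u) != len(common) for u in universes):
        import logging

        logging.getLogger(__name__).info(
            "tissues differ in gene universe; using intersection of %d genes", len(common)
        )
    common = sorted(common)
    models = {"phenotype": np.asarray(phenotype)}
    for j in range(min(3, image_pcs.shape[1])):
        models[f"PC{j + 1}"] = np.asarray(image_pcs[:, j], dtype=float)

    rows, pstore = [], {}
    for t in labels:
        X = tissues[t].loc[common].to_numpy(dtype=float).T  # samples x genes
        for mname, resp in models.items():
            pv, _ = gene_wise_regression(X, resp, sex=sex)
            pstore[(t, mname)] = pv
            est = estimate_pi0(pv, method=method)
            rows.append({"tissue": t, "model": mname, "pi1": est.pi1, "n_genes": len(pv)})
    table = pd.DataFrame(rows)
    argmax = {
        m: table[table["model"] == m].set_index("tissue")["pi1"].idxmax()
        for m in models
    }
    return table, argmax, pstore


def qq_plot_data(pvalues: np.ndarray):
    """Observed vs expected -log10 p-value quantiles and the median inflation.

    Expected quantiles are i/(m+1); the inflation ratio is the ratio of the
    median observed chi-square(1) quantile to its null median (0.4549), the
    genomic-control lambda.

    Returns ``(pairs [m x 2 of (-log10 expected, -log10 observed)], inflation)``.
    """
    p = np.sort(np.asarray(pvalues, dtype=float))
    m = len(p)
    if m < 1:
        raise ValueError("need at least one p-value")
    expected = np.arange(1, m + 1) / (m + 1.0)
    pairs = np.column_stack([-np.log10(expected), -np.log10(np.clip(p, 1e-300, 1.0))])
    chi = stats.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    inflation = float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
    return pairs, inflation


def qq_plot(pvalues: np.ndarray, ax=None, **kwargs):
    """Render the QQ plot; returns the matplotlib axis."""
    import matplotlib.pyplot as plt

    pairs, inflation = qq_plot_data(pvalues)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    ax.plot(pairs[:, 0], pairs[:, 1], ".", ms=3, **kwargs)
    lim = pairs[:, 0].max()
    ax.plot([0, lim], [0, lim], "k--", lw=1)
    ax.set_xlabel("expected $-\\log_{10} p$")
    ax.set_ylabel("observed $-\\log_{10} p$")
    ax.set_title(f"inflation ratio {inflation:.2f}")
    return ax
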