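"""Bulk RNA-seq preparation: TMM normalization, gene filtering, hidden factors.

TMM (trimmed mean of M-values) corrects for library composition between
samples: per sample, log ratios (M) against a reference library are trimmed
(30% on M, 5% on A by default), averaged with inverse-variance weights, and
exponentiated into a scaling factor; factors are rescaled to geometric mean 1.
Hidden confounding is captured by a factor-analysis surrogate — leading
singular directions of the gene-standardized, sex-residualized log-CPM — in
place of the full variational PEER model, and factors significantly
associated with the phenotype (BH q < 0.1) are selected as covariates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HiddenFactorSet",
    "tmm_normalize",
    "logcpm_from_counts",
    "filter_genes",
    "estimate_hidden_factors",
    "select_covariate_factors",
]


@dataclass
class HiddenFactorSet:
    """Latent factor scores with phenotype-association q-values and selection."""

    scores: np.ndarray  # samples x k
    assoc_q: np.ndarray | None = None
    selected: np.ndarray | None = None
    method: str = "residualized-SVD surrogate"

    @property
    def k(self) -> int:
        return self.scores.shape[1]


def _tmm_factor_pair(obs, obs_lib, ref, ref_lib, trim_m=0.30, trim_a=0.05):
    """TMM factor of one sample against the reference library."""
    use = (obs > 0) & (ref > 0)
    if not use.any():
        return 1.0
    p_obs = obs[use] / obs_lib
    p_ref = ref[use] / ref_lib
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M
    w = (obs_lib - obs[use]) / (obs_lib * obs[use]) + (ref_lib - ref[use]) / (ref_lib * ref[use])
    finite = np.isfinite(M) & np.isfinite(A)
    M, A, w = M[finite], A[finite], w[finite]
    if len(M) == 0:
        return 1.0
    lo_m, hi_m = np.quantile(M, [trim_m, 1.0 - trim_m])
    lo_a, hi_a = np.quantile(A, [trim_a, 1.0 - trim_a])
    keep = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
    if not keep.any():
        return 1.0
    f = (M[keep] / w[keep]).sum() / (1.0 / w[keep]).sum()
    return float(2.0**f)


def tmm_normalize(counts: pd.DataFrame, trim_m: float = 0.30, trim_a: float = 0.05):
    """Per-sample TMM factors and the log-CPM view.

    The reference sample is the one whose upper-quartile count fraction is
    closest to the mean upper quartile across samples.  Factors are rescaled
    to have geometric mean 1; log-CPM is
    ``log2((count + 0.5) / (lib_size * factor + 1) * 1e6)``.

    Returns ``(tmm_factors: Series, logcpm: DataFrame)``.
    """
    mat = counts.to_numpy(dtype=float)
    lib = mat.sum(axis=0)
    zero = lib <= 0
    if zero.any():
        bad = list(counts.columns[zero])
        raise ValueError(f"samples with all-zero counts: {bad}")
    uq = np.array([np.quantile(mat[:, j] / lib[j], 0.75) for j in range(mat.shape[1])])
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_factor_pair(mat[:, j], lib[j], mat[:, ref_idx], lib[ref_idx], trim_m, trim_a)
            if j != ref_idx
            else 1.0
            for j in range(mat.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))  # geometric mean 1
    eff = lib * factors
    logcpm = np.log2((mat + 0.5) / (eff[None, :] + 1.0) * 1e6)
    return (
        pd.Series(factors, index=counts.columns, name="tmm_factor"),
        pd.DataFrame(logcpm, index=counts.index, columns=counts.columns),
    )


def logcpm_from_counts(counts: pd.DataFrame) -> pd.DataFrame:
    """Convenience: TMM-normalize and return the log-CPM matrix."""
    return tmm_normalize(counts)[1]


def filter_genes(
    counts: pd.DataFrame,
    min_logcpm: float = 0.0,
    min_fraction: float = 0.2,
    logcpm: pd.DataFrame | None = None,
) -> pd.Index:
    """Genes expressed above ``min_logcpm`` in at least ``min_fraction`` of samples."""
    if not np.isfinite([min_logcpm, min_fraction]).all():
        raise ValueError("thresholds must be finite")
    if logcpm is None:
        logcpm = logcpm_from_counts(counts)
    frac = (logcpm.to_numpy() >= min_logcpm).mean(axis=1)
    return counts.index[frac >= min_fraction]


def estimate_hidden_factors(
    logcpm: pd.DataFrame,
    k: int,
    sex: np.ndarray | None = None,
) -> HiddenFactorSet:
    """Broad variance components via residualized SVD (PEER-style surrogate).

    Sex (if given) is regressed out of each gene, genes are standardized, and
    per-sample scores of the leading ``k`` singular directions are returned.
    The sign of each factor is fixed by making its largest-magnitude gene
    loading positive, so repeated runs are bit-identical.
    """
    n = logcpm.shape[1]
    if k >= n:
        raise ValueError(f"k={k} must be < number of samples ({n})")
    if k == 0:
        return HiddenFactorSet(scores=np.zeros((n, 0)))
    x = logcpm.to_numpy(dtype=float)
    if sex is not None:
        design = np.column_stack([np.ones(n), np.asarray(sex, dtype=float)])
        beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
        x = x - (design @ beta).T
    else:
        x = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    x = np.divide(x, np.where(sd < 1e-12, 1.0, sd))
    U, S, Vt = np.linalg.svd(x, full_matrices=False)
    scores = Vt[:k].T * S[:k]
    for j in range(k):
        lead = np.argmax(np.abs(U[:, j]))
        if U[lead, j] < 0:
            scores[:, j] *= -1.0
    return HiddenFactorSet(scores=scores)


def select_covariate_factors(
    factors: HiddenFactorSet,
    phenotype: np.ndarray,
    q_threshold: float = 0.1,
) -> HiddenFactorSet:
    """Flag factors associated with the phenotype at BH q < ``q_threshold``.

    Each factor is tested by logistic regression of the phenotype on its
    score (Wald p), and Benjamini-Hochberg q-values are computed across
    factors.
    """
    y = np.asarray(phenotype, dtype=float)
    k = factors.k
    if k == 0:
        return HiddenFactorSet(
            scores=factors.scores, assoc_q=np.array([]), selected=np.array([], dtype=bool)
        )
    pvals = np.empty(k)
    import warnings

    for j in range(k):
        X = sm.add_constant(factors.scores[:, j])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            # LR test is robust where separation degrades the Wald statistic
            pvals[j] = fit.llr_pvalue
        except Exception:  # perfect separation
            pvals[j] = 0.0
    _, qvals, *_ = multipletests(pvals, method="fdr_bh")
    return HiddenFactorSet(
        scores=factors.scores,
        assoc_q=qvals,
        selected=qvals < q_threshold,
        method=factors.method,
    )
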