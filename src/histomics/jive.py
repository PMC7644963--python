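"""Joint and Individual Variation Explained (JIVE) plus autoencoder reduction.

JIVE decomposes data blocks sharing a sample dimension as
``X_i = J_i + A_i + R_i``: a joint low-rank part whose sample-space row basis
is common across blocks, block-specific individual low-rank parts orthogonal
to the joint row-space, and residual.  The integrated prediction path
concatenates the denoised blocks (J_i + A_i), compresses them to 20 features
with a dense autoencoder (features -> 64 -> 20 -> 64 -> features, ReLU hidden
layers, linear output, Adam on mean-squared error), and feeds the bottleneck
scores to a random forest under stratified cross-validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .prediction import CVPrediction, auc

logger = logging.getLogger(__name__)

__all__ = [
    "JIVEDecomposition",
    "EncoderReduction",
    "jive_decompose",
    "select_ranks",
    "autoencoder_reduce",
    "integrated_rf_predict",
    "jive_autoencoder_representation",
]


@dataclass
class JIVEDecomposition:
    joint: list  # J_i, features_i x samples
    individual: list  # A_i
    residual: list  # R_i
    joint_rank: int
    individual_ranks: list
    converged: bool
    history: list = field(default_factory=list)
    block_scales: list = field(default_factory=list)

    def check_invariants(self, blocks, tol: float = 1e-6) -> None:
        """Additivity, rank bounds, and joint/individual row-space orthogonality."""
        J_rows = np.vstack(self.joint)
        total = np.linalg.norm(np.vstack(blocks))
        for X, J, A, R, ri in zip(
            blocks, self.joint, self.individual, self.residual, self.individual_ranks
        ):
            assert np.allclose(X, J + A + R, atol=1e-8 * max(1.0, np.abs(X).max()))
            assert np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.linalg.norm(A))) <= ri
            if total > 0:
                assert np.linalg.norm(J_rows @ A.T) <= tol * total


@dataclass
class EncoderReduction:
    scores: np.ndarray  # samples x bottleneck
    loss_trace: np.ndarray
    architecture: tuple


def _svd_truncate(X: np.ndarray, r: int):
    """Rank-r truncation; returns (approximation, right row-space basis V_r)."""
    if r == 0:
        return np.zeros_like(X), np.zeros((X.shape[1], 0))
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    return (U[:, :r] * S[:r]) @ Vt[:r], Vt[:r].T


def jive_decompose(
    blocks: list,
    r: int,
    r_i: list,
    tol: float = 1e-6,
    max_iter: int = 500,
    scale: bool = True,
) -> JIVEDecomposition:
    """Alternating JIVE decomposition of centered blocks (features_i x samples).

    Each iteration takes a rank-``r`` SVD of the stacked (X_i - A_i) as the
    joint part, then a rank-``r_i[i]`` SVD of (X_i - J_i) projected orthogonal
    to the joint row-space as each individual part, until the relative change
    in total fit drops below ``tol``.  Blocks are divided by their Frobenius
    norm beforehand (undone in the returned matrices).
    """
    n = blocks[0].shape[1]
    if any(b.shape[1] != n for b in blocks):
        raise ValueError("blocks must share the sample dimension")
    if r + (max(r_i) if r_i else 0) >= n:
        raise ValueError("r + max(r_i) must be < number of samples")
    scales = [max(np.linalg.norm(b), 1e-12) if scale else 1.0 for b in blocks]
    Xs = [np.asarray(b, dtype=float) / s for b, s in zip(blocks, scales)]
    sizes = [b.shape[0] for b in Xs]
    A = [np.zeros_like(b) for b in Xs]
    J = [np.zeros_like(b) for b in Xs]
    prev_fit = np.inf
    history = []
    converged = False
    for it in range(max_iter):
        stacked = np.vstack([X - a for X, a in zip(Xs, A)])
        Jstack, V = _svd_truncate(stacked, r)
        offs = np.cumsum([0] + sizes)
        J = [Jstack[offs[i]:offs[i + 1]] for i in range(len(Xs))]
        proj = np.eye(n) - V @ V.T  # orthogonal complement of joint row-space
        A = [_svd_truncate((X - j) @ proj, ri)[0] for X, j, ri in zip(Xs, J, r_i)]
        fit = sum(np.linalg.norm(X - j - a) ** 2 for X, j, a in zip(Xs, J, A))
        history.append(fit)
        if np.isfinite(prev_fit) and abs(prev_fit - fit) <= tol * max(fit, 1e-12):
            converged = True
            break
        prev_fit = fit
    if not converged:
        logger.warning("JIVE did not converge in %d iterations; returning best iterate", max_iter)
    R = [X - j - a for X, j, a in zip(Xs, J, A)]
    return JIVEDecomposition(
        joint=[j * s for j, s in zip(J, scales)],
        individual=[a * s for a, s in zip(A, scales)],
        residual=[x * s for x, s in zip(R, scales)],
        joint_rank=r,
        individual_ranks=list(r_i),
        converged=converged,
        history=history,
        block_scales=scales,
    )


def select_ranks(blocks: list, n_perm: int = 20, alpha: float = 0.05, seed: int = 0):
    """Permutation-based selection of the joint and individual ranks.

    Joint rank: the k-th singular value of the stacked scaled blocks is
    compared sequentially with the (1 - alpha) quantile of the k-th singular
    value after independently permuting each block's sample order (which
    keeps within-block structure but destroys cross-block alignment).
    Individual ranks: per block after removing the joint approximation,
    singular values are compared with a within-row entry-permutation
    (structure-free) null the same way.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x71E]))
    scales = [max(np.linalg.norm(b), 1e-12) for b in blocks]
    Xs = [np.asarray(b, dtype=float) / s for b, s in zip(blocks, scales)]
    n = Xs[0].shape[1]

    def _sequential_rank(sv, null_sv):
        # null_sv: n_perm x len(sv); stop at the first non-significant component
        thresh = np.quantile(null_sv, 1.0 - alpha, axis=0)
        r = 0
        for k in range(min(len(sv), null_sv.shape[1])):
            if sv[k] > thresh[k]:
                r += 1
            else:
                break
        return r

    sv = np.linalg.svd(np.vstack(Xs), compute_uv=False)
    null = np.array(
        [
            np.linalg.svd(
                np.vstack([X[:, rng.permutation(n)] for X in Xs]), compute_uv=False
            )
            for _ in range(n_perm)
        ]
    )
    r = _sequential_rank(sv, null)

    if r > 0:
        _, V = _svd_truncate(np.vstack(Xs), r)
    else:
        V = np.zeros((n, 0))
    proj = np.eye(n) - V @ V.T
    r_i = []
    for X in Xs:
        Xres = X @ proj
        sv = np.linalg.svd(Xres, compute_uv=False)
        null = []
        for _ in range(n_perm):
            perm = np.array([row[rng.permutation(n)] for row in Xres])
            null.append(np.linalg.svd(perm, compute_uv=False))
        r_i.append(_sequential_rank(sv, np.array(null)))
    return r, r_i


# ---------------------------------------------------------------------------
# dense autoencoder (numpy Adam backprop)


class _Adam:
    def __init__(self, params, lr):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, b1=0.9, b2=0.999, eps=1e-8):
        self.t += 1
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + eps)


def _he_init(rng, fan_in, fan_out):
    return rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)


def autoencoder_reduce(
    M: np.ndarray,
    bottleneck: int = 20,
    epochs: int = 500,
    lr: float = 1e-3,
    seed: int = 0,
    hidden: int = 64,
    batch_size: int = 32,
) -> EncoderReduction:
    """Nonlinear reduction to ``bottleneck`` features via a symmetric autoencoder.

    Architecture features -> hidden -> bottleneck -> hidden -> features with
    ReLU on hidden layers and linear bottleneck/output, trained with Adam on
    mean-squared reconstruction error.  A NaN loss triggers one restart at
    half the learning rate; a second failure raises.
    """
    X = np.asarray(M, dtype=float)
    n, p = X.shape
    if p <= bottleneck:
        logger.info("bottleneck >= feature count: identity-capacity regime")

    def _train(lr_now):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xAE]))
        dims = [p, hidden, bottleneck, hidden, p]
        Ws = [_he_init(rng, dims[i], dims[i + 1]) for i in range(4)]
        bs = [np.zeros(dims[i + 1]) for i in range(4)]
        opt = _Adam(Ws + bs, lr_now)
        trace = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            ep_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start:start + batch_size]
                xb = X[idx]
                # forward: ReLU on layers 0 and 2; linear bottleneck and output
                h1 = np.maximum(xb @ Ws[0] + bs[0], 0.0)
                z = h1 @ Ws[1] + bs[1]
                h2 = np.maximum(z @ Ws[2] + bs[2], 0.0)
                out = h2 @ Ws[3] + bs[3]
                err = out - xb
                loss = float((err**2).mean())
                ep_loss += loss * len(idx)
                if not np.isfinite(loss):
                    return None, None, None
                g_out = 2.0 * err / err.size
                gW3 = h2.T @ g_out
                gb3 = g_out.sum(0)
                g_h2 = (g_out @ Ws[3].T) * (h2 > 0)
                gW2 = z.T @ g_h2
                gb2 = g_h2.sum(0)
                g_z = g_h2 @ Ws[2].T
                gW1 = h1.T @ g_z
                gb1 = g_z.sum(0)
                g_h1 = (g_z @ Ws[1].T) * (h1 > 0)
                gW0 = xb.T @ g_h1
                gb0 = g_h1.sum(0)
                opt.step(Ws + bs, [gW0, gW1, gW2, gW3, gb0, gb1, gb2, gb3])
            trace.append(ep_loss / n)
        h1 = np.maximum(X @ Ws[0] + bs[0], 0.0)
        scores = h1 @ Ws[1] + bs[1]
        return scores, np.array(trace), dims

    scores, trace, dims = _train(lr)
    if scores is None:
        logger.warning("NaN loss; restarting autoencoder at half learning rate")
        scores, trace, dims = _train(lr / 2.0)
        if scores is None:
            raise RuntimeError("autoencoder training diverged twice (NaN loss)")
    return EncoderReduction(scores=scores, loss_trace=trace, architecture=tuple(dims))


def jive_autoencoder_representation(
    blocks: list,
    r: int = 2,
    r_i: list | None = None,
    bottleneck: int = 20,
    epochs: int = 500,
    lr: float = 1e-3,
    seed: int = 0,
    skip_jive: bool = False,
):
    """Denoise blocks with JIVE, concatenate, and reduce to 20 features.

    With ``skip_jive`` the autoencoder consumes the concatenated raw blocks
    instead.  Input columns are standardized before training.  Returns
    ``(EncoderReduction, JIVEDecomposition | None)``.
    """
    if r_i is None:
        r_i = [2] * len(blocks)
    decomp = None
    if skip_jive:
        concat = np.vstack(blocks).T  # samples x total features
    else:
        decomp = jive_decompose(blocks, r=r, r_i=r_i)
        concat = np.vstack([J + A for J, A in zip(decomp.joint, decomp.individual)]).T
    sd = concat.std(axis=0)
    z = (concat - concat.mean(axis=0)) / np.where(sd < 1e-12, 1.0, sd)
    red = autoencoder_reduce(z, bottleneck=bottleneck, epochs=epochs, lr=lr, seed=seed)
    return red, decomp


def integrated_rf_predict(
    scores: np.ndarray,
    y: np.ndarray,
    n_folds: int = 5,
    seed: int = 0,
    rf_trees: int = 500,
) -> CVPrediction:
    """Random-forest prediction from the 20 integrated features, stratified CV."""
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.model_selection import StratifiedKFold

    X = np.asarray(scores, dtype=float)
    y = np.asarray(y, dtype=int)
    prob = np.zeros(len(y))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    for tr, te in skf.split(X, y):
        rf = RandomForestClassifier(n_estimators=rf_trees, max_features="sqrt", random_state=seed)
        rf.fit(X[tr], y[tr])
        prob[te] = rf.predict_proba(X[te])[:, 1]
    value, roc = auc(prob, y)
    return CVPrediction(prob=prob, n_repeats=1, n_folds=n_folds, auc=value, roc_points=roc)
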