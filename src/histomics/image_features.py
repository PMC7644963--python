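"""Tissue segmentation and multi-scale Haralick texture features.

A whole-slide-style RGB image is segmented by adaptive thresholding of the
channel-mean intensity (tissue is darker than the near-white background),
small pieces are discarded, and for every remaining piece a gray-level
co-occurrence matrix (GLCM) is accumulated per color channel at pixel offsets
of 1, 10 and 100, averaged over the four principal directions.  Thirteen
classical Haralick statistics per GLCM give 13 x 3 channels x 3 distances =
117 features per piece; piece values are averaged per sample.  Across
samples, features are variance-stabilized by a signed log2 transform and
standardized per column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "TissueSegmentation",
    "FeatureMatrix",
    "segment_tissue",
    "filter_pieces",
    "glcm",
    "haralick13",
    "extract_features",
    "feature_names",
    "normalize_features",
]

HARALICK_NAMES = [
    "asm",  # angular second moment (energy)
    "contrast",
    "correlation",
    "variance",  # sum of squares
    "idm",  # inverse difference moment (homogeneity)
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",  # information measure of correlation 1
    "imc2",  # information measure of correlation 2
]

# (row, col) offsets for directions 0, 45, 90, 135 degrees
_DIRECTIONS = [(0, 1), (-1, 1), (-1, 0), (-1, -1)]


@dataclass
class TissueSegmentation:
    """Labeled tissue pieces; label 0 is background, k>0 the k-th largest piece."""

    labels: np.ndarray
    piece_areas: np.ndarray

    @property
    def n_pieces(self) -> int:
        return len(self.piece_areas)


@dataclass
class FeatureMatrix:
    """Samples x 117 feature table with transform provenance."""

    data: pd.DataFrame
    transform: str = "raw"  # raw | log2 | log2+standardized


def segment_tissue(image: np.ndarray, window: int = 101, offset: float = 0.02) -> TissueSegmentation:
    """Adaptive-threshold segmentation of tissue pieces.

    A pixel is tissue when its channel-mean intensity falls below the local
    mean over a ``window x window`` neighborhood minus ``offset``.
    8-connected components are labeled 1..K in decreasing area order.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 3, got {window}")
    img = np.asarray(image, dtype=float)
    gray = img.mean(axis=2) if img.ndim == 3 else img
    local_mean = ndimage.uniform_filter(gray, size=window, mode="reflect")
    tissue = gray < (local_mean - offset)
    labels, n = ndimage.label(tissue, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        return TissueSegmentation(labels=np.zeros_like(labels), piece_areas=np.array([], dtype=int))
    areas = np.bincount(labels.ravel())[1:]
    order = np.argsort(-areas, kind="stable")
    remap = np.zeros(n + 1, dtype=int)
    remap[order + 1] = np.arange(1, n + 1)
    return TissueSegmentation(labels=remap[labels], piece_areas=areas[order])


def filter_pieces(seg: TissueSegmentation, min_area: int) -> TissueSegmentation:
    """Drop pieces smaller than ``min_area`` pixels, relabeling contiguously."""
    if min_area < 0:
        raise ValueError("min_area must be >= 0")
    keep = np.flatnonzero(seg.piece_areas >= min_area)  # already area-sorted
    remap = np.zeros(seg.n_pieces + 1, dtype=int)
    remap[keep + 1] = np.arange(1, len(keep) + 1)
    return TissueSegmentation(labels=remap[seg.labels], piece_areas=seg.piece_areas[keep])


def _quantize(channel: np.ndarray, mask: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of the masked intensity range into ``levels`` bins."""
    vals = channel[mask]
    lo, hi = vals.min(), vals.max()
    if hi <= lo:
        return np.zeros_like(channel, dtype=np.intp)
    q = np.floor((channel - lo) / (hi - lo) * levels).astype(np.intp)
    return np.clip(q, 0, levels - 1)


def glcm(
    channel: np.ndarray,
    mask: np.ndarray,
    distance: int,
    levels: int = 32,
    directions=None,
) -> np.ndarray:
    """Masked, direction-averaged, symmetrized gray-level co-occurrence matrix.

    Pairs are counted only when both pixels lie inside the mask at the given
    offset; the four directions (0, 45, 90, 135 degrees — or the (dr, dc)
    offsets in ``directions``) are accumulated, the matrix is symmetrized and
    normalized to sum to 1.  When the mask admits no pair at this distance an
    all-zero ("empty") matrix is returned.
    """
    if distance < 1:
        raise ValueError("distance must be >= 1")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return np.zeros((levels, levels))
    q = _quantize(np.asarray(channel, dtype=float), mask, levels)
    h, w = q.shape
    P = np.zeros((levels, levels), dtype=float)
    for dr, dc in (directions if directions is not None else _DIRECTIONS):
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        m = mask[r0:r1, c0:c1] & mask[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        if not m.any():
            continue
        np.add.at(P, (a[m], b[m]), 1.0)
    P = P + P.T
    total = P.sum()
    if total > 0:
        P /= total
    return P


def haralick13(P: np.ndarray) -> np.ndarray:
    """The 13 classical Haralick statistics of a normalized GLCM.

    Entropies use log base 2 with the convention 0*log(0) = 0.  An empty
    (all-zero) matrix yields a vector of NaN sentinels, which callers exclude
    from piece averaging.
    """
    P = np.asarray(P, dtype=float)
    n = P.shape[0]
    if P.shape[0] != P.shape[1]:
        raise ValueError("GLCM must be square")
    if P.sum() <= 0:
        return np.full(13, np.nan)

    i = np.arange(n, dtype=float)
    px = P.sum(axis=1)
    py = P.sum(axis=0)
    mu_x = (i * px).sum()
    mu_y = (i * py).sum()
    sd_x = np.sqrt(((i - mu_x) ** 2 * px).sum())
    sd_y = np.sqrt(((i - mu_y) ** 2 * py).sum())

    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj

    def _plog(p):
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)

    asm = (P**2).sum()
    contrast = (diff**2 * P).sum()
    if sd_x * sd_y > 0:
        correlation = ((ii * jj * P).sum() - mu_x * mu_y) / (sd_x * sd_y)
    else:
        correlation = 1.0  # degenerate single-level distribution
    variance = ((ii - mu_x) ** 2 * P).sum()
    idm = (P / (1.0 + diff**2)).sum()

    # p_{x+y}(k), k = 0 .. 2n-2 and p_{x-y}(k), k = 0 .. n-1
    psum = np.zeros(2 * n - 1)
    np.add.at(psum, (ii + jj).astype(int).ravel(), P.ravel())
    pdiff = np.zeros(n)
    np.add.at(pdiff, np.abs(diff).astype(int).ravel(), P.ravel())
    k_sum = np.arange(2 * n - 1, dtype=float)
    k_diff = np.arange(n, dtype=float)

    sum_average = (k_sum * psum).sum()
    sum_variance = ((k_sum - sum_average) ** 2 * psum).sum()
    sum_entropy = -_plog(psum).sum()
    entropy = -_plog(P).sum()
    diff_mean = (k_diff * pdiff).sum()
    difference_variance = ((k_diff - diff_mean) ** 2 * pdiff).sum()
    difference_entropy = -_plog(pdiff).sum()

    # information measures of correlation
    pxy = np.outer(px, py)
    with np.errstate(divide="ignore", invalid="ignore"):
        hxy1 = -np.where((P > 0) & (pxy > 0), P * np.log2(np.where(pxy > 0, pxy, 1.0)), 0.0).sum()
        hxy2 = -_plog(pxy).sum()
    hx = -_plog(px).sum()
    hy = -_plog(py).sum()
    denom = max(hx, hy)
    imc1 = (entropy - hxy1) / denom if denom > 0 else 0.0
    imc2 = np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy))))

    return np.array(
        [asm, contrast, correlation, variance, idm, sum_average, sum_variance,
         sum_entropy, entropy, difference_variance, difference_entropy, imc1, imc2]
    )


def feature_names(distances=(1, 10, 100)) -> list:
    """Column names ``h{1..13}_{R|G|B}_d{distance}`` in extraction order."""
    names = []
    for ch in "RGB":
        for d in distances:
            for k in range(13):
                names.append(f"h{k + 1}_{ch}_d{d}")
    return names


def extract_features(
    image: np.ndarray,
    seg: TissueSegmentation,
    distances=(1, 10, 100),
    levels: int = 32,
) -> np.ndarray | None:
    """117-dimensional multi-scale Haralick vector for one sample.

    Features are computed per piece on its bounding region under its mask and
    averaged across pieces with equal weights; pieces whose GLCM is empty at a
    given channel/distance are excluded from that entry's average.  Returns
    ``None`` (sample flagged missing) when the segmentation has no pieces.
    """
    if seg.n_pieces == 0:
        logger.warning("no tissue pieces found; sample flagged missing")
        return None
    img = np.asarray(image, dtype=float)
    per_piece = []
    slices = ndimage.find_objects(seg.labels)
    for k in range(1, seg.n_pieces + 1):
        sl = slices[k - 1]
        pm = seg.labels[sl] == k
        feats = []
        for c in range(3):
            chan = img[:, :, c][sl]
            for d in distances:
                feats.append(haralick13(glcm(chan, pm, distance=d, levels=levels)))
        per_piece.append(np.concatenate(feats))
    stacked = np.vstack(per_piece)
    with np.errstate(invalid="ignore"):
        out = np.nanmean(stacked, axis=0)
    if np.isnan(out).any():
        logger.warning("some channel/distance cells empty in every piece; filled with 0")
        out = np.nan_to_num(out, nan=0.0)
    assert out.shape == (13 * 3 * len(distances),)
    return out


def extract_cohort_features(
    images,
    sample_ids=None,
    window: int = 101,
    offset: float = 0.02,
    min_area_frac: float = 0.001,
    distances=(1, 10, 100),
    levels: int = 32,
) -> FeatureMatrix:
    """Segment + filter + extract for a list of images; returns a raw FeatureMatrix."""
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(len(images))]
    rows, kept = [], []
    for sid, img in zip(sample_ids, images):
        seg = segment_tissue(img, window=window, offset=offset)
        seg = filter_pieces(seg, min_area=int(min_area_frac * img.shape[0] * img.shape[1]))
        vec = extract_features(img, seg, distances=distances, levels=levels)
        if vec is None:
            logger.warning("sample %s excluded: no pieces after filtering", sid)
            continue
        rows.append(vec)
        kept.append(sid)
    data = pd.DataFrame(np.vstack(rows), index=kept, columns=feature_names(distances))
    return FeatureMatrix(data=data, transform="raw")


def normalize_features(fm: FeatureMatrix) -> FeatureMatrix:
    """Signed-log2 transform then per-column standardization.

    Correlation-type Haralick features can be negative or zero, so the
    transform is ``sign(x) * log2(1 + |x|)``; each column is then centered and
    scaled to unit variance.  Constant columns become all zeros.
    """
    if fm.data.shape[0] < 2:
        raise ValueError("standardization needs at least 2 samples")
    x = fm.data.to_numpy(dtype=float)
    x = np.sign(x) * np.log2(1.0 + np.abs(x))
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    const = sd < 1e-12
    if const.any():
        logger.info("%d constant feature columns set to 0", int(const.sum()))
    sd_safe = np.where(const, 1.0, sd)
    z = (x - mean) / sd_safe
    z[:, const] = 0.0
    return FeatureMatrix(
        data=pd.DataFrame(z, index=fm.data.index, columns=fm.data.columns),
        transform="log2+standardized",
    )
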