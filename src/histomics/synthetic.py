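"""Synthetic cohorts with known ground truth.

Every downstream stage of the pipeline (texture features, expression
normalization, prediction, integration, network embedding, cross-tissue
concordance) is exercised on data produced here, so each generator plants a
signal whose location and strength are recorded in the returned object.

The image generator draws irregular "tissue pieces" of eosin-like hue on a
near-white background; within-piece texture is a Gaussian random field whose
correlation length differs between pathology classes, which is the kind of
difference gray-level co-occurrence statistics respond to.  The expression
generator draws negative-binomial counts with a dispersion-mean trend,
log-normal library sizes, planted differential genes and optional latent
confounding factors.  The network generator produces a planted-partition
graph whose signal module is guaranteed connected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon

__all__ = [
    "SyntheticCohort",
    "SyntheticExpression",
    "SyntheticNetwork",
    "generate_histology_cohort",
    "generate_expression",
    "generate_network",
    "generate_multitissue",
    "write_cohort",
    "write_expression",
    "write_network",
]


@dataclass
class SyntheticCohort:
    """Images plus per-sample phenotype/covariates and ground-truth masks."""

    images: list  # each H x W x 3 float array in [0, 1]
    phenotype: np.ndarray  # 1 = pathology present, 0 = absent
    sex: np.ndarray  # binary
    age: np.ndarray  # years
    masks: list = field(default_factory=list)  # boolean tissue masks, H x W
    sample_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.phenotype):
            raise ValueError("number of images must equal phenotype length")
        if not set(np.unique(self.phenotype)) <= {0, 1}:
            raise ValueError("phenotype must be binary 0/1")
        for img, mask in zip(self.images, self.masks):
            if img.shape[:2] != mask.shape:
                raise ValueError("truth mask must match image height/width")
        if not self.sample_ids:
            self.sample_ids = [f"S{i:04d}" for i in range(len(self.images))]


@dataclass
class SyntheticExpression:
    """Counts with planted differential genes and latent factors."""

    counts: pd.DataFrame  # genes x samples, nonnegative integers
    de_genes: np.ndarray  # indices of planted differential genes
    lfc: np.ndarray  # signed log2 fold change per DE gene
    factors: np.ndarray  # samples x k latent confounder scores
    library_sizes: np.ndarray  # per-sample positive reals
    phenotype: np.ndarray

    def __post_init__(self) -> None:
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be nonnegative")
        n_genes = self.counts.shape[0]
        if len(self.de_genes) and (self.de_genes.min() < 0 or self.de_genes.max() >= n_genes):
            raise ValueError("de_genes out of gene index range")
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")


@dataclass
class SyntheticNetwork:
    """Undirected gene graph with a planted connected module."""

    edges: set  # unordered gene-index pairs, stored as sorted tuples
    module_genes: np.ndarray
    n_genes: int

    def __post_init__(self) -> None:
        for a, b in self.edges:
            if a == b:
                raise ValueError("self-edges are not allowed")
        g = nx.Graph()
        g.add_nodes_from(self.module_genes.tolist())
        g.add_edges_from(e for e in self.edges
                         if e[0] in set(self.module_genes) and e[1] in set(self.module_genes))
        if len(self.module_genes) > 1 and not nx.is_connected(g):
            raise ValueError("module genes must induce a connected subgraph")


def _blob_mask(rng: np.random.Generator, size: int) -> np.ndarray:
    """Random ellipse with a low-frequency perturbed boundary, rasterized."""
    cy = rng.uniform(0.25, 0.75) * size
    cx = rng.uniform(0.25, 0.75) * size
    r0 = rng.uniform(0.12, 0.22) * size
    aspect = rng.uniform(0.6, 1.0)
    rot = rng.uniform(0, np.pi)
    theta = np.linspace(0, 2 * np.pi, 240, endpoint=False)
    wobble = np.zeros_like(theta)
    for k in range(2, 6):
        wobble += rng.normal(0, 0.05) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    rad = r0 * (1.0 + wobble)
    ex = rad * np.cos(theta)
    ey = rad * np.sin(theta) * aspect
    xs = cx + ex * np.cos(rot) - ey * np.sin(rot)
    ys = cy + ex * np.sin(rot) + ey * np.cos(rot)
    rr, cc = draw_polygon(np.clip(ys, 0, size - 1), np.clip(xs, 0, size - 1), (size, size))
    mask = np.zeros((size, size), dtype=bool)
    mask[rr, cc] = True
    return mask


def _texture_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Unit-variance Gaussian random field with correlation length ``sigma``."""
    noise = rng.standard_normal((size, size))
    if sigma > 0:
        fld = ndimage.gaussian_filter(noise, sigma, mode="wrap")
    else:
        fld = noise
    return fld / max(fld.std(), 1e-12)


def generate_histology_cohort(
    n: int,
    prevalence: float = 0.5,
    texture_shift: float = 0.0,
    image_size: int = 512,
    n_pieces_range: tuple = (2, 5),
    seed: int = 0,
    base_sigma: float = 1.0,
    texture_amp: float = 0.35,
) -> SyntheticCohort:
    """Generate a two-class image cohort differing only in texture statistics.

    Cases (phenotype 1) get within-piece texture smoothed with
    ``base_sigma + texture_shift``; controls use ``base_sigma``.  With
    ``texture_shift=0`` the two classes are identical in distribution, so any
    downstream predictor should sit at chance.

    The number of cases is ``round(n * prevalence)``; assignment to samples is
    randomized by the seed.  Output is bit-reproducible for a fixed seed.
    """
    if n < 2:
        raise ValueError("need at least 2 samples")
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    if image_size < 128:
        raise ValueError(f"image_size must be >= 128, got {image_size}")
    if texture_shift < 0:
        raise ValueError("texture_shift must be nonnegative")

    root = np.random.SeedSequence([int(seed), 0x1A6E])
    master = np.random.default_rng(root)
    n_cases = int(round(n * prevalence))
    phenotype = np.zeros(n, dtype=int)
    phenotype[master.permutation(n)[:n_cases]] = 1
    sex = master.integers(0, 2, size=n)
    age = master.uniform(20, 70, size=n)

    images, masks = [], []
    children = root.spawn(n)
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        n_pieces = int(rng.integers(n_pieces_range[0], n_pieces_range[1] + 1))
        img = rng.uniform(0.95, 1.0, size=(image_size, image_size, 3))
        tissue = np.zeros((image_size, image_size), dtype=bool)
        sigma = base_sigma + (texture_shift if phenotype[i] == 1 else 0.0)
        for _ in range(n_pieces):
            pm = _blob_mask(rng, image_size)
            # texture drawn regardless of class size so that the random
            # stream is identical across classes when texture_shift == 0
            fld = _texture_field(rng, image_size, sigma)
            base = np.array([0.82, 0.52, 0.62]) + rng.normal(0, 0.03, size=3)
            for c in range(3):
                chan = img[:, :, c]
                chan[pm] = np.clip(base[c] * (1.0 + texture_amp * fld[pm]), 0.0, 0.94)
            tissue |= pm
        images.append(np.clip(img, 0.0, 1.0).astype(np.float32))  # float32 halves cohort memory
        masks.append(tissue)
    return SyntheticCohort(images=images, phenotype=phenotype, sex=sex, age=age, masks=masks)


def generate_expression(
    n_genes: int,
    n_samples: int,
    n_de: int,
    lfc: float,
    n_factors: int = 0,
    phenotype: np.ndarray | None = None,
    seed: int = 0,
    factor_sd: float = 0.5,
    libsize_sd: float = 0.3,
    de_genes: np.ndarray | None = None,
    lfc_signs: np.ndarray | None = None,
) -> SyntheticExpression:
    """Negative-binomial counts with planted case/control differential genes.

    Gene means follow a log-normal abundance distribution; dispersion follows
    the usual decreasing trend in the mean (phi = 0.05 + 2/mean).  DE genes
    have their mean multiplied by ``2**(lfc * phenotype)`` with random sign
    per gene; latent factors add low-rank structure to the log-means and
    library sizes are log-normal(0, ``libsize_sd``).
    """
    if n_de > n_genes:
        raise ValueError(f"n_de={n_de} exceeds n_genes={n_genes}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xE529]))
    if phenotype is None:
        phenotype = rng.integers(0, 2, size=n_samples)
    phenotype = np.asarray(phenotype, dtype=int)
    if len(phenotype) != n_samples:
        raise ValueError("phenotype length must equal n_samples")

    log2_mu = rng.normal(4.0, 1.5, size=n_genes)
    mu = 2.0 ** log2_mu
    if de_genes is None:
        de_genes = rng.choice(n_genes, size=n_de, replace=False)
    de_genes = np.asarray(de_genes)
    if lfc_signs is None:
        lfc_signs = rng.choice([-1.0, 1.0], size=len(de_genes))
    lfc_per_gene = lfc * lfc_signs

    log2_mean = np.tile(np.log2(mu)[:, None], (1, n_samples))
    log2_mean[de_genes, :] += lfc_per_gene[:, None] * phenotype[None, :]

    factors = rng.standard_normal((n_samples, max(n_factors, 0)))
    if n_factors > 0:
        loadings = rng.normal(0.0, factor_sd, size=(n_genes, n_factors))
        log2_mean += loadings @ factors.T

    library = np.exp(rng.normal(0.0, libsize_sd, size=n_samples))
    mean = 2.0 ** log2_mean * library[None, :]

    phi = 0.05 + 2.0 / np.maximum(mu, 1e-6)  # dispersion-mean trend
    # gamma-Poisson mixture == negative binomial with dispersion phi
    shape = 1.0 / phi
    lam = rng.gamma(shape[:, None], mean / shape[:, None])
    counts = rng.poisson(lam)

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    return SyntheticExpression(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        de_genes=de_genes,
        lfc=lfc_per_gene,
        factors=factors,
        library_sizes=library,
        phenotype=phenotype,
    )


def generate_network(
    n_genes: int,
    module_genes: np.ndarray,
    p_in: float,
    p_out: float,
    seed: int = 0,
) -> SyntheticNetwork:
    """Planted-partition graph with a guaranteed-connected signal module.

    Pairs inside the module connect with probability ``p_in``; every other
    pair with ``p_out``.  If the module is disconnected, edges along a random
    spanning tree of the module are added.
    """
    if not 0.0 <= p_out < p_in <= 1.0 and not (p_in == p_out == 0.0):
        raise ValueError("require 0 <= p_out < p_in <= 1 (or both zero)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6E7]))
    module_genes = np.asarray(sorted(module_genes))
    in_module = np.zeros(n_genes, dtype=bool)
    in_module[module_genes] = True

    iu, ju = np.triu_indices(n_genes, k=1)
    pair_p = np.where(in_module[iu] & in_module[ju], p_in, p_out)
    keep = rng.random(len(iu)) < pair_p
    edges = {(int(a), int(b)) for a, b in zip(iu[keep], ju[keep])}

    # connectivity repair: random spanning tree over the module's components
    if len(module_genes) > 1:
        g = nx.Graph()
        g.add_nodes_from(module_genes.tolist())
        mset = set(module_genes.tolist())
        g.add_edges_from(e for e in edges if e[0] in mset and e[1] in mset)
        comps = [list(c) for c in nx.connected_components(g)]
        if len(comps) > 1:
            rng.shuffle(comps)
            for prev, nxt in zip(comps[:-1], comps[1:]):
                a = int(rng.choice(prev))
                b = int(rng.choice(nxt))
                edges.add((min(a, b), max(a, b)))
    return SyntheticNetwork(edges=edges, module_genes=module_genes, n_genes=n_genes)


def generate_multitissue(
    n_tissues: int,
    signal_strengths,
    phenotype: np.ndarray,
    n_genes: int = 2000,
    n_de: int = 200,
    lfc: float = 1.5,
    n_factors: int = 0,
    seed: int = 0,
) -> list:
    """Expression for several tissues sharing one phenotype signal.

    Tissue ``t`` carries ``round(signal_strengths[t] * n_de)`` truly associated
    genes, drawn from a common master DE set so overlap across tissues mirrors
    shared biology.  All tissues share the same gene universe.
    """
    signal_strengths = np.asarray(signal_strengths, dtype=float)
    if len(signal_strengths) != n_tissues:
        raise ValueError("signal_strengths length must equal n_tissues")
    if ((signal_strengths < 0) | (signal_strengths > 1)).any():
        raise ValueError("signal strengths must be in [0, 1]")
    master_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x7155]))
    master_de = master_rng.choice(n_genes, size=n_de, replace=False)
    tissues = []
    for t in range(n_tissues):
        k = int(round(signal_strengths[t] * n_de))
        tissues.append(
            generate_expression(
                n_genes=n_genes,
                n_samples=len(phenotype),
                n_de=k,
                lfc=lfc,
                n_factors=n_factors,
                phenotype=phenotype,
                seed=int(master_rng.integers(0, 2**31 - 1)),
                de_genes=master_de[:k],
            )
        )
    return tissues


# ---------------------------------------------------------------------------
# plain-text writers


def write_cohort(cohort: SyntheticCohort, out_dir) -> None:
    """Write PNG images, a covariate TSV, and ground truth as JSON + PNG masks."""
    from PIL import Image

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    for sid, img, mask in zip(cohort.sample_ids, cohort.images, cohort.masks):
        Image.fromarray((img * 255).astype(np.uint8)).save(out / "images" / f"{sid}.png")
        Image.fromarray((mask * 255).astype(np.uint8)).save(out / "images" / f"{sid}_mask.png")
    pd.DataFrame(
        {
            "sample_id": cohort.sample_ids,
            "phenotype": cohort.phenotype,
            "sex": cohort.sex,
            "age": np.round(cohort.age, 1),
        }
    ).to_csv(out / "phenotype.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump({"phenotype": cohort.phenotype.tolist()}, fh)


def write_expression(expr: SyntheticExpression, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr.counts.to_csv(out / "counts.tsv", sep="\t")
    with open(out / "truth.json", "w") as fh:
        json.dump(
            {
                "de_genes": [int(i) for i in expr.de_genes],
                "lfc": [float(x) for x in expr.lfc],
                "phenotype": expr.phenotype.tolist(),
            },
            fh,
        )


def write_network(net: SyntheticNetwork, path) -> None:
    rows = sorted(net.edges)
    pd.DataFrame(rows, columns=["gene_a", "gene_b"]).to_csv(path, sep="\t", index=False)
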