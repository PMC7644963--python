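"""Gene-set enrichment of phenotype-associated genes.

Significant genes are called at Benjamini-Hochberg q < 0.1 from per-gene
p-values; each user-supplied gene set (GMT format) is then tested for
over-representation among the significant genes by a one-sided Fisher exact
(hypergeometric) test against the background of all tested genes, and set
p-values are again BH-adjusted with significance declared at q < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "bh_qvalues",
    "fisher_enrichment",
    "run_enrichment",
    "read_gmt",
    "write_gmt",
]


@dataclass
class GeneSetCollection:
    sets: dict  # name -> set of gene ids
    descriptions: dict

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> genes...)."""
    sets, desc = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name = parts[0]
            if name in sets:
                raise ValueError(f"duplicate gene set name {name!r}")
            sets[name] = set(g for g in parts[2:] if g)
            desc[name] = parts[1]
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, collection.descriptions.get(name, "")] + sorted(genes)))
            fh.write("\n")


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def fisher_enrichment(significant: set, gene_set: set, background: set):
    """One-sided (enrichment) Fisher exact test of set membership.

    The 2x2 table crosses set membership with significance over the
    background; p is the hypergeometric upper tail at the observed overlap.
    The odds ratio uses the Haldane 0.5 correction when any cell is zero.

    Returns ``(odds_ratio, pvalue, overlap)``.
    """
    if not background:
        raise ValueError("background gene set must be non-empty")
    if not gene_set <= background or not significant <= background:
        raise ValueError("gene_set and significant genes must be subsets of the background")
    N = len(background)
    K = len(gene_set)
    n = len(significant)
    a = len(significant & gene_set)
    b = K - a
    c = n - a
    d = N - K - c
    pvalue = float(stats.hypergeom.sf(a - 1, N, K, n))
    if min(a, b, c, d) == 0:
        odds = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        odds = (a * d) / (b * c)
    return float(odds), min(pvalue, 1.0), a


def run_enrichment(
    gene_pvalues: pd.Series,
    gene_sets: GeneSetCollection,
    background: set | None = None,
    gene_q_threshold: float = 0.1,
    set_q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Significant-gene selection then per-set Fisher enrichment with FDR.

    ``gene_pvalues`` maps gene id -> association p-value.  Background
    defaults to all tested genes; a larger background may be supplied.  Gene
    sets are restricted to the background before testing.
    """
    genes = set(gene_pvalues.index)
    if background is None:
        background = genes
    else:
        background = set(background) | genes
    q = bh_qvalues(gene_pvalues.to_numpy())
    significant = set(gene_pvalues.index[q < gene_q_threshold])

    rows = []
    for name, members in gene_sets.sets.items():
        members_bg = members & background
        if not members_bg:
            continue
        odds, p, overlap = fisher_enrichment(significant, members_bg, background)
        rows.append(
            {
                "set": name,
                "description": gene_sets.descriptions.get(name, ""),
                "overlap": overlap,
                "set_size": len(members_bg),
                "n_significant": len(significant),
                "background_size": len(background),
                "odds_ratio": odds,
                "p": p,
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = bh_qvalues(table["p"].to_numpy())
        table["significant"] = table["q"] < set_q_threshold
        table = table.sort_values("p", kind="stable").reset_index(drop=True)
    return table
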