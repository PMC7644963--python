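"""Simulate the study inputs: a histology cohort, bulk expression, a gene
network whose signal genes form a connected module, and a two-tissue cohort
sharing one phenotype.  Writes plain-text artifacts under results/sim/.

Run:  python analysis/01_simulate.py [--seed 1]
"""

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from histomics.synthetic import (  # noqa: E402
    generate_expression,
    generate_histology_cohort,
    generate_multitissue,
    generate_network,
    write_cohort,
    write_expression,
    write_network,
)

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--out-dir", default="results/sim")
args = ap.parse_args()
out = Path(args.out_dir)

cohort = generate_histology_cohort(
    n=80, prevalence=0.4, texture_shift=2.0, seed=args.seed)
write_cohort(cohort, out / "cohort")
print(f"cohort: {len(cohort.images)} images, "
      f"{int(cohort.phenotype.sum())} cases / {int((1 - cohort.phenotype).sum())} controls")

expr = generate_expression(
    n_genes=1500, n_samples=80, n_de=50, lfc=1.5,
    n_factors=2, phenotype=cohort.phenotype, seed=args.seed)
write_expression(expr, out / "expression")
print(f"expression: {expr.counts.shape[0]} genes x {expr.counts.shape[1]} samples, "
      f"{len(expr.de_genes)} planted DE genes")

net = generate_network(1500, expr.de_genes, p_in=0.25, p_out=0.01, seed=args.seed)
write_network(net, out / "network_edges.tsv")
print(f"network: {len(net.edges)} edges; module of {len(net.module_genes)} genes connected")

y = cohort.phenotype
tissues = generate_multitissue(2, [0.4, 0.0], y, n_genes=1500, n_de=1500,
                               lfc=1.5, seed=args.seed)
for i, t in enumerate(tissues):
    write_expression(t, out / f"tissue_{i}")
print("multitissue: tissue_0 carries the phenotype signal, tissue_1 is a global null")
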