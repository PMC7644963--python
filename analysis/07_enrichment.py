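"""Gene-set enrichment of phenotype-associated genes: BH q<0.1 significant
genes, Fisher-exact over-representation per gene set, FDR across sets.
Gene sets are simulated: one concentrated in the planted module, decoys
random.

Run after 06_crosstissue_pi1.py:  python analysis/07_enrichment.py
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from histomics.enrichment import GeneSetCollection, run_enrichment, write_gmt  # noqa: E402
from histomics.expression import tmm_normalize  # noqa: E402
from histomics.pi1 import gene_wise_regression  # noqa: E402

SEED = 1
rng = np.random.default_rng(SEED)
counts = pd.read_csv("results/sim/expression/counts.tsv", sep="\t", index_col=0)
pheno = pd.read_csv("results/sim/cohort/phenotype.tsv", sep="\t")
y = pheno["phenotype"].to_numpy()
truth = json.load(open("results/sim/expression/truth.json"))
planted = [counts.index[i] for i in truth["de_genes"]]

_, logcpm = tmm_normalize(counts)
pv, _ = gene_wise_regression(logcpm.to_numpy().T, y, sex=pheno["sex"].to_numpy())
pvals = pd.Series(pv, index=counts.index)

sets = {"planted_module": set(rng.choice(planted, int(0.8 * len(planted)),
                                         replace=False).tolist())}
for k in range(10):
    sets[f"random_set_{k}"] = set(
        rng.choice(counts.index, 40, replace=False).tolist())
coll = GeneSetCollection(sets=sets, descriptions={k: "" for k in sets})
write_gmt(coll, "results/simulated_sets.gmt")

table = run_enrichment(pvals, coll)
table.to_csv("results/enrichment.tsv", sep="\t", index=False)
print(table[["set", "overlap", "set_size", "odds_ratio", "p", "q",
             "significant"]].head(5).to_string(index=False))
n_sig_genes = int(table["n_significant"].iloc[0]) if len(table) else 0
print(f"{n_sig_genes} genes significant at q<0.1; "
      f"{int(table['significant'].sum())} gene set(s) enriched at q<0.1")
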