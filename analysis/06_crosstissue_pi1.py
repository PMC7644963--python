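"""Cross-tissue concordance: per-gene regressions of phenotype and image PCs
1-3 against expression in each simulated tissue, Storey pi1 per tissue per
model, and the QQ plot of the phenotype regression in the signal tissue.

Run after 02_image_features.py:  python analysis/06_crosstissue_pi1.py
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from histomics.expression import tmm_normalize  # noqa: E402
from histomics.pi1 import pi1_profile, qq_plot, qq_plot_data  # noqa: E402
from histomics.prediction import pca_reduce  # noqa: E402

out = Path("results")
feats = pd.read_csv(out / "features_normalized.tsv", sep="\t", index_col=0)
pheno = pd.read_csv("results/sim/cohort/phenotype.tsv", sep="\t").set_index("sample_id")
y = pheno.loc[feats.index, "phenotype"].to_numpy()
sex = pheno.loc[feats.index, "sex"].to_numpy()
pcs = pca_reduce(feats.to_numpy(), 3).scores

tissues = {}
for t in (0, 1):
    counts = pd.read_csv(f"results/sim/tissue_{t}/counts.tsv", sep="\t",
                         index_col=0)[list(feats.index)]
    tissues[f"tissue_{t}"] = tmm_normalize(counts)[1]

table, argmax, pstore = pi1_profile(tissues, y, pcs, sex=sex)
table.to_csv(out / "pi1_profile.tsv", sep="\t", index=False)
print(table.pivot(index="tissue", columns="model", values="pi1").round(3))
print("highest pi1 for the phenotype model:", argmax["phenotype"])

pv = pstore[(argmax["phenotype"], "phenotype")]
pairs, infl = qq_plot_data(pv)
pd.DataFrame(pairs, columns=["expected_mlog10p", "observed_mlog10p"]).to_csv(
    out / "qq_phenotype_signal_tissue.tsv", sep="\t", index=False)
ax = qq_plot(pv)
ax.figure.savefig(out / "qq_phenotype_signal_tissue.png", dpi=120,
                  bbox_inches="tight")
print(f"QQ inflation ratio in the signal tissue: {infl:.2f}")
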