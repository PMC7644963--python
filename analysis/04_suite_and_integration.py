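"""The wider prediction suite (RF/SVM/NB/LD/QD/LR on 10 image PCs or 20
expression PCs) and the integrative path: JIVE on the two blocks, autoencoder
reduction to 20 features, random-forest CV prediction.

Run after 02_image_features.py:  python analysis/04_suite_and_integration.py
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from histomics.expression import tmm_normalize  # noqa: E402
from histomics.jive import (  # noqa: E402
    integrated_rf_predict,
    jive_autoencoder_representation,
    select_ranks,
)
from histomics.prediction import classifier_suite, pca_reduce  # noqa: E402

SEED = 1
out = Path("results")
feats = pd.read_csv(out / "features_normalized.tsv", sep="\t", index_col=0)
pheno = pd.read_csv("results/sim/cohort/phenotype.tsv", sep="\t").set_index("sample_id")
y = pheno.loc[feats.index, "phenotype"].to_numpy()
counts = pd.read_csv("results/sim/expression/counts.tsv", sep="\t", index_col=0)[list(feats.index)]
_, logcpm = tmm_normalize(counts)
Xe = logcpm.to_numpy().T
Xe = (Xe - Xe.mean(0)) / np.maximum(Xe.std(0), 1e-12)

img_suite = classifier_suite(pca_reduce(feats.to_numpy(), 10).scores, y, seed=SEED)
expr_suite = classifier_suite(pca_reduce(Xe, 20).scores, y, seed=SEED)
print("image suite best:", img_suite["best"], "| expression suite best:", expr_suite["best"])

blocks = [feats.to_numpy().T, Xe.T]
r, r_i = select_ranks(blocks, seed=SEED)
print(f"permutation rank selection: joint r={r}, individual r_i={r_i}")
red, decomp = jive_autoencoder_representation(
    blocks, r=max(r, 1), r_i=[max(v, 1) for v in r_i], epochs=400, lr=3e-3, seed=SEED)
cv = integrated_rf_predict(red.scores, y, seed=SEED)
print(f"JIVE + autoencoder(20) + RF cross-validated AUC: {cv.auc:.3f}")

pd.DataFrame(red.scores, index=feats.index,
             columns=[f"ae{j}" for j in range(red.scores.shape[1])]).to_csv(
    out / "integrated_scores.tsv", sep="\t")
with open(out / "suite_and_integration_metrics.json", "w") as fh:
    json.dump({
        "image_suite": {k: round(v, 3) for k, v in img_suite.items() if k != "best"},
        "expression_suite": {k: round(v, 3) for k, v in expr_suite.items() if k != "best"},
        "jive_joint_rank": r, "jive_individual_ranks": r_i,
        "integrated_rf_cv_auc": round(cv.auc, 3),
    }, fh, indent=2)
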