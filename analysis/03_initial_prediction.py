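"""The initial prediction analyses: pathology from 10 image PCs (in-sample
and repeated-CV logistic), from LASSO-selected genes, and from the combined
model; with and without covariates (sex, age, phenotype-associated hidden
factors).  Writes predictions and a metrics table.

Run after 02_image_features.py:  python analysis/03_initial_prediction.py
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from histomics.expression import (  # noqa: E402
    estimate_hidden_factors,
    select_covariate_factors,
    tmm_normalize,
)
from histomics.prediction import (  # noqa: E402
    combined_glm_predict,
    fit_full_logistic,
    lasso_cv_predict,
    pca_reduce,
    repeated_cv_logistic,
)

SEED = 1
N_REPEATS = 10  # study design uses 50; 10 keeps this driver quick

out = Path("results")
feats = pd.read_csv(out / "features_normalized.tsv", sep="\t", index_col=0)
pheno = pd.read_csv("results/sim/cohort/phenotype.tsv", sep="\t").set_index("sample_id")
pheno = pheno.loc[feats.index]
y = pheno["phenotype"].to_numpy()
counts = pd.read_csv("results/sim/expression/counts.tsv", sep="\t", index_col=0)
counts = counts[list(feats.index)]

pcs = pca_reduce(feats.to_numpy(), 10).scores
_, logcpm = tmm_normalize(counts)
X = logcpm.to_numpy().T
X = (X - X.mean(0)) / np.maximum(X.std(0), 1e-12)

hf = estimate_hidden_factors(logcpm, k=10, sex=pheno["sex"].to_numpy())
hf = select_covariate_factors(hf, y)
basic_cov = pheno[["sex", "age"]].to_numpy(dtype=float)
full_cov = np.column_stack([basic_cov, hf.scores[:, hf.selected]])
print(f"hidden factors: {hf.k} estimated, {int(hf.selected.sum())} phenotype-"
      f"associated at q<0.1 (kept as covariates)")

metrics = {}
for tag, cov in (("no_covariates", None), ("with_covariates", full_cov)):
    full = fit_full_logistic(pcs, y, covariates=cov)
    img = repeated_cv_logistic(pcs, y, covariates=cov, n_repeats=N_REPEATS, seed=SEED)
    expr_cv, sel = lasso_cv_predict(X, y, covariates=cov, n_repeats=2, seed=SEED)
    comb = combined_glm_predict(pcs, X, y, covariates=cov, n_repeats=2, seed=SEED)
    metrics[tag] = {
        "image_in_sample_auc": round(full.auc, 3),
        "image_cv_auc": round(img.auc, 3),
        "expression_lasso_cv_auc": round(expr_cv.auc, 3),
        "combined_cv_auc": round(comb.auc, 3),
        "lasso_consensus_genes": int(len(sel.consensus)),
    }
    pd.DataFrame({"sample_id": feats.index, "prob": comb.prob, "label": y}).to_csv(
        out / f"combined_predictions_{tag}.tsv", sep="\t", index=False)

with open(out / "initial_prediction_metrics.json", "w") as fh:
    json.dump(metrics, fh, indent=2)
print(json.dumps(metrics, indent=2))
truth = json.load(open("results/sim/expression/truth.json"))
planted = set(truth["de_genes"])
sel_idx = {int(g[1:]) for g in logcpm.index[list(
    lasso_cv_predict(X, y, n_repeats=1, seed=SEED)[1].consensus)]}
print(f"consensus recovers {len(sel_idx & planted)}/{len(planted)} planted genes")
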