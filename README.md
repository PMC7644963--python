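# histomics

Prediction of **sub-clinical tissue pathology** — histological abnormality in
donors without a clinical diagnosis (fibrosis, steatosis, congestion,
thyroiditis, atherosclerosis) — from whole-slide histology texture, bulk gene
expression, and their combination, together with the statistics used to ask
*which* tissue's expression carries the pathology signal.

The package is aimed at quantitative biologists working with paired
image/expression cohorts.  Because real cohorts of this kind are
controlled-access, every stage ships with a synthetic-data generator that
plants known signal (texture differences inside simulated tissue pieces,
negative-binomial differential genes, connected network modules, tissues of
graded signal strength), so the full pipeline is testable end to end against
ground truth.

## What it computes

**Texture features.** Tissue pieces are segmented by adaptive thresholding of
the channel-mean intensity; per piece, gray-level co-occurrence matrices
(GLCMs) are accumulated at pixel offsets d ∈ {1, 10, 100} in four directions,
and the 13 classical Haralick statistics are evaluated per RGB channel:
13 × 3 channels × 3 scales = **117 features per sample**, averaged over
pieces, then signed-log2-transformed and standardized.

**Prediction.** With phenotype y ∈ {0,1}:

- logistic regression of y on the first 10 feature PCs, both in-sample and
  with repeated stratified cross-validation (default 50 × 5-fold), held-out
  probabilities averaged over repeats, performance as the Mann–Whitney AUC;
- L1-penalized (LASSO) logistic regression over genes, the penalty λ chosen
  per training fold by inner 5-fold CV at minimum deviance, selected genes =
  nonzero coefficients at λ̂; a consensus set collects genes selected in
  ≥ 50 % of folds;
- a combined generalized linear model on [10 image PCs + fold-selected
  genes (+ covariates)];
- a six-classifier suite (RF, SVM, NB, LDA, QDA, LR) on 10 image PCs or 20
  expression PCs.

**Integration.** JIVE decomposes the feature and expression blocks as
X_i = J_i + A_i + R_i with a shared joint row-space, block-specific
individual parts orthogonal to it, and residuals; the denoised concatenation
is compressed to 20 features by an autoencoder (p → 64 → 20 → 64 → p, ReLU,
Adam) and classified by a random forest.

**Network embedding.** Genes passing a univariate p < 0.05 screen feed a
feedforward net whose first p → p layer is elementwise-masked by a gene-gene
adjacency matrix (unit diagonal), then dense 64/16/2 with softmax output —
only network-adjacent connections are learnable, and masked weights are
exactly zero after every Adam step.

**Cross-tissue concordance.** Per tissue, four regressions per gene (binary
phenotype — logistic; image PCs 1–3 — least squares; sex as covariate) give
p-value collections summarized by Storey's π₁ = 1 − π₀ with
π̂₀(λ) = #{p > λ}/(m(1−λ)) and a cubic smoother at max λ — a sample-size-
insensitive measure of how much of the transcriptome tracks the phenotype.

**Enrichment.** Significant genes at BH q < 0.1; per gene set (GMT), a
one-sided Fisher exact (hypergeometric) test against the tested-gene
background, BH-adjusted across sets.

## Worked example

The numbered drivers under `analysis/` run the whole study on simulated data
(≈2 min total):

```bash
python analysis/01_simulate.py --seed 1
python analysis/02_image_features.py
python analysis/03_initial_prediction.py
python analysis/04_suite_and_integration.py
python analysis/05_network_embedding.py
python analysis/06_crosstissue_pi1.py
python analysis/07_enrichment.py
```

With seed 1 (80 samples, texture shift 2.0, 50 planted genes at |log2FC| 1.5)
this prints, among other things:

```
cohort: 80 images, 32 cases / 48 controls
extracted 117 features for 80 samples (transform: log2+standardized)
"image_cv_auc": 1.0, "expression_lasso_cv_auc": 1.0, "combined_cv_auc": 1.0
consensus recovers 27/50 planted genes
JIVE + autoencoder(20) + RF cross-validated AUC: 0.985
full_data_screen: cv AUC 1.000 (masked first-layer weights all exactly 0: True)
model       PC1    PC2    PC3  phenotype
tissue_0  0.315  0.000  0.055      0.439
tissue_1  0.000  0.157  0.000      0.000
highest pi1 for the phenotype model: tissue_0
planted_module  overlap 37/40  p 1.4e-60  significant True
```

Reading: at this signal strength every predictor saturates (AUC 1.0); the
LASSO consensus is conservative (27 of 50 planted genes appear in ≥ 50 % of
folds — correlated NB genes substitute for each other); π₁ ranks the tissue
that actually carries the signal first (0.44 vs 0.00 for the null tissue,
with PC1 of the image features tracking it at 0.32); and the gene set built
from the planted module is the only one enriched.

## Layout

- `src/histomics/` — the library: `synthetic`, `image_features`,
  `expression`, `prediction`, `jive`, `gedfn`, `pi1`, `enrichment`
- `analysis/` — numbered narrative drivers (above)
- `tests/` — pytest suite including end-to-end checks
- `docs/methods.md` — model assumptions, parameter choices, limitations
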