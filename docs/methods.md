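# Methods

This note records the models implemented, the parameter choices that matter,
what the synthetic data does and does not emulate, and the numerical
decisions a maintainer would want to know.

## Synthetic data: the study conditions

The generators define the conditions under which the pipeline is validated.

**Images.** Each sample is a near-white background (intensity U(0.95, 1)) with
2–5 tissue pieces: ellipses with low-frequency boundary perturbation, hue
jittered around an eosin-like pink (0.82, 0.52, 0.62), default canvas
512×512.  Within-piece texture is a Gaussian white-noise field smoothed by an
isotropic Gaussian kernel and scaled to amplitude 0.35; controls use
correlation length σ = 1 px, cases σ = 1 + `texture_shift`.  GLCM contrast
and correlation respond monotonically to correlation length, so
`texture_shift` is the single dial for class separation, and
`texture_shift = 0` makes the classes exactly exchangeable.  Case count is
`round(n·prevalence)`; sex ~ Bernoulli(0.5), age ~ U(20, 70), independent of
the phenotype by default.  What is *not* emulated: stain variation between
scanners, pyramidal slide formats, nuclei/gland morphology — so passing tests
show the texture statistics and everything downstream of them work, not that
segmentation would survive scanner artifacts.

**Expression.** Counts are gamma–Poisson (negative binomial): gene abundance
log2-mean ~ N(4, 1.5²), dispersion φ = 0.05 + 2/μ (the usual decreasing
trend), library sizes log-normal(0, 0.3).  Differential genes multiply their
mean by 2^(±lfc) in cases (random sign per gene); latent confounders add a
rank-k low-rank term to the log-means.  Not emulated: GC/length bias,
isoform structure, batch-by-design confounding.

**Network.** Planted-partition graph: within-module edge probability `p_in`,
all other pairs `p_out`; module connectivity is guaranteed by adding a random
spanning tree across its components.

**Multi-tissue.** Tissue t carries `round(signal_strengths[t] · n_de)` truly
associated genes, nested within a master DE set so tissue signals overlap the
way shared biology would.  Note that `n_de` is the *candidate pool*; to plant
"fraction f of the genome non-null" set `n_de = n_genes` and strength f.

## Texture features

Segmentation thresholds the channel-mean intensity against its local mean
(window 101 px, offset 0.02, both configurable); 8-connected components are
labeled in decreasing area order, and pieces below 0.1 % of the image area
are dropped.  These three values are explicit choices: the upstream
literature names adaptive thresholding but no parameters.

GLCMs use 32 equal-width gray levels over the masked intensity range per
channel (common texture-analysis practice; keeps the d = 100 matrix
populated), accumulate pairs whose two pixels both lie in the piece mask at
offsets d ∈ {1, 10, 100} along 0°/45°/90°/135°, symmetrize, and normalize.
Pairs crossing the mask are skipped, not padded.  Direction averaging makes
the features invariant to 90° rotations by construction.  A piece too small
to contain any pair at a given distance yields an "empty" GLCM whose 13
statistics are NaN sentinels excluded from the across-piece average (equal
piece weights; an area-weighted option exists).  If *no* piece has a valid
pair at some channel/distance, those entries are set to 0 and logged — the
feature count is always 117.

Haralick statistics use log base 2 with 0·log 0 := 0; the correlation of a
single-level (degenerate) distribution is defined as 1.  Across samples,
features are transformed by sign(x)·log2(1+|x|) — correlation-type features
can be ≤ 0, so a raw log2 would be undefined — then standardized per column;
constant columns become 0 and are logged.

## Expression preparation

TMM follows the trimmed-mean-of-M-values recipe: reference = sample whose
count-fraction upper quartile is closest to the mean upper quartile; genes
positive in both libraries contribute M (log ratio) and A (log abundance);
trims of 30 % on M and 5 % on A; weights are inverse delta-method variances;
factors are rescaled to geometric mean 1.  The implementation agrees with
edgeR's `calcNormFactors` to ~1e-7 on random matrices (asserted in the test
suite via Rscript).  log-CPM = log2((count+0.5)/(lib·factor+1)·1e6).
Gene filtering keeps genes with log-CPM ≥ 0 in ≥ 20 % of samples by default;
both thresholds are parameters.

Hidden confounders are estimated by a deliberately simple surrogate for the
variational factor-analysis machinery used in large consortia: sex is
regressed out per gene, genes are standardized, and the leading k
right-singular directions score each sample.  Signs are fixed by making each
factor's largest-|loading| gene positive, so runs are bit-identical.  Factors
associated with the phenotype (per-factor logistic regression,
likelihood-ratio p, BH q < 0.1) are flagged as covariates.  The surrogate
recovers planted factors at |r| > 0.99 when factor variance dominates noise;
it does not model count noise explicitly the way the full method does.

## Prediction

Cross-validation is stratified (per-fold case counts differ by ≤ 1) with a
seeded RNG per repeat; held-out probabilities are averaged over repeats and
a single AUC is computed on the averaged probabilities (the "average the
predictions, then evaluate" reading).  The AUC is the Mann–Whitney statistic
with ties counted 1/2; it equals brute-force pair counting exactly.

The L1-penalized logistic path is solved by proximal gradient (FISTA) with
strong-rule screening and KKT working-set checks, warm-started along a
100-point log-spaced path from the smallest all-zero penalty down by 1e-4,
intercept and covariates unpenalized, path truncated once more than
min(n, 200) genes are active.  Solutions match liblinear's optimum to ~1e-6
in objective at matched penalties.  Gene selection happens *inside each
training fold* (inner 5-fold CV picks λ at minimum held-out deviance); the
alternative — selecting once on all data — leaks test information and is not
offered for the combined model.  Folds that select zero genes fall back to
an intercept(+covariate) model and are logged.

Suite hyperparameters (the original study used GUI defaults): RF 500 trees
with √k features per split; SVM RBF with C = 1, γ = 1/k, scored by decision
values; Gaussian NB; LDA; QDA with covariance shrinkage 1e-3; unpenalized
LR.  All configurable.

## JIVE + autoencoder

Blocks are scaled by their Frobenius norms, then alternately fitted: joint =
rank-r SVD of the stacked (X_i − A_i); individual = rank-r_i SVD of
(X_i − J_i) projected orthogonal to the joint row-space; stop when the total
fit changes by < 1e-6 relatively (max 500 iterations; non-convergence returns
the best iterate, flagged).  The additive identity, rank bounds, and
joint/individual orthogonality are asserted after every run.  Rank selection
is a sequential permutation test: for the joint rank the null permutes each
block's sample order independently (destroying cross-block alignment while
keeping within-block spectra); for individual ranks the null permutes entries
within rows (structure-free).  Defaults r = 2, r_i = 2 when selection is off.

The autoencoder consumes the concatenated *denoised* blocks (J_i + A_i)ᵀ,
standardized — at default ranks the sample-score representation would have
fewer dimensions than the 20-unit bottleneck, so the feature-space
concatenation is the reading that uses both stated components.  Architecture
p → 64 → 20 → 64 → p, ReLU on the two hidden layers, linear bottleneck and
output, MSE loss, Adam (lr 1e-3, batch 32), He initialization from a seeded
RNG; a NaN loss triggers one restart at half the learning rate.  "Twenty
features" are the bottleneck activations; no ordering is imposed.  A
`skip_jive` flag feeds raw concatenated blocks instead, for comparison.

## Graph-embedded network

The univariate screen keeps genes with per-gene logistic Wald p < 0.05.  The
adjacency over kept genes is symmetric binary with unit diagonal
(self-connections let every gene pass its own signal).  The first p → p layer
is masked elementwise by the adjacency at initialization and after every Adam
update, so masked weights are exactly zero at all times — asserted, not
approximated.  Then dense 64 and 16 ReLU layers and a 2-unit softmax
(retained instead of a single sigmoid to match the stated output width);
cross-entropy loss; lr 1e-3, 100 epochs, batch 32, no weight decay, no early
stopping (reproducibility).  Training-fold standardization is applied to the
held-out fold with training statistics.

The screen-before-CV workflow leaks selection information: under a pure null
(n = 60, 500 genes) it yields CV AUC ≈ 0.87, because genes chosen for
full-data association remain associated in every fold.  Both modes are
implemented (`gedfn_pipeline(filter_in_fold=...)`); calibration claims are
made for the in-fold variant, and results always record which mode produced
them.

## π₁ concordance

For a binary response the per-gene model is logistic (response ~ gene + sex,
Wald p for the gene term), vectorized as a Newton solver batched across
genes; under separation the Wald statistic degenerates, so flagged genes fall
back to a ridge-stabilized (1e-4) likelihood-ratio test.  Constant genes get
p = 1, flagged.  Continuous responses (image PCs) use closed-form partial
t-tests.  Batched p-values match per-gene statsmodels fits to ~1e-4 relative.

π̂₀(λ) is evaluated on λ = 0.05…0.95 (step 0.05); the smoother is a cubic
polynomial least-squares fit to the curve read off at λ = 0.95 (a low-df
stand-in for the smoothing-spline formulation), clipped to [0, 1]; a fixed-λ
variant exposes the raw counting formula.  Estimator behavior worth knowing:
any π₀ estimator is blind to alternative density sitting at p ≈ 1, so an
alternative like Beta(0.1, 1) (density 0.1 at 1) leaves an irreducible
≈ −0.1·π₁ bias; with alternatives that vanish near 1 (e.g. normal mean-shift
tests) the estimator is essentially unbiased.  With m genes the estimate has
sampling sd ≈ √(0.05·0.95/m)/0.05, i.e. ±0.15 at m = 800 — π₁ comparisons
across tissues need thousands of genes to be stable, which is why the
profile analyses use m ≥ 3000.  Tissues with different gene universes are
intersected (logged).  The binary-phenotype model is logistic, not linear;
per-PC p-values are reported separately (an omnibus over PCs 1–3 can be added
downstream from the returned per-model p-values).

The QQ utility returns observed vs expected −log10 quantiles (expected
i/(m+1)) and the genomic-control-style inflation ratio: median observed
χ²(1) quantile over its null median 0.4549.

## Enrichment

BH q-values are the step-up procedure with a cumulative minimum from the
largest p.  Fisher enrichment is the one-sided hypergeometric upper tail at
the observed overlap (equal to the exhaustive tail sum to 1e-12, asserted);
odds ratios use the Haldane 0.5 correction when a cell is zero.  The default
background is the set of tested genes — the database-wide backgrounds of
commercial annotation tools cannot be shipped — and can be overridden.

## Validation design and problem sizes

The end-to-end suite checks: feature dimensionality (117), oracle agreement
of the hand-implemented statistics (Haralick to 1e-10, AUC exactly, Fisher to
1e-12, TMM vs edgeR), null calibration of all six pipelines at
texture_shift = 0 / lfc = 0 (mean CV AUC over 3 seeds inside the 95%
Mann–Whitney permutation band around 0.5), signal recovery at
texture_shift = 2 / lfc = 1.5 (n = 300: image-PC, LASSO, and combined AUC
≥ 0.85; consensus recall ≥ 60 %), JIVE exactness on noiseless planted blocks,
mask integrity and module-signal AUC ≥ 0.8 for the embedded net, π₁ recovery
within ±0.05 across mixture fractions at m = 10,000, planted-tissue ranking
in 20 replicates, and the enrichment statistics.  Monte-Carlo sizes (seeds
per check, repeats per CV, genes per matrix) are chosen so the suite runs in
minutes on a single CPU while keeping each check's sampling error well below
its assertion margin; the repeated-CV default of 50 repeats is the study
design, and tests use fewer repeats because AUC of averaged probabilities
stabilizes after a handful.

## Known limitations

- Segmentation assumes dark tissue on a light background; it is not robust
  to inverted stains or heavy artifacts.
- The hidden-factor surrogate captures broad variance components only; it is
  not the full variational model and is labeled as a surrogate in outputs.
- The d = 100 GLCM scale is uninformative for pieces smaller than ~100 px;
  those entries fall back to the across-piece average or 0.
- π₁ estimates on few genes (< ~1000) are noisy, and correlated tests widen
  the spread further; treat small-m profiles qualitatively.
- The permutation rank selection for JIVE is conservative when joint signal
  is weak relative to block-specific structure; the pipeline floors ranks at
  1 when using selected ranks for the integrative path.
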