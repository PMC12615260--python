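# Methods

This note records the modeling assumptions, parameter choices and
numerical conventions behind `potencynet`, and what the synthetic-data
experiments do and do not demonstrate.

## Model and assumptions

The model assumes that each of the six broad potency categories
(differentiated < unipotent < oligopotent < multipotent < pluripotent <
totipotent) is characterized by multivariate gene-expression programs
that are conserved across datasets and platforms, and that those
programs can be captured by *discrete* gene sets rather than dense
weight vectors. Constraining the gene-selection layer to binary weights
is both a regularizer and the source of interpretability: every hidden
unit is a gene set that can be read off the trained model.

Two deliberately different encodings of expression feed the model.
The within-cell rank matrix R is invariant to any monotone per-cell
transformation, which suppresses library-size, platform and batch
effects; the log2(1 + CPM/TPM) matrix L retains quantitative contrasts
the ranks discard. Each gene set is scored in both spaces (rank-based
Score_U, background-subtracted Score_A), and the competition between the
two scores regularizes what the enrichment layer can exploit.

The continuous potency score is the expectation of the ordered anchors
t = [0, 0.2, 0.4, 0.6, 0.8, 1.0] under the predicted category
likelihoods. It therefore carries the model's uncertainty: a cell
predicted halfway between two categories lands between their anchors.

## Preprocessing conventions

- **Gene dictionary.** Human symbols are paired with their closest mouse
  ortholog by sequence similarity; when several human genes best-hit one
  mouse gene, only the most similar human gene is kept (ties broken
  alphabetically); human genes without an ortholog become singleton
  features. Features are named by the mouse symbol of a pair and listed
  sorted. Tests and the synthetic workflow use generated fixture
  dictionaries; a full-genome dictionary is a drop-in table.
- **Ranks.** Ordinal within-cell ranks, rank 1 = highest expression,
  ties broken by ascending feature index. All-zero genes therefore
  occupy the trailing rank block in index order, and every column of R
  is an exact permutation of 1..N. Combined with harmonization (which
  reorders genes into feature order first), the pipeline is invariant to
  the gene order of the input file.
- **Log transform.** log2(x + 1) after scaling each cell to 10⁶ total.
  The pseudocount 1 keeps zeros at zero. CPM and TPM are both treated as
  "scale the column to 10⁶"; gene-length correction is the caller's
  responsibility.
- Duplicate input gene symbols are collapsed by summation before
  mapping, preserving total signal.

## Background map

Score_A compares each gene set against expression-matched background
genes. Genes are ranked by reference mean log-expression (the training
corpus by default) and split into `n_bins` = 24 rank bins; each gene
draws its background from its own bin, self excluded, with a count
sampled once from a Gaussian with mean `n_sample` and variance
`n_sample(s_bin − n_sample)/s_bin`, rounded and clamped to
[1, s_bin − 1]. The map is sampled once per model (seeded) and fixed
thereafter, so inference never depends on the composition of the query
dataset. The builder rejects configurations with `s_bin ≤ n_sample`
(non-positive variance); on small feature spaces `n_sample` must shrink
accordingly (the 500-gene standard workflow uses `n_sample` = 10 against
a bin size of ~20).

A subtlety worth recording: with the background matrix B defined so that
row i lists the background genes *of* gene i, the matrix that maps the
genes of a gene set to their backgrounds is Bᵀ, not B. `ams_score`
therefore computes L·(Bᵀ W^B) with background genes counted with
multiplicity when shared between set members — the behavior module-score
implementations in the field exhibit.

## Training

- **Loss.** J = J_S + Σ_w v_w·CE_w. The gene-set-size penalty uses the
  identity that the diagonal of (W^B)ᵀW^B/N holds the relative set sizes
  S_j/N, so J_S = a·λ·Σ_p ‖S_p/N‖₂ with a = √(12/M) making the term
  invariant to the number of gene sets at equal sizes. Defaults:
  M = 24 gene sets per category, dropout ρ = 0.5 on the normalized
  scores (train only), λ = 0.01, lr = 0.001, batch size 1,024, 100
  epochs with the best validation checkpoint after epoch 15 returned.
- **Hierarchical weights.** v assigns equal total mass to every broad
  category, to every phenotype within its category, and to every dataset
  within its phenotype; the batch sampler draws cells with replacement
  proportionally to v. Within a mini-batch the sampled cells' weights
  are renormalized to unit sum so the gradient scale is independent of
  batch composition.
- **Binary backprop.** The forward pass binarizes W at 0 (strict
  inequality; exactly 0 maps to 0); the backward pass is a
  straight-through estimator masked by the hardtanh window |W| ≤ 1.
  τ is reparameterized through τ_m (uniform [0, 1] init) and rounded
  with an identity-gradient straight-through; the rank-trimming
  min(R, τ) passes gradient to τ where τ is the minimum. Gene sets that
  empty out during training produce constant scores (guarded
  denominators) and receive no further gradient; they can only be
  revived by the optimizer's momentum.
- **Optimizer.** NAdam (betas 0.9/0.999, eps 1e-8, momentum decay
  0.004) with state persisting across epochs — the momentum inertia
  damps binary bit flipping. The whole training graph runs on the
  package's reverse-mode autodiff engine (`potencynet.autodiff`), whose
  operations are gradient-checked against central finite differences in
  the test suite.
- **Normalization.** Batch-norm-style score standardization without
  affine parameters: batch moments during training (running statistics
  updated with momentum 0.1, unbiased variance), stored statistics at
  inference, eps 1e-5.
- **Early stopping metric.** F1 is computed per (phenotype, dataset)
  group against the group's true category, then averaged across
  datasets per phenotype, phenotypes per category, and categories.
  Within a pure group this reduces to 2r/(1 + r) in the group recall r.
- **Ensembling** averages member likelihood matrices entrywise and
  rederives ŷ and RPS from the mean.

## Postprocessing

- **Diffusion.** Pearson correlation between cells over the top 1,000
  genes by dispersion (variance/mean of L; zero-mean genes score 0),
  negatives clipped to zero, rows normalized (the self-correlation of 1
  guarantees positive row sums). The Jacobi iteration
  s ← α·P_M·s + (1 − α)·RPS with α = 0.9 converges to
  (1 − α)(I − αP_M)⁻¹RPS, a row-stochastic image of RPS, hence bounded
  by [min RPS, max RPS]. Tolerance 1e-5 (L∞), cap 10,000 iterations;
  cells with undefined correlation (constant expression) fall back to
  identity rows with a warning. Block-subsampled diffusion for corpora
  beyond ~10,000 cells is out of scope at desk scale.
- **Binning.** Within predicted category p, ascending rank r of r_max by
  smoothed score (ties by cell index), placed at
  (p − 1)/6 + (r/(r_max + 1))/6. The r/(r_max + 1) convention keeps all
  scores strictly interior to the category's interval, so
  `score_to_category` (left-closed, right-open intervals; 1.0 →
  totipotent) recovers ŷ exactly.
- **Adaptive k-NN.** Applied only above 100 cells. Cells are
  standardized per cell, projected to 30 PCs (deterministic sign:
  largest-magnitude loading positive), and each center's 30 nearest
  neighbors form the candidate set with distances rescaled to unit
  maximum (the 30th neighbor thus gets weight zero). The neighborhood
  grows while the mean scores of {w, c₁..c_m} and {c_{m+1}..c_{2m+1}}
  map to different categories, stopping at k = 2m + 1 on agreement, with
  k = 3 as fallback once the group size reaches 15. Group means are
  unweighted; the final score is the (1 − d)²-weighted mean including
  the center at d = 0. The procedure is fully deterministic.

## Synthetic data

The generator emulates the *structure* the model relies on — six ordered
categories, phenotypes nested in categories, datasets nested in
phenotypes, disjoint per-category marker programs, library-size
variation, overdispersed counts and dropout sparsity — using a
negative-binomial model: a shared lognormal baseline expression profile,
category markers up-shifted by a fold change, mild phenotype-specific
and no explicit batch effects beyond sampling noise, lognormal library
sizes, Gamma–Poisson counts (var = μ + 0.5μ²) and Bernoulli dropout.

Standard workflow conditions (chosen once): 500 genes, 2 phenotypes per
category, 2 datasets per phenotype, 50 cells per phenotype–dataset
(1,200 cells), 20 markers per category at 5× fold change, library size
2,000 (lognormal σ = 0.3), dropout 0.2. Dataset `ds1` trains, `ds2` is
the held-out validation set — the one-held-out-dataset contract.
Training uses the default hyperparameters except batch size 128 and
background `n_sample` = 10, both consequences of the 500-gene scale.

What passing on this fixture shows: the training machinery can recover
planted discriminative programs (held-out weighted accuracy ≈ 0.99;
≳ 85% of each category's planted markers in the top 5% of its
feature-importance column, hypergeometric p ≪ 1e-6) and the full
pipeline respects its invariants. What it does not show: performance on
real tissue atlases, robustness to cross-platform technical variation,
or the biological validity of learned programs — the synthetic markers
are cleanly disjoint and unrealistically strong by design, and no
attempt is made to mimic any real dataset.

Label-noise perturbations use a Gaussian rank-distance transition
matrix, P(i|j) ∝ exp(−(j − i)²/2σ²), rows normalized; σ is calibrated by
root-finding so the expected changed-label fraction under a uniform
label distribution (the assumed π) matches a target titration level
(5–80%; the uniform-kernel ceiling is 5/6). Gene-count downsampling
keeps each cell's top-g genes with seeded random tie resolution; UMI
downsampling is a per-cell multinomial draw, cells at or below the
target left unaltered; rarity titration subsamples one phenotype
uniformly without replacement.

## Numerical conventions and degenerate inputs

- Softmax with max subtraction; cross-entropy in log-sum-exp form.
- Empty gene sets: the standalone `ucell_score`/`ams_score` raise by
  contract; the forward pass and training graph guard denominators
  (S ← max(S, 1)) and warn, so a trained model with a dead set still
  predicts.
- Constant score columns are protected by the batch-norm eps; constant
  expression falls back to identity diffusion; datasets of ≤ 100 cells
  (or fewer than 4 non-self neighbors) skip k-NN smoothing with
  pass-through scores.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); training, simulation and background
  sampling are bitwise reproducible, and inference is seed-free
  deterministic.

## Problem sizes

The test suite and the acceptance script run the standard workflow at
500 genes × 1,200 cells with a single trained model (~20 s on one CPU);
the full-scale feature space (14,271 genes) appears only in the
initialization statistics, where no forward pass is needed. These sizes
are the package's reference desk-scale conditions; all operations accept
larger inputs unchanged.

## Known limitations

- Training cost grows with N × M per module; the dense N × N-shaped
  background map is stored sparse (~`n_sample` entries per row) but the
  cell–cell similarity matrix in diffusion is dense, so corpora beyond
  ~20k cells need the (out-of-scope) block-sampled variant.
- The straight-through estimator is a biased surrogate: the true
  gradient of the binarized forward pass with respect to W is zero
  almost everywhere, so convergence claims are empirical, not
  variational.
- The hierarchical weighted-accuracy metric rewards within-group
  consistency (it reduces to a recall transform in pure groups); it is
  intentionally different from the benchmark-style mean multiclass F1
  in `potencynet.evaluate`.
- Granular (24-level) labels are carried through for evaluation only;
  the training loss uses broad categories.
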