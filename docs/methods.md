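# Methods

## Model

For samples x₁…xₙ ∈ ℝᴹ with subtype labels yᵢ ∈ {1…K}, the classifier is
a multinomial logistic model on the *overlap-expanded* design: every gene
appears once per class, and class t's copy of the design has its columns
ordered so that class t's gene groups are contiguous blocks. With
expanded samples x̄ᵢ ∈ ℝ^{KM}, coefficients β ∈ ℝ^{K×KM} and intercepts
β₀ ∈ ℝᴷ, the fitted objective is the mean multinomial negative
log-likelihood plus a two-level penalty

    P(β) = (1−α) λ Σₖ Σₗ √mₗ ‖βₗ^{(k)}‖₂ + α λ Σₖ Σⱼ wⱼ |βⱼ^{(k)}|,

where l runs over the V groups of the expansion (mₗ columns each) and w
are per-column adaptive weights. Penalty blocks are per (class k, group
l), exactly as the double sum is written; a `cross_class=True` flag
instead groups the K class rows of a block jointly (the convention of
some multinomial group-Lasso software). The weighted ℓ₁ term is the
elementwise-weighted norm: each gene's coefficient carries its weight in
every discriminant function. Intercepts are unpenalised, and the softmax
shift degeneracy is anchored by centring β₀ to mean zero.

Predictions take argmax over the K linear discriminants, ties to the
lowest class index.

## Stages and their assumptions

**Robust PCA** (`rpca`). Principal component pursuit
`min ‖D‖* + λ‖E‖₁ s.t. X = D + E`, solved by the inexact augmented
Lagrange multiplier method: alternating singular-value thresholding for
D and soft-thresholding for E, with penalty μ initialised at 1.25/‖X‖₂
and grown by 1.6 per iteration; feasibility tolerance 1e-7, at most 1000
iterations (exhaustion flags `converged=False`, never raises). Default
λ = 1/√max(n, M), the standard theoretical choice. The decomposition
assumes the clean signal is low-rank with *incoherent* singular vectors;
group-structured expression signals are partially coherent (factor
loadings live on gene blocks), so at the default λ a few percent of a
clean matrix's energy can legitimately end up in E. The planted-recovery
guarantee (relative error ≤ 1e-3) therefore holds in the incoherent
regime (rank ≲ 0.1·min dims, ≤ 5% corruption), which is where the method
is designed to operate. Missing values are an error; callers may impute
per-gene means beforehand.

**Affinity propagation** (`ap_cluster`). Exact responsibility and
availability updates with damping 0.9, at most 1000 iterations, and
convergence declared when the exemplar set is unchanged for 100
consecutive iterations — the canonical defaults. No jitter is added by
default (determinism); a seeded `jitter` option exists. An empty
exemplar set at termination falls back to the single point with the
largest self-evidence and flags non-convergence. Ties in the assignment
argmax break to the lowest index.

**Per-class grouping** (`grouping`). For each class, gene profiles are
z-scored across that class's samples and clustered by affinity
propagation on negative squared Euclidean distances with the median
preference. For z-scored vectors this distance is a monotone affine
function of the Pearson correlation, so this single computation honours
both the correlation view and the distance view of gene similarity.
Genes constant within a class z-score to the zero profile rather than
NaN. Exactly identical z-scored profiles are merged before clustering
and re-expanded afterwards: identical points make the message-passing
equations symmetric and degenerate (both twins claim exemplarhood), and
identical profiles must co-cluster by definition anyway.

**Adaptive weights.** Reliability s_j = 1/(‖Ē_j‖₁ + ε) with ε = 1e-6 and
weight w_j = 1/s_j per expanded noise column. `build_weight_matrix`
leaves the weights on their natural scale by default; the *pipeline*
rescales them to mean 1 (`normalize_weights=True`). Rationale: the
absolute scale of w multiplies the ℓ₁ term of the penalty, so without
normalisation the effective ℓ₁/group balance depends on the absolute
noise magnitude and the cross-validated α grid loses its meaning (with
5% gross noise the mean weight is ≈15, making α = 0.1 behave like
α ≈ 0.7). Normalising preserves the *relative* penalisation of noisy
versus clean genes — the point of the adaptive weights — while keeping
α interpretable.

**Solver** (`msgl_solver`). Three nested loops:

* *Outer*: for each class in turn, a quadratic approximation of the
  likelihood at the current point — working responses
  z = score + (y − p)/h with curvature h = p(1−p), floored at 1e-5 for
  stability (the glmnet convention).
* *Middle*: block coordinate descent over that class's group blocks on
  the penalised weighted least-squares subproblem. One matrix-vector
  product per sweep screens all currently-zero blocks at once via the
  block optimality certificate ‖soft(∇ₗ, αλw)‖₂ ≤ (1−α)λ√mₗ (with a
  1e-10 relative slack so blocks exactly on the boundary — e.g. at
  λ_max — stay zero under rounding). At most 3 sweeps per
  approximation; the outer loop re-approximates anyway.
* *Inner*: proximal-gradient steps within an active block — elementwise
  soft-threshold then group-norm shrinkage — accelerated by FISTA with
  adaptive restart, step size 1/(max(h)·σ²(X_block)/n) from the
  subproblem curvature bound; at most 15 iterations per visit.

Each class update is safeguarded by halving the step toward the
subproblem solution until the true objective (likelihood + penalty) does
not increase, so the objective is monotone across outer iterations.
Termination is by certificate: the largest violation of the block
subgradient conditions (KKT residual) must fall below 10·tol, with
tol = 1e-5 by default and i_max = 1000 outer iterations. A pure
first-order prox-gradient variant handles the cross-class grouping flag,
whose joint group norm the per-class quadratic cannot represent.

λ_max — the smallest λ at which the all-zero coefficient matrix (with
intercepts at the null maximum likelihood, i.e. log class proportions)
is optimal — is found in closed form at the α endpoints and by bisection
otherwise. Auto paths use 100 log-spaced values from λ_max down to
1e-3·λ_max. Columns are standardised (mean 0, sd 1; constant columns
left unscaled) before fitting and coefficients back-transformed;
objective values along the path are reported on the standardised scale.

**Pipeline** (`pipeline`). RPCA → per-class AP grouping → expansion of D
and E → weights → model selection → refit → evaluate. Model selection is
stratified 5-fold cross-validated accuracy over
α ∈ {0.1, 0.25, 0.5, 0.75, 0.9} × 30 λ values log-spaced to
1e-2·λ_max (the glmnet n < p convention; the grid is anchored at the
full-training-set λ_max so all folds share levels). Fold fits run at
tol 1e-4 — label decisions are insensitive beyond that — and the final
refit at 1e-5. Ties prefer the larger λ (sparser model), then the
smaller α (more group structure). The expansion and weights are computed
once from the full training set; only the regression is
cross-validated. Held-out samples are expanded *raw* — cleaning a single
new sample with a transductive decomposition is ill-posed — with a
`clean_test` option substituting training means for non-finite entries.
Repeated experiments derive run r's seed as master_seed + r; key genes
are those selected (any expanded copy, deduplicated to original IDs) in
at least `key_threshold` of `n_runs` runs (default 9 of 10).

## Synthetic data generator

`generate` plants the structure the pipeline assumes, with full ground
truth:

* Genes are partitioned into 4 groups per class (M = 120, so 30 genes
  each). The 2 informative groups occupy the same genes in every class;
  the remaining genes are partitioned per class by a seeded shuffle.
* Each (class, group) is driven by a dominant latent factor with
  loadings U(0.5, 1) plus a weaker second factor with loadings
  U(0.1, 0.5) across that class's samples. The second factor exists
  because with a single factor every gene in a group z-scores to the
  *same* profile, which both degenerates message passing and makes
  support recovery ill-posed; with it, within-group gene-gene
  correlations land in the 0.7–0.98 range typical of real co-expression
  modules. The clean matrix has rank ≈ 2·K·G ≈ 24.
* Informative groups carry class-dependent mean shifts arranged on a
  regular simplex, so every class pair is equally separated. The default
  `effect_size = 4.0` is derived, not tuned: the group-mean statistic
  has roughly unit factor noise per group dimension, pairwise class
  distance equals the effect size, so the clean-data Bayes error is
  ≈ 2Φ(−effect_size/2); 4.0 places Bayes accuracy near 95%, the regime
  the method targets in its motivating application.
* Gross noise: 5% of entries set to ±7.5 (≈10× the per-gene signal sd)
  at uniformly random positions. X = L + S holds exactly; labels are
  balanced (20 per class); everything is deterministic given the seed.

What the generator does *not* emulate: dense measurement noise, batch
effects, dye bias, count distributions, unbalanced classes, or groups
whose informative genes differ between classes. Passing the recovery
tests therefore demonstrates that the pipeline exploits the structure it
assumes — not that it is robust to real-data violations of that
structure.

## Degenerate inputs and numerical choices

* Zero matrix → RPCA returns (0, 0) immediately.
* A class with < 2 samples cannot be clustered (error); a class absent
  from training or a single-class label file is an error.
* Rounding in the split is half-away-from-zero per class; a class
  rounding to zero training samples or an empty test set is an error.
* Exact score ties predict the lowest class index.
* Non-convergence (RPCA or solver iteration caps) is flagged on the
  result, never raised.
* Solver tolerances: tol 1e-5 (relative coefficient change scale), KKT
  certificate 10·tol, h floor 1e-5, zero-block slack 1e-10 relative.

## Problem sizes

Default study conditions are desk-scale: 60 samples × 120 genes, 3
classes, 4 groups per class. One full pipeline run (RPCA, 3 AP
clusterings, 25-fit cross-validation, refit) takes ~10 s on one CPU; the
20-replicate recovery study a few minutes. The solver itself handles the
3 × 3571-gene expansion arithmetic trivially; fitting at that scale is
supported but not exercised by the test suite.

## Known limitations

* The pipeline's accuracy on raw (noise-carrying) held-out samples is
  bounded by the spike exposure of the selected genes; group-dominant
  penalties (small α) spread weight and are empirically more robust.
* RPCA at the universal λ shaves a few percent of coherent
  (group-localised) clean signal into E; weights are therefore never
  exactly ε even for noise-free genes.
* Affinity propagation is not guaranteed to maximise net similarity in
  general; optimality is verified only on small enumerable instances.
* The cross-class grouping variant uses the slower first-order solver
  path.
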