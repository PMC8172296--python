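# ramrsgl

Robust adaptive multinomial regression with a sparse group Lasso penalty,
for multiclass classification and group-structured gene selection from
gene-expression matrices.

## The problem

Microarray and expression studies of cancer subtypes pose a
small-sample, ultrahigh-dimensional multiclass problem: tens of samples,
thousands of genes, K ≥ 3 subtype labels, only a handful of genes truly
informative. Two features of such data are usually ignored by sparse
regression methods: (i) gross, entrywise-sparse noise contaminates the
measurements, and (ii) genes act in correlated co-expression groups whose
composition can differ between subtypes.

`ramrsgl` addresses both with a five-stage pipeline:

1. **Robust PCA** — split the training matrix into a low-rank clean part
   `D` and a sparse noise part `E` by principal component pursuit
   (`min ‖D‖* + λ‖E‖₁  s.t.  X = D + E`), solved with the inexact
   augmented Lagrange multiplier method.
2. **Per-class affinity propagation** — cluster the genes within each
   class on the clean signal, exchanging responsibility/availability
   messages; the number of groups emerges from the preference on the
   similarity diagonal (default: median of the off-diagonal
   similarities).
3. **Overlap expansion** — duplicate every gene once per class and
   reorder each copy so that class t's groups form contiguous blocks,
   giving an n × KM design with V = Σ_t (clusters of class t) groups.
4. **Noise-adaptive weights** — per expanded column j, reliability
   `s_j = 1/(‖Ē_j‖₁ + ε)` and ℓ₁ weight `w_j = 1/s_j`: noisier genes are
   penalised harder.
5. **Weighted multinomial sparse group Lasso** — fit intercepts β₀ ∈ ℝᴷ
   and coefficients β ∈ ℝ^{K×KM} by minimising

   ```
   −(1/n) Σᵢ [ β₀^{(yᵢ)} + x̄ᵢᵀβ^{(yᵢ)} − log Σₖ exp(β₀^{(k)} + x̄ᵢᵀβ^{(k)}) ]
     + (1−α) λ Σₖ Σₗ √mₗ ‖βₗ^{(k)}‖₂  +  α λ Σₖ Σⱼ wⱼ |βⱼ^{(k)}|
   ```

   over a decreasing λ path by three-level block coordinate descent
   (outer quadratic approximation, middle block sweep with a zero-block
   certificate, inner proximal updates), selecting (α, λ) by stratified
   cross-validated accuracy. Whole groups are switched off by the ℓ₂
   term; individual genes inside surviving groups by the weighted ℓ₁
   term.

Prediction is `argmax_k β₀^{(k)} + x̄ᵀβ^{(k)}` on the expanded sample.
Repeated random-split experiments summarise accuracy and selection
stability; genes selected in at least 9 of 10 runs are reported as key
genes.

Baselines `MRSGL` (unit weights), `MRGL` (α = 0, pure group Lasso) and
`L1` (plain lasso-penalised multinomial regression, no grouping) are
available as configurations of the same pipeline.

## Worked example

The synthetic generator plants the exact structure the method assumes:
a low-rank class signal with genes in correlated groups, two truly
discriminative groups carrying class-dependent mean shifts, and 5% gross
noise at ten times the signal scale.

```python
import ramrsgl as rg

(X, y, gene_ids, sample_ids), truth = rg.generate(seed=7)
ds = rg.ExpressionDataset(X=X, y=y, gene_ids=gene_ids, sample_ids=sample_ids)
train, test = rg.stratified_split(ds, train_fraction=2/3, seed=7)
result = rg.run_ramrsgl(train, test, seed=7)

print(f"chosen alpha:        {result.alpha}")
print(f"chosen lambda:       {result.lam:.4f}")
print(f"CV accuracy:         {result.cv_accuracy:.3f}")
print(f"held-out accuracy:   {result.test_accuracy:.3f}")
print(f"genes selected:      {result.n_selected} / {len(gene_ids)}")
informative = {gene_ids[g] for g in truth.informative_genes}
print(f"informative genes recovered: {len(result.selected_genes & informative)} / {len(informative)}")
```

prints

```
chosen alpha:        0.1
chosen lambda:       0.2760
CV accuracy:         1.000
held-out accuracy:   0.952
genes selected:      60 / 120
informative genes recovered: 60 / 60
```

Cross-validation picks a group-dominant penalty (α = 0.1), the model
classifies 95% of the held-out samples (whose raw, still-noisy values
are expanded with the training column map), and the 60 genes it selects
are exactly the 60 genes of the two planted discriminative groups.

The same pipeline is available from the shell:

```bash
ramrsgl simulate --seed 7 --out data/sim_
ramrsgl run --expr data/sim_expr.tsv --labels data/sim_labels.tsv --seed 7 --out results/
```

which writes `metrics.json` (accuracy and gene-count means ± sd over the
repeated splits), `selected_genes.tsv` (per-gene selection counts and the
key-gene flag) and the final model's sparse coefficients. Individual
stages are exposed as `decompose`, `cluster`, `expand`, `fit` and
`evaluate` subcommands on tab-delimited text files.

## Documentation

`docs/methods.md` describes the model, the solver, the synthetic-data
generator and every numerical choice in detail.
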