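"""End-to-end pipeline: decompose, cluster, expand, weight, fit, evaluate.

One run proceeds as: RPCA splits the training matrix into clean signal D
and sparse noise E; affinity propagation clusters the genes of each class
on D; the per-class clusterings drive the overlap expansion of both D and
E; the expanded noise columns set the adaptive l1 weights; a stratified
cross-validated grid over (alpha, lambda) selects the penalty; the chosen
model is refit on the full training set and scored on held-out samples,
whose raw values are expanded by the same column map.  Repeated random
splits give stability summaries and the key-gene rule (genes selected in
at least a threshold number of runs).

Baseline configurations recover the simpler members of the family: the
unweighted sparse group Lasso (MRSGL), the pure group Lasso (MRGL, alpha
fixed at 0) and plain l1-penalised multinomial regression (L1, singleton
groups on the raw columns, no expansion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ramrsgl.grouping import (
    GroupStructure,
    apply_expansion,
    build_weight_matrix,
    cluster_per_class,
    expand_matrix,
    gene_reliability,
)
from ramrsgl.msgl_solver import Coefficients, fit_path, predict
from ramrsgl.rpca import rpca_decompose

__all__ = [
    "ExpressionDataset",
    "PipelineConfig",
    "PipelineResult",
    "RepeatSummary",
    "stratified_split",
    "run_ramrsgl",
    "repeat_experiment",
    "baseline_config",
]


@dataclass
class ExpressionDataset:
    """Samples x genes expression values with 1-based integer class labels."""

    X: np.ndarray
    y: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != len(self.y):
            raise ValueError("label count does not match sample count")
        if self.X.shape[1] != len(self.gene_ids):
            raise ValueError("gene id count does not match column count")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.y))

    def subset(self, idx: np.ndarray) -> "ExpressionDataset":
        return ExpressionDataset(
            X=self.X[idx],
            y=self.y[idx],
            gene_ids=self.gene_ids,
            sample_ids=[self.sample_ids[i] for i in idx],
        )


@dataclass
class PipelineConfig:
    """Settings for one pipeline run; see :func:`baseline_config` for presets."""

    name: str = "RAMRSGL"
    use_rpca: bool = True
    use_grouping: bool = True
    adaptive_weights: bool = True
    alpha_grid: tuple[float, ...] = (0.1, 0.25, 0.5, 0.75, 0.9)
    n_lambda: int = 30
    lambda_min_ratio: float = 1e-2
    cv_tol: float = 1e-4
    cv_folds: int = 5
    ap_preference: float | str = "median"
    ap_damping: float = 0.9
    eps: float = 1e-6
    normalize_weights: bool = True
    tol: float = 1e-5
    i_max: int = 1000
    standardize: bool = True
    clean_test: bool = False
    rpca_lam: float | None = None


@dataclass
class PipelineResult:
    alpha: float
    lam: float
    coef: Coefficients
    gs: GroupStructure
    selected_genes: set[str]
    selected_groups: set[tuple[int, int]]
    test_accuracy: float
    cv_accuracy: float
    n_selected: int


@dataclass
class RepeatSummary:
    accuracies: np.ndarray
    gene_counts: np.ndarray
    accuracy_mean: float
    accuracy_sd: float
    gene_count_mean: float
    gene_count_sd: float
    selection_counts: dict[str, int]
    key_genes: set[str]
    n_runs: int
    key_threshold: int
    results: list[PipelineResult] = field(repr=False, default_factory=list)


def stratified_split(
    ds: ExpressionDataset, train_fraction: float, seed: int
) -> tuple[ExpressionDataset, ExpressionDataset]:
    """Class-balanced random split, deterministic given ``seed``.

    Per class, ``round(n_class * fraction)`` samples (half rounded away
    from zero) go to training, the rest to test.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for cls in np.unique(ds.y):
        members = np.flatnonzero(ds.y == cls)
        n_train = int(np.floor(len(members) * train_fraction + 0.5))
        if n_train == 0:
            raise ValueError(f"class {cls} would get no training samples")
        perm = rng.permutation(members)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    if not test_idx:
        raise ValueError("split leaves an empty test set")
    return ds.subset(np.sort(train_idx)), ds.subset(np.sort(test_idx))


def _unit_indicators(M: int) -> list[np.ndarray]:
    """Singleton groups on the raw columns (no duplication, no blocks)."""
    return [np.arange(1, M + 1)]


def _cv_select(
    X_bar: np.ndarray,
    Y: np.ndarray,
    y: np.ndarray,
    gs: GroupStructure,
    w: np.ndarray,
    config: PipelineConfig,
    seed: int,
) -> tuple[float, float, float]:
    """Pick (alpha, lambda) by stratified k-fold CV accuracy.

    The lambda grid for each alpha is anchored at the full-training-set
    lambda_max so every fold is evaluated at the same levels.  Ties prefer
    the larger lambda (sparser model), then the smaller alpha.
    """
    from ramrsgl.msgl_solver import compute_lambda_max

    counts = np.bincount(y)[1:]
    n_splits = min(config.cv_folds, int(counts[counts > 0].min()))
    if n_splits < 2:
        raise ValueError("smallest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed % (2**32))

    best = (-1.0, None)  # (accuracy, (lam, alpha))
    for alpha in config.alpha_grid:
        lam_max = compute_lambda_max(
            X_bar, Y, alpha, gs.global_groups, gs.group_sizes, w, standardize=config.standardize
        )
        lambdas = np.geomspace(lam_max, config.lambda_min_ratio * lam_max, config.n_lambda)
        correct = np.zeros(len(lambdas))
        total = 0
        for tr, te in skf.split(X_bar, y):
            path = fit_path(
                X_bar[tr],
                Y[tr],
                gs.global_groups,
                gs.group_sizes,
                w,
                alpha=alpha,
                lambdas=lambdas,
                tol=config.cv_tol,
                i_max=config.i_max,
                standardize=config.standardize,
            )
            total += len(te)
            for i, pt in enumerate(path):
                labels, _ = predict(pt.coef, X_bar[te])
                correct[i] += np.sum(labels == y[te])
        acc = correct / total
        for i, lam in enumerate(lambdas):
            # ties: larger lambda wins within alpha (iterate high->low and use
            # strict >); across alphas, the earlier (smaller) alpha wins
            if acc[i] > best[0] + 1e-12:
                best = (acc[i], (float(lam), float(alpha)))
    assert best[1] is not None
    lam, alpha = best[1]
    return alpha, lam, float(best[0])


def run_ramrsgl(
    train: ExpressionDataset,
    test: ExpressionDataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """One full train/evaluate cycle; see the module docstring for the stages."""
    config = config or PipelineConfig()
    if train.gene_ids != test.gene_ids:
        raise ValueError("train and test must share gene ids")
    if not set(np.unique(test.y)) <= set(np.unique(train.y)):
        raise ValueError("test contains a class absent from training")
    K = train.n_classes
    M = train.X.shape[1]

    if config.use_rpca:
        dec = rpca_decompose(train.X, lam=config.rpca_lam)
        D, E = dec.D, dec.E
    else:
        D, E = train.X, np.zeros_like(train.X)

    if config.use_grouping:
        indicators = cluster_per_class(
            D, train.y, preference=config.ap_preference, damping=config.ap_damping
        )
    else:
        indicators = _unit_indicators(M)

    D_bar, gs = expand_matrix(D, indicators)
    E_bar = apply_expansion(E, gs)

    if config.adaptive_weights:
        s = gene_reliability(E_bar, gs, eps=config.eps)
        w = build_weight_matrix(s, K, eps=config.eps, normalize=config.normalize_weights).w
    else:
        w = np.ones(gs.n_expanded)

    classes = np.unique(train.y)
    Y = (train.y[:, None] == classes[None, :]).astype(float)

    alpha, lam, cv_acc = _cv_select(D_bar, Y, train.y, gs, w, config, seed)

    path = fit_path(
        D_bar,
        Y,
        gs.global_groups,
        gs.group_sizes,
        w,
        alpha=alpha,
        lambdas=np.array([lam]),
        tol=config.tol,
        i_max=config.i_max,
        standardize=config.standardize,
    )
    coef = path[0].coef

    if config.clean_test:
        X_test = np.where(np.isfinite(test.X), test.X, np.nan)
        col_mean = D.mean(axis=0)
        X_test = np.where(np.isnan(X_test), col_mean[None, :], X_test)
    else:
        X_test = test.X
    X_test_bar = apply_expansion(X_test, gs)
    labels, _probs = predict(coef, X_test_bar)
    pred_classes = classes[labels - 1]
    accuracy = float(np.mean(pred_classes == test.y))

    nz_cols = np.flatnonzero(np.any(coef.beta != 0.0, axis=0))
    genes = gs.source_genes()
    selected_genes = {train.gene_ids[g] for g in genes[nz_cols]}
    selected_groups: set[tuple[int, int]] = set()
    for k in range(coef.beta.shape[0]):
        for l in range(1, gs.V + 1):
            idx = gs.global_groups == l
            if np.any(coef.beta[k, idx] != 0.0):
                selected_groups.add((k + 1, l))

    return PipelineResult(
        alpha=alpha,
        lam=lam,
        coef=coef,
        gs=gs,
        selected_genes=selected_genes,
        selected_groups=selected_groups,
        test_accuracy=accuracy,
        cv_accuracy=cv_acc,
        n_selected=len(selected_genes),
    )


def repeat_experiment(
    ds: ExpressionDataset,
    n_runs: int = 10,
    key_threshold: int = 9,
    config: PipelineConfig | None = None,
    master_seed: int = 0,
    train_fraction: float = 2.0 / 3.0,
) -> RepeatSummary:
    """Repeat split+fit ``n_runs`` times; aggregate accuracy and selections.

    Run r uses seed ``master_seed + r``.  Key genes are those selected in
    at least ``key_threshold`` runs.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be at least 1")
    if not 1 <= key_threshold <= n_runs:
        raise ValueError("key_threshold must be in 1..n_runs")
    config = config or PipelineConfig()
    accuracies = []
    gene_counts = []
    results = []
    counts: dict[str, int] = {}
    for r in range(n_runs):
        seed = master_seed + r
        train, test = stratified_split(ds, train_fraction, seed)
        res = run_ramrsgl(train, test, config, seed=seed)
        accuracies.append(res.test_accuracy)
        gene_counts.append(res.n_selected)
        results.append(res)
        for g in res.selected_genes:
            counts[g] = counts.get(g, 0) + 1
    acc = np.asarray(accuracies)
    gc = np.asarray(gene_counts, dtype=float)
    return RepeatSummary(
        accuracies=acc,
        gene_counts=gc,
        accuracy_mean=float(acc.mean()),
        accuracy_sd=float(acc.std(ddof=1)) if n_runs > 1 else 0.0,
        gene_count_mean=float(gc.mean()),
        gene_count_sd=float(gc.std(ddof=1)) if n_runs > 1 else 0.0,
        selection_counts=counts,
        key_genes={g for g, c in counts.items() if c >= key_threshold},
        n_runs=n_runs,
        key_threshold=key_threshold,
        results=results,
    )


def baseline_config(name: str, on_clean: bool = False) -> PipelineConfig:
    """Preset configurations for the method and its ablations.

    ``RAMRSGL`` is the full pipeline.  ``MRSGL`` drops the adaptive
    weights, ``MRGL`` additionally fixes alpha = 0 (pure group Lasso), and
    ``L1`` is plain lasso-penalised multinomial regression without
    grouping or expansion.  ``on_clean`` runs a baseline on the
    RPCA-cleaned matrix instead of the raw one.
    """
    name_up = name.upper()
    if name_up == "AMRSGL":
        raise ValueError("AMRSGL (WGCNA-based grouping) is not supported")
    if name_up == "RAMRSGL":
        return PipelineConfig(name="RAMRSGL")
    if name_up == "MRSGL":
        return PipelineConfig(name="MRSGL", use_rpca=on_clean, adaptive_weights=False)
    if name_up == "MRGL":
        return PipelineConfig(
            name="MRGL", use_rpca=on_clean, adaptive_weights=False, alpha_grid=(0.0,)
        )
    if name_up == "L1":
        return PipelineConfig(
            name="L1",
            use_rpca=on_clean,
            use_grouping=False,
            adaptive_weights=False,
            alpha_grid=(1.0,),
        )
    raise ValueError(f"unknown configuration {name!r}")
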