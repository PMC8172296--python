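"""Synthetic expression data with the structure the pipeline assumes.

The generator plants everything the method is designed to exploit, with
full ground truth for recovery tests:

* an approximately low-rank clean signal ``L``: within each class, genes
  are organised into groups driven by a dominant shared latent factor
  (loadings uniform on [0.5, 1]) plus a weaker second factor, so genes in
  a group are strongly correlated across that class's samples and ``L``
  has rank about ``2 * K * groups_per_class``;
* sparse gross noise ``S``: a ``noise_fraction`` of entries, chosen
  uniformly at random, set to +/- ``noise_amplitude`` (large relative to
  the signal, as RPCA expects);
* a small set of informative groups whose genes receive class-dependent
  mean shifts of size ``effect_size`` arranged on a regular simplex, so
  every pair of classes is equally separated;
* balanced class labels.

The observed matrix is exactly ``X = L + S``.  Informative groups occupy
the same genes in every class's grouping; the remaining genes are
partitioned into class-specific groups by a seeded per-class shuffle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SyntheticParams", "SyntheticTruth", "generate"]


@dataclass
class SyntheticParams:
    """Generation settings.

    Defaults describe a desk-scale three-class study: 60 samples, 120
    genes in 4 groups per class of which 2 are informative, 5% of entries
    hit by gross noise an order of magnitude above the signal scale.
    """

    K: int = 3
    n_per_class: int = 20
    M: int = 120
    groups_per_class: int = 4
    n_informative_groups: int = 2
    noise_fraction: float = 0.05
    noise_amplitude: float = 7.5
    effect_size: float = 4.0

    def validate(self) -> None:
        if self.K < 2:
            raise ValueError("need at least two classes")
        if self.M < self.groups_per_class:
            raise ValueError("more groups than genes")
        if not 0 <= self.n_informative_groups <= self.groups_per_class:
            raise ValueError("informative groups must be between 0 and groups_per_class")
        if not 0.0 <= self.noise_fraction <= 1.0:
            raise ValueError("noise_fraction must be in [0, 1]")
        if self.n_per_class < 2:
            raise ValueError("need at least two samples per class")


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    L: np.ndarray
    S: np.ndarray
    per_class_groups: list[np.ndarray]
    informative_genes: np.ndarray
    informative_groups: np.ndarray
    labels: np.ndarray
    params: SyntheticParams = field(repr=False)


def _simplex_vertices(K: int, d: int) -> np.ndarray:
    """K unit-separated points embedded in d dims (regular simplex, padded)."""
    V = np.eye(K) - 1.0 / K
    # orthonormalise to K-1 dims, then pad/trim to d
    Q, _ = np.linalg.qr(V.T)
    pts = V @ Q[:, : K - 1]
    pts /= np.linalg.norm(pts[0] - pts[1])
    out = np.zeros((K, d))
    use = min(d, K - 1)
    out[:, :use] = pts[:, :use]
    return out


def generate(params: SyntheticParams | None = None, seed: int = 0):
    """Generate one dataset with ground truth.

    Returns
    -------
    (X, y, gene_ids, sample_ids), truth : tuple, SyntheticTruth
        ``X`` is the n x M observed matrix (``L + S`` exactly), ``y`` the
        1-based class labels.  Deterministic given ``seed``.
    """
    params = params or SyntheticParams()
    params.validate()
    rng = np.random.default_rng(seed)
    K, M, G = params.K, params.M, params.groups_per_class
    n = params.n_per_class * K

    labels = np.repeat(np.arange(1, K + 1), params.n_per_class)

    # group assignments: informative groups occupy a fixed block of genes in
    # every class; the rest are shuffled per class
    base_sizes = np.full(G, M // G)
    base_sizes[: M % G] += 1
    bounds = np.concatenate([[0], np.cumsum(base_sizes)])
    n_inf_genes = bounds[params.n_informative_groups]
    per_class_groups: list[np.ndarray] = []
    for t in range(K):
        v = np.empty(M, dtype=int)
        for g in range(params.n_informative_groups):
            v[bounds[g] : bounds[g + 1]] = g + 1
        rest = np.arange(n_inf_genes, M)
        perm = rng.permutation(rest)
        pos = 0
        for g in range(params.n_informative_groups, G):
            sz = base_sizes[g]
            v[perm[pos : pos + sz]] = g + 1
            pos += sz
        per_class_groups.append(v)

    shifts = params.effect_size * _simplex_vertices(K, params.n_informative_groups)

    L = np.zeros((n, M))
    for t in range(1, K + 1):
        rows = np.flatnonzero(labels == t)
        v = per_class_groups[t - 1]
        for g in range(1, G + 1):
            genes = np.flatnonzero(v == g)
            z1 = rng.standard_normal(len(rows))
            z2 = rng.standard_normal(len(rows))
            # dominant shared factor plus a weaker second one: without the
            # second factor every gene in a group z-scores to the same
            # profile, which degenerates message passing and makes recovery
            # trivial; with it, pairwise gene-gene correlation lands in the
            # 0.7-0.98 range typical of real co-expression modules
            a = rng.uniform(0.5, 1.0, size=len(genes))
            b = rng.uniform(0.1, 0.5, size=len(genes))
            L[np.ix_(rows, genes)] = np.outer(z1, a) + np.outer(z2, b)
            if g <= params.n_informative_groups:
                L[np.ix_(rows, genes)] += shifts[t - 1, g - 1]

    S = np.zeros((n, M))
    n_corrupt = int(round(params.noise_fraction * n * M))
    if n_corrupt > 0:
        flat = rng.choice(n * M, size=n_corrupt, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_corrupt)
        S.flat[flat] = signs * params.noise_amplitude

    X = L + S
    gene_ids = [f"gene_{j + 1}" for j in range(M)]
    sample_ids = [f"sample_{i + 1}" for i in range(n)]
    informative_genes = np.arange(n_inf_genes)
    truth = SyntheticTruth(
        L=L,
        S=S,
        per_class_groups=per_class_groups,
        informative_genes=informative_genes,
        informative_groups=np.arange(1, params.n_informative_groups + 1),
        labels=labels,
        params=params,
    )
    return (X, labels, gene_ids, sample_ids), truth
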