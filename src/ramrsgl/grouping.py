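"""Per-class gene grouping, overlap expansion, and noise-adaptive weights.

Each cancer class may organise the same genes into different co-expression
groups.  The overlapping clustering strategy honours this by clustering the
genes separately within each class (on the clean, noise-removed signal) and
then duplicating every gene once per class: class t's copy of the design
matrix has its columns reordered so that class t's groups form contiguous
blocks, and the K reordered copies are concatenated into an n x (K*M)
expanded design.  The noise matrix is expanded by the same column map and
its per-column l1 norms define gene reliabilities s = 1/(||e||_1 + eps);
the adaptive l1 weights are the reciprocals w = 1/s, so noisier genes pay a
larger penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ramrsgl.ap_cluster import ap_cluster, set_preference, similarity_negative_sq_euclidean

__all__ = [
    "GroupStructure",
    "ExpandedData",
    "WeightMatrix",
    "cluster_per_class",
    "expand_matrix",
    "apply_expansion",
    "gene_reliability",
    "build_weight_matrix",
]


@dataclass
class GroupStructure:
    """Bookkeeping for the class-wise overlap expansion.

    Attributes
    ----------
    per_class_indicators : list of ndarray
        K vectors of length M; entry g of vector t is the 1-based group of
        gene g within class t's clustering.
    global_groups : ndarray of shape (K*M,)
        1-based global group index of each expanded column; groups are
        contiguous blocks ordered class 1's groups, then class 2's, ...
    V : int
        Total number of global groups (sum of per-class cluster counts).
    group_sizes : ndarray of shape (V,)
        Number of expanded columns in each global group.
    column_map : ndarray of shape (K*M, 3)
        Per expanded column the triple (class t, original gene index,
        global group), classes/groups 1-based, gene indices 0-based.
    K, M : int
        Class and gene counts.
    """

    per_class_indicators: list[np.ndarray]
    global_groups: np.ndarray
    V: int
    group_sizes: np.ndarray
    column_map: np.ndarray
    K: int
    M: int

    @property
    def n_expanded(self) -> int:
        return self.K * self.M

    def source_genes(self) -> np.ndarray:
        """0-based original gene index of every expanded column."""
        return self.column_map[:, 1]


@dataclass
class ExpandedData:
    """Expanded clean and noise matrices sharing one GroupStructure."""

    D_bar: np.ndarray
    E_bar: np.ndarray
    gs: GroupStructure


@dataclass
class WeightMatrix:
    """Adaptive penalty weights: w per expanded column, replicated K times."""

    s: np.ndarray
    w: np.ndarray
    eps: float
    K: int

    @property
    def W(self) -> np.ndarray:
        return np.tile(self.w, (self.K, 1))


def _renumber_first_appearance(labels: np.ndarray) -> np.ndarray:
    """Map arbitrary cluster ids to 1..n_clusters in order of first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty(labels.shape, dtype=int)
    for i, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[i] = mapping[lab]
    return out


def cluster_per_class(
    D: np.ndarray,
    y: np.ndarray,
    preference: float | str = "median",
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 100,
) -> list[np.ndarray]:
    """Cluster the genes within each class of the clean matrix.

    For class t the sub-matrix of class-t samples is taken, every gene
    profile is z-scored across those samples, and affinity propagation is
    run on negative squared Euclidean gene-gene distances.  For z-scored
    profiles this distance is a monotone affine function of the Pearson
    correlation, so correlation-similar genes cluster together.  Genes that
    are constant within a class z-score to the zero vector.

    Returns K indicator vectors with groups numbered 1..count in order of
    first appearance.
    """
    D = np.asarray(D, dtype=float)
    y = np.asarray(y, dtype=int)
    classes = np.unique(y)
    indicators: list[np.ndarray] = []
    for cls in classes:
        sub = D[y == cls]
        if sub.shape[0] < 2:
            raise ValueError(f"class {cls} has fewer than 2 samples; cannot cluster")
        mu = sub.mean(axis=0)
        sd = sub.std(axis=0)
        sd_safe = np.where(sd > 0, sd, 1.0)
        Z = (sub - mu) / sd_safe  # genes with zero variance become zero profiles
        # identical profiles must co-cluster by definition, and exact
        # duplicates make message passing degenerate (symmetric ties), so
        # cluster the unique profiles and map back
        uniq, inverse = np.unique(Z.T, axis=0, return_inverse=True)
        if uniq.shape[0] == 1:
            indicators.append(np.ones(Z.shape[1], dtype=int))
            continue
        sim = similarity_negative_sq_euclidean(uniq)
        sim = set_preference(sim, preference)
        res = ap_cluster(sim, damping=damping, max_iter=max_iter, conv_iter=conv_iter)
        indicators.append(_renumber_first_appearance(res.labels[inverse]))
    return indicators


def expand_matrix(A: np.ndarray, indicators: list[np.ndarray]) -> tuple[np.ndarray, GroupStructure]:
    """Duplicate and reorder columns of ``A`` once per class.

    For class t the columns are stably reordered so genes of class t's
    group 1 come first, then group 2, ...; the K reordered copies are
    concatenated left-to-right.  Within a group, genes keep their original
    relative order (stable sort).
    """
    A = np.asarray(A, dtype=float)
    M = A.shape[1]
    K = len(indicators)
    for t, v in enumerate(indicators):
        if len(v) != M:
            raise ValueError(f"indicator {t} has length {len(v)}, expected {M}")

    blocks = []
    col_map_rows = []
    global_groups = []
    group_offset = 0
    for t, v in enumerate(indicators, start=1):
        v = np.asarray(v, dtype=int)
        order = np.argsort(v, kind="stable")
        blocks.append(A[:, order])
        for j in order:
            g = group_offset + int(v[j])
            col_map_rows.append((t, int(j), g))
            global_groups.append(g)
        group_offset += int(v.max())

    global_groups_arr = np.asarray(global_groups, dtype=int)
    V = group_offset
    group_sizes = np.bincount(global_groups_arr, minlength=V + 1)[1:]
    gs = GroupStructure(
        per_class_indicators=[np.asarray(v, dtype=int) for v in indicators],
        global_groups=global_groups_arr,
        V=V,
        group_sizes=group_sizes,
        column_map=np.asarray(col_map_rows, dtype=int),
        K=K,
        M=M,
    )
    return np.concatenate(blocks, axis=1), gs


def apply_expansion(x: np.ndarray, gs: GroupStructure) -> np.ndarray:
    """Expand a length-M sample (or n x M matrix) by the recorded column map."""
    x = np.asarray(x, dtype=float)
    genes = gs.source_genes()
    if x.ndim == 1:
        if x.shape[0] != gs.M:
            raise ValueError(f"expected length {gs.M}, got {x.shape[0]}")
        return x[genes]
    if x.shape[1] != gs.M:
        raise ValueError(f"expected {gs.M} columns, got {x.shape[1]}")
    return x[:, genes]


def gene_reliability(E_bar: np.ndarray, gs: GroupStructure, eps: float = 1e-6) -> np.ndarray:
    """Reliability of each expanded column: s_j = 1 / (||E_bar[:, j]||_1 + eps).

    A noisier gene (larger l1 noise column) is less reliable.  ``eps``
    keeps the reliability finite for noise-free columns.
    """
    if eps <= 0:
        raise ValueError("eps must be positive")
    E_bar = np.asarray(E_bar, dtype=float)
    return 1.0 / (np.sum(np.abs(E_bar), axis=0) + eps)


def build_weight_matrix(s: np.ndarray, K: int, eps: float = 1e-6, normalize: bool = False) -> WeightMatrix:
    """Adaptive l1 weights w = 1/s, replicated across the K discriminants.

    With ``normalize=True`` the weights are rescaled to mean 1, decoupling
    the lambda scale from the absolute noise magnitude.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("reliabilities must be strictly positive")
    w = 1.0 / s
    if normalize:
        w = w / w.mean()
    return WeightMatrix(s=s, w=w, eps=eps, K=K)
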