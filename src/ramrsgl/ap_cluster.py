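"""Affinity propagation clustering by responsibility/availability messages.

Affinity propagation treats every point as a candidate exemplar (cluster
center) and exchanges two kinds of real-valued messages: the responsibility
r(i,k), how well suited point k is to serve as the exemplar of i relative to
other candidates, and the availability a(i,k), how appropriate it would be
for i to choose k given the support k has gathered from other points.  The
diagonal of the similarity matrix holds the preference p(k), the
self-similarity controlling how readily k becomes an exemplar; the number
of clusters emerges from it rather than being fixed in advance.

The message updates live here as standalone operations so they can be
checked against brute-force loops; :func:`ap_cluster` iterates them with
damping until the exemplar set is stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimilarityMatrix",
    "APResult",
    "similarity_negative_sq_euclidean",
    "set_preference",
    "update_responsibility",
    "update_availability",
    "ap_cluster",
]


@dataclass
class SimilarityMatrix:
    """n x n similarity matrix; diagonal holds the exemplar preferences.

    Off-diagonal ``S[i, k]`` is the similarity s(i,k); the diagonal is NaN
    until :func:`set_preference` fills it.
    """

    S: np.ndarray

    @property
    def n(self) -> int:
        return self.S.shape[0]

    def preference_is_set(self) -> bool:
        return bool(np.all(np.isfinite(np.diag(self.S))))


@dataclass
class APResult:
    exemplars: tuple[int, ...]
    labels: np.ndarray
    n_iter: int
    converged: bool
    sum_of_similarities: float
    net_similarity: float
    _: dict = field(default_factory=dict, repr=False)


def similarity_negative_sq_euclidean(points: np.ndarray) -> SimilarityMatrix:
    """Pairwise similarities s(i,k) = -||p_i - p_k||^2; diagonal left unset."""
    P = np.atleast_2d(np.asarray(points, dtype=float))
    if P.shape[0] == 0:
        raise ValueError("need at least one point")
    if not np.all(np.isfinite(P)):
        raise ValueError("points contain non-finite values")
    sq = np.sum(P * P, axis=1)
    S = -(sq[:, None] + sq[None, :] - 2.0 * (P @ P.T))
    S = np.minimum(S, 0.0)  # clamp round-off above zero
    np.fill_diagonal(S, np.nan)
    return SimilarityMatrix(S=S)


def set_preference(sim: SimilarityMatrix, p: float | str = "median") -> SimilarityMatrix:
    """Fill the diagonal with a common preference.

    ``p="median"`` uses the median of all off-diagonal similarities — the
    conventional default that yields a moderate number of clusters.
    """
    S = sim.S.copy()
    n = S.shape[0]
    if isinstance(p, str):
        if p != "median":
            raise ValueError(f"unknown preference rule {p!r}")
        if n == 1:
            val = 0.0
        else:
            off = S[~np.eye(n, dtype=bool)]
            val = float(np.median(off))
    else:
        val = float(p)
    np.fill_diagonal(S, val)
    return SimilarityMatrix(S=S)


def update_responsibility(
    S: np.ndarray, R: np.ndarray, A: np.ndarray, damping: float = 0.0
) -> np.ndarray:
    """One responsibility sweep: r(i,k) <- s(i,k) - max_{k'!=k}[a(i,k') + s(i,k')].

    The returned matrix is ``damping*R + (1-damping)*candidate``.
    """
    if not 0.0 <= damping < 1.0:
        raise ValueError("damping must be in [0, 1)")
    AS = A + S
    n = S.shape[0]
    idx_max = np.argmax(AS, axis=1)
    row_max = AS[np.arange(n), idx_max]
    AS_masked = AS.copy()
    AS_masked[np.arange(n), idx_max] = -np.inf
    row_second = np.max(AS_masked, axis=1)
    cand = S - row_max[:, None]
    cand[np.arange(n), idx_max] = S[np.arange(n), idx_max] - row_second
    return damping * R + (1.0 - damping) * cand


def update_availability(R: np.ndarray, A: np.ndarray, damping: float = 0.0) -> np.ndarray:
    """One availability sweep.

    Off-diagonal: a(i,k) <- min(0, r(k,k) + sum_{i' not in {i,k}} max(0, r(i',k)));
    diagonal: a(k,k) <- sum_{i'!=k} max(0, r(i',k)).
    """
    if not 0.0 <= damping < 1.0:
        raise ValueError("damping must be in [0, 1)")
    n = R.shape[0]
    Rp = np.maximum(R, 0.0)
    np.fill_diagonal(Rp, 0.0)
    colpos = np.sum(Rp, axis=0)  # sum_{i'!=k} max(0, r(i',k))
    cand = np.minimum(0.0, np.diag(R)[None, :] + colpos[None, :] - Rp)
    cand[np.arange(n), np.arange(n)] = colpos
    return damping * A + (1.0 - damping) * cand


def _assign(S: np.ndarray, exemplars: np.ndarray) -> np.ndarray:
    """Label each point with its best exemplar (ties to lowest index)."""
    labels = np.empty(S.shape[0], dtype=int)
    sub = S[:, exemplars]
    best = np.argmax(sub, axis=1)  # argmax ties break to lowest index
    labels[:] = exemplars[best]
    labels[exemplars] = exemplars
    return labels


def ap_cluster(
    sim: SimilarityMatrix,
    damping: float = 0.9,
    max_iter: int = 1000,
    conv_iter: int = 100,
    jitter: float = 0.0,
    seed: int | None = None,
) -> APResult:
    """Run affinity propagation to convergence of the exemplar set.

    Point k is an exemplar when a(k,k) + r(k,k) > 0; iteration stops once
    the exemplar set has been unchanged for ``conv_iter`` consecutive
    iterations (the cluster boundaries no longer move) or at ``max_iter``.
    ``jitter`` optionally adds tiny seeded noise to break exact symmetries;
    it is off by default so results are deterministic.
    """
    S = np.array(sim.S, dtype=float)
    n = S.shape[0]
    if not np.all(np.isfinite(S)):
        raise ValueError("similarity matrix has non-finite entries; set the preference first")
    if not 0.0 <= damping < 1.0:
        raise ValueError("damping must be in [0, 1)")
    if jitter > 0.0:
        rng = np.random.default_rng(seed)
        scale = jitter * (np.max(S) - np.min(S) + np.finfo(float).tiny)
        S = S + scale * rng.standard_normal(S.shape)

    R = np.zeros_like(S)
    A = np.zeros_like(S)
    prev_ex: tuple[int, ...] | None = None
    stable = 0
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        R = update_responsibility(S, R, A, damping)
        A = update_availability(R, A, damping)
        ex = tuple(np.flatnonzero(np.diag(A) + np.diag(R) > 0).tolist())
        if ex and ex == prev_ex:
            stable += 1
            if stable >= conv_iter:
                converged = True
                break
        else:
            stable = 0
        prev_ex = ex

    exemplars = np.flatnonzero(np.diag(A) + np.diag(R) > 0)
    if exemplars.size == 0:
        exemplars = np.array([int(np.argmax(np.diag(A) + np.diag(R)))])
        converged = False
    labels = _assign(S, exemplars)

    non_ex = np.setdiff1d(np.arange(n), exemplars)
    sum_sim = float(np.sum(S[non_ex, labels[non_ex]])) if non_ex.size else 0.0
    net = sum_sim + float(np.sum(S[exemplars, exemplars]))
    return APResult(
        exemplars=tuple(int(e) for e in exemplars),
        labels=labels,
        n_iter=it,
        converged=converged,
        sum_of_similarities=sum_sim,
        net_similarity=net,
    )
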