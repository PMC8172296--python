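"""Robust principal component analysis by principal component pursuit.

Gene-expression matrices carry gross, entrywise-sparse corruption on top of
a low-rank biological signal.  Principal component pursuit separates the two
by solving

    min_{D,E}  ||D||_* + lam * ||E||_1   s.t.   X = D + E,

where ``||.||_*`` is the nuclear norm (sum of singular values, a convex
surrogate for rank) and ``||.||_1`` the entrywise l1 norm.  The solver here
is the inexact augmented Lagrange multiplier (IALM) method, whose only
problem parameter is ``lam``; the canonical theoretical choice
``lam = 1/sqrt(max(n, m))`` is the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RPCADecomposition", "rpca_decompose", "singular_value_threshold"]


@dataclass
class RPCADecomposition:
    """Low-rank + sparse split ``X = D + E`` of an expression matrix.

    Attributes
    ----------
    D : ndarray
        Clean low-rank part, same shape as the input.
    E : ndarray
        Entrywise-sparse noise part, same shape as the input.
    rank_D : int
        Number of singular values of ``D`` above ``1e-8`` times the largest.
    lam : float
        Sparsity trade-off weight actually used.
    n_iter : int
        Number of IALM iterations performed.
    converged : bool
        Whether the feasibility residual reached tolerance within the
        iteration budget.
    """

    D: np.ndarray
    E: np.ndarray
    rank_D: int
    lam: float
    n_iter: int
    converged: bool


def singular_value_threshold(A: np.ndarray, tau: float) -> np.ndarray:
    """Proximal operator of the nuclear norm: shrink singular values by ``tau``.

    Returns ``U @ diag(max(s - tau, 0)) @ Vt`` for the SVD ``A = U s Vt``.
    """
    A = np.asarray(A, dtype=float)
    if not np.all(np.isfinite(A)):
        raise ValueError("singular_value_threshold: input contains non-finite entries")
    if tau < 0:
        raise ValueError("tau must be nonnegative")
    if tau == 0:
        return A.copy()
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    keep = s > 0
    return (U[:, keep] * s[keep]) @ Vt[keep]


def _soft(A: np.ndarray, tau: float) -> np.ndarray:
    return np.sign(A) * np.maximum(np.abs(A) - tau, 0.0)


def rpca_decompose(
    X: np.ndarray,
    lam: float | None = None,
    tol: float = 1e-7,
    max_iter: int = 1000,
) -> RPCADecomposition:
    """Decompose ``X`` into low-rank ``D`` plus sparse ``E`` via IALM.

    Parameters
    ----------
    X : ndarray of shape (n_samples, n_genes)
        Finite matrix to decompose.
    lam : float, optional
        Weight of the l1 term.  ``None`` selects ``1/sqrt(max(n, m))``.
    tol : float
        Relative feasibility tolerance ``||X - D - E||_F / ||X||_F``.
    max_iter : int
        IALM iteration budget; exhaustion flags ``converged=False`` rather
        than raising.

    Notes
    -----
    The augmented-Lagrangian penalty is initialised as ``mu = 1.25/||X||_2``
    and grown by a factor 1.6 per iteration, the standard IALM schedule.
    The decomposition is scale-equivariant: decomposing ``c*X`` (same lam)
    yields ``(c*D, c*E)`` for ``c > 0``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-d matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("rpca_decompose: input contains non-finite entries")
    n, m = X.shape
    if lam is None:
        lam = 1.0 / np.sqrt(max(n, m))
    if lam <= 0:
        raise ValueError("lam must be positive")

    norm_fro = np.linalg.norm(X)
    if norm_fro == 0.0:
        Z = np.zeros_like(X)
        return RPCADecomposition(D=Z, E=Z.copy(), rank_D=0, lam=lam, n_iter=0, converged=True)

    norm_two = np.linalg.norm(X, 2)
    mu = 1.25 / norm_two
    rho = 1.6
    # dual ascent starting point scaled as in Lin et al.'s IALM
    J = max(norm_two, np.max(np.abs(X)) / lam)
    Y = X / J

    D = np.zeros_like(X)
    E = np.zeros_like(X)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        D = singular_value_threshold(X - E + Y / mu, 1.0 / mu)
        E = _soft(X - D + Y / mu, lam / mu)
        R = X - D - E
        Y = Y + mu * R
        mu = min(mu * rho, 1e7 / norm_two)
        if np.linalg.norm(R) / norm_fro < tol:
            converged = True
            break

    s = np.linalg.svd(D, compute_uv=False)
    rank_D = 0 if s.size == 0 or s[0] == 0 else int(np.sum(s > 1e-8 * s[0]))
    return RPCADecomposition(D=D, E=E, rank_D=rank_D, lam=float(lam), n_iter=it, converged=converged)
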