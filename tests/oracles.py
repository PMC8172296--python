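"""Independent oracles shared by the test suite.

These deliberately avoid the package's own solver paths: exhaustive
enumeration for exemplar subsets, and a generic bound-constrained
quasi-Newton minimizer (on the split-variable reformulation) for the
penalised multinomial objective.
"""

import itertools

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp


def exhaustive_best_net_similarity(S):
    """Best net similarity over all non-empty exemplar subsets."""
    n = S.shape[0]
    best = -np.inf
    for r in range(1, n + 1):
        for ex in itertools.combinations(range(n), r):
            ex = list(ex)
            net = sum(S[k, k] for k in ex)
            for i in range(n):
                if i not in ex:
                    net += max(S[i, k] for k in ex)
            best = max(best, net)
    return best


def reference_objective(X, Y, alpha, lam, groups, sizes, w, beta0, beta):
    """Penalised multinomial objective computed from scratch."""
    scores = beta0 + X @ beta.T
    nll = float(np.mean(logsumexp(scores, axis=1) - np.sum(Y * scores, axis=1)))
    pen = 0.0
    for l in range(1, len(sizes) + 1):
        idx = groups == l
        pen += (1 - alpha) * lam * np.sqrt(sizes[l - 1]) * np.linalg.norm(beta[:, idx], axis=1).sum()
    pen += alpha * lam * float(np.sum(np.abs(beta) * w[None, :]))
    return nll + pen


def generic_convex_minimum(X, Y, alpha, lam, groups, sizes, w):
    """Minimum objective from an independent generic convex minimizer.

    Splits beta into nonnegative parts so the weighted l1 term is linear,
    smooths the group norm by 1e-14, runs L-BFGS-B, and reports the exact
    (unsmoothed) objective at the solution found.
    """
    n, P = X.shape
    K = Y.shape[1]
    nb = K * P

    def unpack(z):
        b0 = z[:K]
        B = z[K : K + nb].reshape(K, P) - z[K + nb :].reshape(K, P)
        return b0, B

    def obj(z):
        b0, B = unpack(z)
        scores = b0 + X @ B.T
        nll = np.mean(logsumexp(scores, axis=1) - np.sum(Y * scores, axis=1))
        l1 = np.sum((z[K : K + nb].reshape(K, P) + z[K + nb :].reshape(K, P)) * w[None, :])
        grp = 0.0
        for l in range(1, len(sizes) + 1):
            idx = groups == l
            grp += np.sqrt(sizes[l - 1]) * np.sum(np.sqrt(np.sum(B[:, idx] ** 2, axis=1) + 1e-14))
        return nll + (1 - alpha) * lam * grp + alpha * lam * l1

    z0 = np.zeros(K + 2 * nb)
    bounds = [(None, None)] * K + [(0.0, None)] * (2 * nb)
    res = minimize(
        obj, z0, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 50000, "ftol": 1e-16, "gtol": 1e-12},
    )
    b0, B = unpack(res.x)
    return reference_objective(X, Y, alpha, lam, groups, sizes, w, b0, B)
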