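import numpy as np
import pytest

import ramrsgl as rg


@pytest.fixture(scope="session")
def planted_rpca_instance():
    """50x40 rank-2 signal with 5% +/-10 spikes and the planted parts."""
    rng = np.random.default_rng(0)
    L = rng.standard_normal((50, 2)) @ rng.standard_normal((2, 40))
    S = np.zeros((50, 40))
    idx = rng.choice(L.size, size=int(0.05 * L.size), replace=False)
    S.flat[idx] = rng.choice([-10.0, 10.0], size=len(idx))
    return L, S


@pytest.fixture(scope="session")
def tiny_multinomial_instance():
    """30 samples, 6 features in 2 groups, 3 classes, fixed seed."""
    rng = np.random.default_rng(7)
    n, K, P = 30, 3, 6
    groups = np.array([1, 1, 1, 2, 2, 2])
    sizes = np.array([3, 3])
    w = rng.uniform(0.5, 2.0, P)
    X = rng.standard_normal((n, P))
    beta_true = np.zeros((K, P))
    beta_true[0, 0] = 2.0
    beta_true[1, 1] = -2.0
    beta_true[2, 3] = 1.5
    y = np.array([np.argmax(s + rng.gumbel(size=K)) for s in X @ beta_true.T])
    Y = np.eye(K)[y]
    return X, Y, y, groups, sizes, w


@pytest.fixture(scope="session")
def default_dataset():
    """One synthetic dataset at generator defaults with its ground truth."""
    (X, y, gene_ids, sample_ids), truth = rg.generate(seed=11)
    ds = rg.ExpressionDataset(X=X, y=y, gene_ids=gene_ids, sample_ids=sample_ids)
    return ds, truth
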