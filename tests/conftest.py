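import numpy as np
import pytest

from gsblr.blr_single import GeneSetDesign


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_design(rng):
    """60 genes, 3 disjoint sets of 20 (enumeration-oracle scale)."""
    n, m = 60, 3
    X = np.zeros((n, m))
    for j in range(m):
        X[20 * j : 20 * (j + 1), j] = 1
    return GeneSetDesign([f"g{i}" for i in range(n)], ["a", "b", "c"], X)


@pytest.fixture
def random_design(rng):
    """200 genes, 20 overlapping random sets."""
    n, m = 200, 20
    X = (rng.random((n, m)) < 0.2).astype(float)
    X[:, X.sum(axis=0) == 0] = 1.0
    return GeneSetDesign([f"g{i}" for i in range(n)], [f"s{j}" for j in range(m)], X)


def exact_spike_slab_pips(y, X, sigma_b2, sigma_e2, pi):
    """Exact posterior inclusion by enumeration over all 2^m submodels.

    Conjugate marginal likelihoods: y_c | gamma ~ N(0, sigma_e2 I +
    sigma_b2 X_g X_g').  Independent oracle for the Gibbs sampler;
    feasible for m <= ~12.
    """
    import itertools

    yc = y - y.mean()
    n, m = X.shape
    models = list(itertools.product([0, 1], repeat=m))
    logw = []
    for g in models:
        idx = [j for j in range(m) if g[j]]
        C = sigma_e2 * np.eye(n)
        if idx:
            C = C + sigma_b2 * X[:, idx] @ X[:, idx].T
        _, logdet = np.linalg.slogdet(C)
        ll = -0.5 * (yc @ np.linalg.solve(C, yc)) - 0.5 * logdet
        lp = sum(np.log(pi) if gi else np.log(1 - pi) for gi in g)
        logw.append(ll + lp)
    logw = np.array(logw)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return np.array(
        [sum(w[i] for i, g in enumerate(models) if g[j]) for j in range(m)]
    )
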