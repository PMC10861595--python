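import numpy as np
import pytest

from ceda.datasets import DomainDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_domain_pair(seed, n_s=60, n_t=50, d=5, labeled=True):
    """Two generic Gaussian domains with mild shift, for contract tests."""
    r = np.random.default_rng(seed)
    Xs = r.standard_normal((n_s, d)) @ r.standard_normal((d, d)) * 0.5
    Xt = r.standard_normal((n_t, d)) @ r.standard_normal((d, d)) * 0.5 + 0.3
    ys = None
    if labeled:
        ys = np.tile([1, 2], n_s // 2 + 1)[:n_s]
        Xs[ys == 2] += 2.0
    return (
        DomainDataset(Xs, ys, domain_tag="source"),
        DomainDataset(Xt, None, domain_tag="target"),
    )


def separable_domain(seed, n_per_class=40, d=3, gap=8.0, tag="source"):
    """Well-separated two-class Gaussians (1NN is essentially perfect)."""
    r = np.random.default_rng(seed)
    X1 = r.standard_normal((n_per_class, d))
    X2 = r.standard_normal((n_per_class, d)) + gap
    X = np.vstack([X1, X2])
    y = np.concatenate(
        [np.full(n_per_class, 1, np.int64), np.full(n_per_class, 2, np.int64)]
    )
    return DomainDataset(X, y, domain_tag=tag)
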