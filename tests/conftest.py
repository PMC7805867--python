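import numpy as np
import pytest

from selfopt.connectome import CHEMICAL
from selfopt.network import SignedNetwork


def make_net(n, edges, names=None):
    """Small SignedNetwork from (pre, post, w[, kind]) tuples."""
    pre = np.array([e[0] for e in edges], dtype=np.int64)
    post = np.array([e[1] for e in edges], dtype=np.int64)
    w = np.array([e[2] for e in edges], dtype=float)
    kind = np.array([e[3] if len(e) > 3 else CHEMICAL for e in edges],
                    dtype=object)
    neurons = list(names) if names else [f"n{i}" for i in range(n)]
    return SignedNetwork(neurons, pre, post, kind, w, np.zeros_like(w))


def random_symmetric_net(rng, n=None, p_edge=0.5, self_coupling=False):
    """Random net whose aggregated weight matrix is symmetric with
    non-negative diagonal (the classic Lyapunov regime)."""
    if n is None:
        n = int(rng.integers(3, 13))
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p_edge:
                w = float(rng.uniform(0.1, 1.0) * rng.choice([-1.0, 1.0]))
                edges.append((i, j, w))
                edges.append((j, i, w))
    if self_coupling:
        for i in range(n):
            if rng.random() < 0.3:
                edges.append((i, i, float(rng.uniform(0.1, 0.5))))
    if not edges:
        edges = [(0, 1, 0.5), (1, 0, 0.5)]
    return make_net(n, edges)


def random_net(rng, n=None, m=None):
    """Random directed multigraph net (parallel edges allowed)."""
    if n is None:
        n = int(rng.integers(2, 11))
    if m is None:
        m = int(rng.integers(1, 3 * n))
    edges = []
    for _ in range(m):
        i, j = int(rng.integers(n)), int(rng.integers(n))
        w = float(rng.uniform(0.05, 1.0) * rng.choice([-1.0, 1.0]))
        edges.append((i, j, w))
    return make_net(n, edges)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
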