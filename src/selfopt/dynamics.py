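"""Asynchronous binary Hopfield dynamics and constraint-satisfaction energy.

States are ±1 vectors, one entry per neuron.  A single asynchronous
update sets neuron *i* to the sign of its local field — the weighted sum
of its presynaptic states over all incoming edges (parallel edges sum;
self-edges contribute ``w · s_i``).  A zero field keeps the previous
state, so attractor detection is not perturbed by an arbitrary
tie-break.

The energy ``E = −Σ_edges w^O · s_pre · s_post`` measures constraint
satisfaction against the *original* weights: an edge's constraint is
satisfied when ``w · s_pre · s_post > 0``, so lower energy means better
coordination.  The dynamics themselves run on the behavioral
(original + learned, clamped) weights; both layers are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import ClusterPartition
from .exceptions import CapacityError
from .network import SignedNetwork

#: Sentinel scope selecting only edges whose endpoints lie in different clusters.
INTER = "inter"


def random_state(n: int, rng: np.random.Generator) -> np.ndarray:
    """IID uniform ±1 state vector of length n."""
    return (rng.integers(0, 2, n) * 2 - 1).astype(np.float64)


@dataclass
class RelaxationResult:
    final_state: np.ndarray
    is_fixed_point: bool
    steps_taken: int


def aggregate_matrix(net: SignedNetwork, use_behavioral: bool = True,
                     clip: bool = True) -> np.ndarray:
    """Dense incoming-weight matrix A with ``A[i, j] = Σ_k w(j→i)``.

    Parallel edges are summed, so ``field = A @ s`` reproduces the
    multigraph edge-sum exactly.
    """
    w = net.behavioral_weights(clip) if use_behavioral else net.w_original
    A = np.zeros((net.n, net.n))
    np.add.at(A, (net.post, net.pre), w)
    return A


def local_field(net: SignedNetwork, s: np.ndarray, i: int,
                use_behavioral: bool = True, clip: bool = True) -> float:
    """Weighted input to neuron i: Σ over incoming edges (j→i, k) of w·s_j."""
    mask = net.post == i
    w = net.behavioral_weights(clip) if use_behavioral else net.w_original
    return float(np.dot(w[mask], s[net.pre[mask]]))


def update_neuron(net: SignedNetwork, s: np.ndarray, i: int,
                  use_behavioral: bool = True) -> np.ndarray:
    """One asynchronous update of neuron i; returns the new state vector."""
    f = local_field(net, s, i, use_behavioral)
    out = s.copy()
    if f > 0:
        out[i] = 1.0
    elif f < 0:
        out[i] = -1.0
    return out


def _relax_matrix(A: np.ndarray, s: np.ndarray, targets) -> np.ndarray:
    """Sequential asynchronous updates of the listed target neurons (in place)."""
    for t in targets:
        f = A[t] @ s
        if f > 0.0:
            s[t] = 1.0
        elif f < 0.0:
            s[t] = -1.0
    return s


def _violations(A: np.ndarray, s: np.ndarray) -> np.ndarray:
    f = A @ s
    return ((f > 0) & (s != 1.0)) | ((f < 0) & (s != -1.0))


def is_fixed_point(net: SignedNetwork, s: np.ndarray,
                   use_behavioral: bool = True, clip: bool = True) -> bool:
    """True iff no single-neuron update would change the state."""
    return not _violations(aggregate_matrix(net, use_behavioral, clip), s).any()


def relax(net: SignedNetwork, s0: np.ndarray, n_updates: int | None = None,
          rng: int | np.random.Generator = 0, use_behavioral: bool = True,
          check_interval: int | None = None) -> RelaxationResult:
    """Run asynchronous updates from s0, targets drawn uniformly at random.

    Defaults to a fixed budget of ``10 × n`` updates.  With
    ``check_interval`` set, the relaxation stops early as soon as a
    fixed-point check at that interval succeeds.  Deterministic given
    the generator/seed.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = net.n
    if n_updates is None:
        n_updates = 10 * n
    if n_updates < 0:
        raise ValueError("n_updates must be >= 0")
    A = aggregate_matrix(net, use_behavioral)
    s = np.asarray(s0, dtype=np.float64).copy()
    done = 0
    while done < n_updates:
        block = n_updates - done
        if check_interval:
            block = min(block, check_interval)
        targets = rng.integers(0, n, block).tolist()
        _relax_matrix(A, s, targets)
        done += block
        if check_interval and not _violations(A, s).any():
            break
    return RelaxationResult(s, not _violations(A, s).any(), done)


def _scope_mask(net: SignedNetwork, scope, partition: ClusterPartition | None):
    if scope is None:
        return slice(None)
    if partition is None:
        raise ValueError("a scope requires a cluster partition")
    labels = partition.labels_for(net.neurons)
    a, b = labels[net.pre], labels[net.post]
    if scope == INTER:
        return a != b
    scope = {str(l) for l in scope}
    return np.isin(a, list(scope)) & np.isin(b, list(scope))


def energy(net: SignedNetwork, s: np.ndarray, scope=None,
           partition: ClusterPartition | None = None) -> float:
    """Constraint-satisfaction energy −Σ w_original·s_pre·s_post.

    Always evaluated against the original weights, never the learned
    layer.  ``scope`` restricts the sum to edges with both endpoints in
    the given cluster-label set, or — with the :data:`INTER` sentinel —
    to edges crossing cluster boundaries.
    """
    m = _scope_mask(net, scope, partition)
    return float(-(net.w_original[m] * s[net.pre[m]] * s[net.post[m]]).sum())


def behavioral_energy(net: SignedNetwork, s: np.ndarray, clip: bool = True) -> float:
    """Energy under the behavioral (learned) weights, for diagnostics."""
    w = net.behavioral_weights(clip)
    return float(-(w * s[net.pre] * s[net.post]).sum())


def enumerate_stable_states(net: SignedNetwork, use_behavioral: bool = True,
                            max_n: int = 20) -> list[np.ndarray]:
    """All fixed points of the asynchronous dynamics, by brute force.

    Exhaustively checks every one of the 2^n states; guarded to small
    networks.  Intended as a test oracle for attractor and energy
    properties.
    """
    n = net.n
    if n > max_n:
        raise CapacityError(f"enumeration of 2^{n} states refused (n > {max_n})")
    A = aggregate_matrix(net, use_behavioral)
    codes = np.arange(2 ** n, dtype=np.int64)
    S = (((codes[:, None] >> np.arange(n)) & 1) * 2 - 1).astype(np.float64)
    F = S @ A.T
    bad = ((F > 0) & (S != 1.0)) | ((F < 0) & (S != -1.0))
    stable = ~bad.any(axis=1)
    return [S[i].copy() for i in np.flatnonzero(stable)]
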