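"""Signed, normalized weight structure over a connectome multigraph.

The network keeps two weight layers per directed edge: ``w_original``,
the normalized (and sign-assigned) connectome weight that defines the
constraint-satisfaction energy, and ``w_delta``, the accumulated Hebbian
changes.  The dynamics run on the *behavioral* weight
``clamp(w_original + w_delta, -1, 1)`` while reported energies always
use ``w_original``.

Inhibition is introduced by negating a fixed fraction of edge weights,
placed uniformly, only within clusters, or only between clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .connectome import GAP, ClusterPartition, Connectome
from .exceptions import CapacityError

logger = logging.getLogger(__name__)


@dataclass
class SignedNetwork:
    """Directed multigraph with original and learned weight layers."""

    neurons: list[str]
    pre: np.ndarray
    post: np.ndarray
    kind: np.ndarray
    w_original: np.ndarray
    w_delta: np.ndarray
    n_clipped: int = 0

    @property
    def n(self) -> int:
        return len(self.neurons)

    @property
    def n_edges(self) -> int:
        return len(self.pre)

    def behavioral_weights(self, clip: bool = True) -> np.ndarray:
        w = self.w_original + self.w_delta
        return np.clip(w, -1.0, 1.0) if clip else w

    def copy(self) -> "SignedNetwork":
        return SignedNetwork(list(self.neurons), self.pre.copy(), self.post.copy(),
                             self.kind.copy(), self.w_original.copy(),
                             self.w_delta.copy(), self.n_clipped)

    def reset_learning(self) -> None:
        self.w_delta[:] = 0.0

    def sign_pattern(self) -> np.ndarray:
        """Indices of inhibitory (negative original-weight) edges."""
        return np.flatnonzero(self.w_original < 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pre": [self.neurons[i] for i in self.pre],
            "post": [self.neurons[j] for j in self.post],
            "kind": list(self.kind),
            "w_original": self.w_original,
            "w_delta": self.w_delta,
        })

    def to_table(self, path: str | Path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        self.to_frame().to_csv(path, sep=sep, index=False)

    @classmethod
    def from_table(cls, path: str | Path) -> "SignedNetwork":
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        t = pd.read_csv(path, sep=sep)
        order: dict[str, int] = {}
        for a, b in zip(t["pre"].astype(str), t["post"].astype(str)):
            order.setdefault(a, len(order))
            order.setdefault(b, len(order))
        neurons = list(order)
        pre = np.array([order[a] for a in t["pre"].astype(str)], dtype=np.int64)
        post = np.array([order[b] for b in t["post"].astype(str)], dtype=np.int64)
        return cls(neurons, pre, post, t["kind"].to_numpy(dtype=object),
                   t["w_original"].to_numpy(dtype=float),
                   t["w_delta"].to_numpy(dtype=float))


@dataclass(frozen=True)
class InhibitionScheme:
    """Where and how many inhibitory (negative) edges to place.

    ``fraction`` is a fraction of the *total* edge count by default,
    even when the eligible pool is restricted to intra- or inter-cluster
    edges (``fraction_of="pool"`` switches to pool-relative semantics).
    ``couple_gap_pairs`` negates reciprocal gap edges jointly, each pair
    counting 2 toward the target.
    """

    mode: str = "uniform"           # uniform | inter_cluster | intra_cluster
    fraction: float = 0.3
    couple_gap_pairs: bool = False
    fraction_of: str = "total"      # total | pool

    def __post_init__(self) -> None:
        if self.mode not in {"uniform", "inter_cluster", "intra_cluster"}:
            raise ValueError(f"unknown inhibition mode {self.mode!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.fraction_of not in {"total", "pool"}:
            raise ValueError("fraction_of must be 'total' or 'pool'")


def _round_half_away(x: float) -> int:
    return int(np.floor(x + 0.5)) if x >= 0 else -int(np.floor(-x + 0.5))


def normalize_weights(c: Connectome, cutoff: int = 44,
                      order: str = "clip_first") -> SignedNetwork:
    """Turn multiplicities into normalized positive weights in (0, 1].

    Default (``clip_first``): ``w = min(multiplicity, cutoff) / cutoff``,
    so heavy edges land exactly at 1.  The alternative ``scale_first``
    divides by the maximum multiplicity and sets clipped edges to 1.
    The number of clipped edges (multiplicity > cutoff) is recorded on
    the returned network and logged.
    """
    if cutoff < 1:
        raise ValueError("cutoff must be >= 1")
    m = c.multiplicity.astype(float)
    clipped = int((c.multiplicity > cutoff).sum())
    if order == "clip_first":
        w = np.minimum(m, cutoff) / cutoff
    elif order == "scale_first":
        w = m / (m.max() if len(m) else 1.0)
        w[c.multiplicity > cutoff] = 1.0
    else:
        raise ValueError(f"unknown normalization order {order!r}")
    logger.info("normalized %d edges (cutoff %d): %d clipped to 1",
                c.n_edges, cutoff, clipped)
    return SignedNetwork(list(c.neurons), c.pre.copy(), c.post.copy(),
                         c.kind.copy(), w, np.zeros_like(w), clipped)


def _gap_pair_units(net: SignedNetwork, pool: np.ndarray) -> list[tuple[int, ...]]:
    """Group eligible edges into selection units, pairing reciprocal gaps."""
    pool_set = set(pool.tolist())
    units: list[tuple[int, ...]] = []
    open_gaps: dict[tuple[int, int, float], list[int]] = {}
    for e in pool.tolist():
        if net.kind[e] != GAP or net.pre[e] == net.post[e]:
            units.append((e,))
            continue
        i, j, w = int(net.pre[e]), int(net.post[e]), abs(float(net.w_original[e]))
        back = open_gaps.get((j, i, w))
        if back:
            units.append((back.pop(), e))
        else:
            open_gaps.setdefault((i, j, w), []).append(e)
    for stack in open_gaps.values():      # partner outside the pool
        units.extend((e,) for e in stack)
    assert sum(len(u) for u in units) == len(pool_set)
    return units


def assign_inhibition(net: SignedNetwork, scheme: InhibitionScheme,
                      partition: ClusterPartition | None = None,
                      seed: int | np.random.Generator = 0) -> SignedNetwork:
    """Negate a fixed number of edge weights, selected uniformly at random.

    Exactly ``k = round(fraction × M)`` edges flip sign (M = total edge
    count, or the eligible-pool size under pool semantics); magnitudes
    are untouched.  Deterministic given the seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = net.copy()
    M = out.n_edges
    if scheme.mode == "uniform":
        pool = np.arange(M)
    else:
        if partition is None:
            raise ValueError(f"{scheme.mode} inhibition requires a cluster partition")
        labels = partition.labels_for(out.neurons)
        same = labels[out.pre] == labels[out.post]
        pool = np.flatnonzero(same if scheme.mode == "intra_cluster" else ~same)
    base = M if scheme.fraction_of == "total" else len(pool)
    k = _round_half_away(scheme.fraction * base)
    if k > len(pool):
        raise CapacityError(
            f"need {k} inhibitory edges but the {scheme.mode} pool has only "
            f"{len(pool)}")
    if k == 0:
        return out
    if scheme.couple_gap_pairs:
        units = _gap_pair_units(out, pool)
        chosen: list[int] = []
        remaining = k
        for u in rng.permutation(len(units)):
            unit = units[int(u)]
            if len(unit) <= remaining:
                chosen.extend(unit)
                remaining -= len(unit)
            if remaining == 0:
                break
        if remaining:
            raise CapacityError(
                f"cannot negate exactly {k} edges with gap pairs coupled")
        idx = np.array(chosen, dtype=np.int64)
    else:
        idx = rng.choice(pool, size=k, replace=False)
    out.w_original[idx] = -out.w_original[idx]
    return out


def extract_cluster(net: SignedNetwork, partition: ClusterPartition,
                    labels: Iterable[str]) -> SignedNetwork:
    """Induced subnetwork on the neurons carrying the given cluster labels.

    Only edges with both endpoints inside survive; weights, learned
    deltas and signs carry over; neuron order is preserved.
    """
    labels = {str(l) for l in labels}
    if not labels:
        raise ValueError("labels must be nonempty")
    known = set(partition.labels)
    unknown = labels - known
    if unknown:
        raise ValueError(f"unknown cluster label(s): {', '.join(sorted(unknown))}")
    node_labels = partition.labels_for(net.neurons)
    inside = np.isin(node_labels, list(labels))
    keep_names = [n for n, m in zip(net.neurons, inside) if m]
    remap = np.full(net.n, -1, dtype=np.int64)
    remap[np.flatnonzero(inside)] = np.arange(len(keep_names))
    keep_edge = inside[net.pre] & inside[net.post]
    return SignedNetwork(keep_names, remap[net.pre[keep_edge]],
                         remap[net.post[keep_edge]], net.kind[keep_edge],
                         net.w_original[keep_edge], net.w_delta[keep_edge])
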