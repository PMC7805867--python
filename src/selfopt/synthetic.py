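"""Synthetic modular connectomes for testing every stage without real data.

The generator emulates the structural features the method relies on:
a modular directed multigraph with exact per-cluster intra-edge counts
and per-cluster-pair inter-edge counts, heavy-tailed (truncated
Zipf-like) edge multiplicities so that a clipping cutoff actually binds,
reciprocal gap-junction pairs sharing one multiplicity, and optional
self-connections.  All counts are met exactly, not in expectation, and
generation is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .connectome import CHEMICAL, GAP, ClusterPartition, Connectome
from .exceptions import CapacityError


@dataclass
class SyntheticSpec:
    """Structural recipe for one synthetic connectome.

    ``inter_edges`` is either a mapping (cluster index pair) → count of
    directed edges, or a single total distributed as evenly as possible
    over all ordered cluster pairs in lexicographic order.
    ``gap_fraction`` is the fraction of connections realized as
    reciprocal gap pairs; ``mult_exponent``/``mult_max`` parameterize
    the truncated power-law multiplicity distribution (the exponent is a
    modeling choice, not a measured value).
    """

    cluster_sizes: Sequence[int]
    intra_edges: Sequence[int]
    inter_edges: int | Mapping[tuple[int, int], int] = 0
    labels: Sequence[str] | None = None
    super_clusters: Mapping[str, frozenset] | None = None
    mult_exponent: float = 2.0
    mult_max: int = 81
    gap_fraction: float = 0.0
    self_edge_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.cluster_sizes) != len(self.intra_edges):
            raise ValueError("cluster_sizes and intra_edges must align")
        if any(s < 1 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be positive")
        for name, f in (("gap_fraction", self.gap_fraction),
                        ("self_edge_fraction", self.self_edge_fraction)):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mult_max < 1:
            raise ValueError("mult_max must be >= 1")


def _sample_multiplicities(rng: np.random.Generator, size: int,
                           exponent: float, mult_max: int) -> np.ndarray:
    k = np.arange(1, mult_max + 1, dtype=float)
    p = k ** -exponent
    p /= p.sum()
    return rng.choice(np.arange(1, mult_max + 1), size=size, p=p)


def _decode_unordered(idx: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    # idx enumerates pairs (i<j) of range(m) in row-major order
    i = np.zeros_like(idx)
    j = np.zeros_like(idx)
    for t, x in enumerate(idx):
        a = 0
        row = m - 1
        x = int(x)
        while x >= row:
            x -= row
            a += 1
            row -= 1
        i[t] = a
        j[t] = a + 1 + x
    return i, j


def _decode_ordered(idx: np.ndarray, m: int) -> tuple[np.ndarray, np.ndarray]:
    # idx enumerates ordered pairs (i != j) of range(m)
    i = idx // (m - 1)
    j = idx % (m - 1)
    j = j + (j >= i)
    return i, j


def _inter_counts(spec: SyntheticSpec) -> dict[tuple[int, int], int]:
    K = len(spec.cluster_sizes)
    pairs = [(a, b) for a in range(K) for b in range(K) if a != b]
    if isinstance(spec.inter_edges, Mapping):
        counts = {p: 0 for p in pairs}
        for p, c in spec.inter_edges.items():
            if tuple(p) not in counts:
                raise ValueError(f"bad cluster pair {p!r}")
            counts[tuple(p)] = int(c)
        return counts
    total = int(spec.inter_edges)
    if total and K < 2:
        raise CapacityError("inter-cluster edges need at least two clusters")
    counts = {p: 0 for p in pairs}
    if pairs:
        base, rem = divmod(total, len(pairs))
        for t, p in enumerate(pairs):
            counts[p] = base + (1 if t < rem else 0)
    return counts


def generate(spec: SyntheticSpec) -> tuple[Connectome, ClusterPartition]:
    """Build a connectome and matching partition from a structural spec.

    Every count (nodes per cluster, intra edges per cluster, inter edges
    per cluster pair) is realized exactly; unrealizable requests raise
    :class:`CapacityError`.
    """
    rng = np.random.default_rng(spec.seed)
    K = len(spec.cluster_sizes)
    labels = ([str(l) for l in spec.labels] if spec.labels is not None
              else [f"c{i + 1}" for i in range(K)])
    offsets = np.concatenate([[0], np.cumsum(spec.cluster_sizes)])
    neurons = [f"{labels[c]}_{j:03d}" for c in range(K)
               for j in range(spec.cluster_sizes[c])]

    pre: list[int] = []
    post: list[int] = []
    kind: list[str] = []
    mult: list[int] = []

    def add_gap_pair(i: int, j: int, m: int) -> None:
        pre.extend((i, j)); post.extend((j, i)); kind.extend((GAP, GAP))
        mult.extend((m, m))

    def add_chem(i: np.ndarray, j: np.ndarray, m: np.ndarray) -> None:
        pre.extend(int(x) for x in i)
        post.extend(int(x) for x in j)
        kind.extend(CHEMICAL for _ in i)
        mult.extend(int(x) for x in m)

    for c in range(K):
        m_sz, E, o = spec.cluster_sizes[c], int(spec.intra_edges[c]), int(offsets[c])
        n_self = min(int(round(spec.self_edge_fraction * E)), m_sz, E)
        rem = E - n_self
        n_gap = int(np.floor(spec.gap_fraction * rem / 2))
        n_chem = rem - 2 * n_gap
        if spec.gap_fraction == 1.0 and n_chem > 0:
            raise CapacityError(
                f"cluster {labels[c]}: {rem} non-self edges cannot be fully "
                f"paired into gap junctions")
        n_unordered = m_sz * (m_sz - 1) // 2
        n_ordered = m_sz * (m_sz - 1)
        if n_gap > n_unordered or n_chem > n_ordered:
            raise CapacityError(
                f"cluster {labels[c]} (size {m_sz}) cannot host {E} intra edges "
                f"with gap_fraction {spec.gap_fraction}")
        if n_gap:
            gi, gj = _decode_unordered(
                rng.choice(n_unordered, size=n_gap, replace=False), m_sz)
            for a, b, w in zip(gi, gj, _sample_multiplicities(
                    rng, n_gap, spec.mult_exponent, spec.mult_max)):
                add_gap_pair(o + int(a), o + int(b), int(w))
        if n_chem:
            ci, cj = _decode_ordered(
                rng.choice(n_ordered, size=n_chem, replace=False), m_sz)
            add_chem(o + ci, o + cj, _sample_multiplicities(
                rng, n_chem, spec.mult_exponent, spec.mult_max))
        if n_self:
            nodes = rng.choice(m_sz, size=n_self, replace=False)
            add_chem(o + nodes, o + nodes, _sample_multiplicities(
                rng, n_self, spec.mult_exponent, spec.mult_max))

    counts = _inter_counts(spec)
    for a in range(K):
        for b in range(a + 1, K):
            c_ab, c_ba = counts.get((a, b), 0), counts.get((b, a), 0)
            sa, sb = spec.cluster_sizes[a], spec.cluster_sizes[b]
            cap = sa * sb
            g = int(np.floor(spec.gap_fraction * (c_ab + c_ba) / 2))
            g = min(g, c_ab, c_ba, cap)
            if spec.gap_fraction == 1.0 and (c_ab - g or c_ba - g):
                raise CapacityError(
                    f"inter-cluster counts {c_ab}/{c_ba} between {labels[a]} and "
                    f"{labels[b]} cannot be fully paired into gap junctions")
            if c_ab - g > cap or c_ba - g > cap:
                raise CapacityError(
                    f"too many inter-cluster edges between {labels[a]} "
                    f"({sa} nodes) and {labels[b]} ({sb} nodes)")
            oa, ob = int(offsets[a]), int(offsets[b])
            if g:
                idx = rng.choice(cap, size=g, replace=False)
                gi, gj = idx // sb, idx % sb
                for x, y, w in zip(gi, gj, _sample_multiplicities(
                        rng, g, spec.mult_exponent, spec.mult_max)):
                    add_gap_pair(oa + int(x), ob + int(y), int(w))
            for (src_o, dst_o, src_n, dst_n, cnt) in (
                    (oa, ob, sa, sb, c_ab - g), (ob, oa, sb, sa, c_ba - g)):
                if cnt:
                    idx = rng.choice(src_n * dst_n, size=cnt, replace=False)
                    add_chem(src_o + idx // dst_n, dst_o + idx % dst_n,
                             _sample_multiplicities(rng, cnt, spec.mult_exponent,
                                                    spec.mult_max))

    connectome = Connectome(neurons, np.array(pre), np.array(post),
                            np.array(kind, dtype=object), np.array(mult))
    connectome.validate()
    assignment = {f"{labels[c]}_{j:03d}": labels[c] for c in range(K)
                  for j in range(spec.cluster_sizes[c])}
    supers = ({k: frozenset(v) for k, v in spec.super_clusters.items()}
              if spec.super_clusters else {})
    partition = ClusterPartition(assignment, supers)
    if not supers:
        partition = partition.derive_hierarchy()
    return connectome, partition


#: Structural spec mirroring the reference five-cluster connectome shape
#: (node and edge counts only; names, multiplicity law and gap placement
#: are synthetic).
TABLE1_SHAPE_SPEC = SyntheticSpec(
    cluster_sizes=(57, 79, 14, 74, 55),
    intra_edges=(665, 1107, 115, 1109, 396),
    inter_edges=2196,
    labels=("11", "12", "13", "21", "22"),
    super_clusters={"1": frozenset({"11", "12", "13"}),
                    "2": frozenset({"21", "22"})},
    mult_exponent=2.0,
    mult_max=81,
    gap_fraction=0.3,
    self_edge_fraction=0.01,
    seed=2020,
)


def make_fixture(name: str) -> tuple[Connectome, ClusterPartition]:
    """Deterministic small instances shared across the test suite.

    Presets: ``tiny_symmetric`` (4 nodes, all-positive symmetric,
    attractors are the two uniform states), ``frustrated_triangle``
    (3 nodes, symmetric couplings; negate one pair to frustrate it),
    ``two_cluster_small`` (8 nodes, 2 clusters, known intra/inter
    counts) and ``table1_shape`` (reference-scale modular multigraph).
    """
    if name == "tiny_symmetric":
        nodes = ["A", "B", "C", "D"]
        pre, post = [], []
        for i in range(4):
            for j in range(i + 1, 4):
                pre.extend((i, j)); post.extend((j, i))
        c = Connectome(nodes, np.array(pre), np.array(post),
                       np.array([GAP] * len(pre), dtype=object),
                       np.ones(len(pre), dtype=np.int64))
        return c, ClusterPartition.trivial(nodes)
    if name == "frustrated_triangle":
        nodes = ["A", "B", "C"]
        pre = [0, 1, 1, 2, 2, 0]
        post = [1, 0, 2, 1, 0, 2]
        c = Connectome(nodes, np.array(pre), np.array(post),
                       np.array([GAP] * 6, dtype=object),
                       np.ones(6, dtype=np.int64))
        return c, ClusterPartition.trivial(nodes)
    if name == "two_cluster_small":
        return generate(SyntheticSpec(cluster_sizes=(4, 4), intra_edges=(6, 6),
                                      inter_edges=4, mult_max=3, seed=7))
    if name == "table1_shape":
        return generate(TABLE1_SHAPE_SPEC)
    raise ValueError(f"unknown fixture preset {name!r}")
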