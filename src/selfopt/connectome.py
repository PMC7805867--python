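"""Connectome edge tables, cluster partitions, and graph statistics.

A wiring diagram is represented as a directed multigraph.  Chemical
synapses are single directed edges from the presynaptic to the
postsynaptic neuron; gap junctions (electrical couplings) appear as a
reciprocal pair of directed edges with equal multiplicity.  The
multiplicity of an edge counts the individual contacts between the two
neurons and later becomes the (normalized) edge weight.

Edge tables are plain delimited text (CSV or TSV, autodetected from the
file extension).  Column names and the gap-junction storage convention
vary between published layouts, so both are configurable through
:class:`EdgeTableDialect`.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import ConsistencyError, CoverageError, FormatError

logger = logging.getLogger(__name__)

CHEMICAL = "chemical"
GAP = "gap"


@dataclass(frozen=True)
class EdgeTableDialect:
    """Column names and storage conventions of a connectome edge table.

    ``gap_stored_once`` — if true, each gap junction occupies a single
    (undirected) row that is expanded into the reciprocal directed pair
    on load; if false, the table stores both directions explicitly and
    they are validated for reciprocity.
    """

    pre: str = "pre"
    post: str = "post"
    kind: str = "type"
    multiplicity: str = "count"
    chemical_value: str = CHEMICAL
    gap_value: str = GAP
    gap_stored_once: bool = True


DEFAULT_DIALECT = EdgeTableDialect()


@dataclass
class Connectome:
    """Directed multigraph of neurons and their connections.

    ``neurons`` is an ordered list of unique names; edges reference
    neurons by index.  Gap edges always come in reciprocal pairs of
    equal multiplicity.  Self-connections are allowed.
    """

    neurons: list[str]
    pre: np.ndarray
    post: np.ndarray
    kind: np.ndarray
    multiplicity: np.ndarray

    def __post_init__(self) -> None:
        self.pre = np.asarray(self.pre, dtype=np.int64)
        self.post = np.asarray(self.post, dtype=np.int64)
        self.kind = np.asarray(self.kind, dtype=object)
        self.multiplicity = np.asarray(self.multiplicity, dtype=np.int64)

    @property
    def n_neurons(self) -> int:
        return len(self.neurons)

    @property
    def n_edges(self) -> int:
        return len(self.pre)

    @property
    def index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.neurons)}

    def validate(self) -> None:
        """Check structural invariants; raise on violation."""
        n = self.n_neurons
        if self.n_edges and (self.pre.min() < 0 or self.pre.max() >= n
                             or self.post.min() < 0 or self.post.max() >= n):
            raise ConsistencyError("edge endpoint index out of range")
        if self.n_edges and self.multiplicity.min() < 1:
            raise FormatError("edge multiplicities must be >= 1")
        gap = self.kind == GAP
        fwd = Counter(zip(self.pre[gap].tolist(), self.post[gap].tolist(),
                          self.multiplicity[gap].tolist()))
        for (i, j, m), c in fwd.items():
            if fwd[(j, i, m)] != c:
                a, b = self.neurons[i], self.neurons[j]
                raise ConsistencyError(
                    f"gap edge {a}->{b} (multiplicity {m}) lacks a reciprocal "
                    f"partner of equal multiplicity")

    def _edge_multiset(self) -> Counter:
        return Counter(
            (self.neurons[i], self.neurons[j], k, int(m))
            for i, j, k, m in zip(self.pre, self.post, self.kind, self.multiplicity)
        )

    def __eq__(self, other: object) -> bool:
        # Equality is by neuron *set* and named edge multiset: an edge
        # table cannot encode first-appearance order, so round-tripped
        # connectomes compare equal even if the index order moved.
        if not isinstance(other, Connectome):
            return NotImplemented
        return (set(self.neurons) == set(other.neurons)
                and self._edge_multiset() == other._edge_multiset())

    def to_frame(self, dialect: EdgeTableDialect = DEFAULT_DIALECT) -> pd.DataFrame:
        """Serialize to an edge table in the given dialect.

        With ``gap_stored_once`` each reciprocal gap pair is written as a
        single row (the direction with the lower neuron index).
        """
        rows = []
        gap_budget: Counter = Counter()
        for i, j, k, m in zip(self.pre, self.post, self.kind, self.multiplicity):
            if k == GAP and dialect.gap_stored_once:
                key = (min(i, j), max(i, j), int(m))
                if gap_budget[key] > 0:       # twin already written
                    gap_budget[key] -= 1
                    continue
                gap_budget[key] += 1
            value = dialect.gap_value if k == GAP else dialect.chemical_value
            rows.append((self.neurons[i], self.neurons[j], value, int(m)))
        return pd.DataFrame(
            rows, columns=[dialect.pre, dialect.post, dialect.kind,
                           dialect.multiplicity])

    def to_table(self, path: str | Path,
                 dialect: EdgeTableDialect = DEFAULT_DIALECT) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        self.to_frame(dialect).to_csv(path, sep=sep, index=False)


@dataclass
class ClusterPartition:
    """Assignment of neurons to functional clusters.

    ``super_clusters`` optionally groups cluster labels into hierarchical
    super-clusters (for the reference partition: ``{"1": {"11", "12",
    "13"}, "2": {"21", "22"}}``).
    """

    assignment: dict[str, str]
    super_clusters: dict[str, frozenset[str]] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for v in self.assignment.values():
            seen.setdefault(v)
        return list(seen)

    def sizes(self) -> dict[str, int]:
        out = Counter(self.assignment.values())
        return dict(out)

    def labels_for(self, neurons: Sequence[str]) -> np.ndarray:
        missing = [n for n in neurons if n not in self.assignment]
        if missing:
            raise CoverageError(
                f"partition does not cover {len(missing)} neuron(s): "
                + ", ".join(missing[:10]) + ("..." if len(missing) > 10 else ""))
        return np.array([self.assignment[n] for n in neurons], dtype=object)

    def restrict(self, neurons: Iterable[str]) -> "ClusterPartition":
        sub = {n: self.assignment[n] for n in neurons}
        kept = set(sub.values())
        supers = {s: frozenset(ls & kept) for s, ls in self.super_clusters.items()
                  if ls & kept}
        return ClusterPartition(sub, supers)

    @classmethod
    def trivial(cls, neurons: Iterable[str], label: str = "0") -> "ClusterPartition":
        return cls({n: label for n in neurons})

    def to_frame(self) -> pd.DataFrame:
        label_super = {l: s for s, ls in self.super_clusters.items() for l in ls}
        rows = [(n, c, label_super.get(c, c)) for n, c in self.assignment.items()]
        return pd.DataFrame(rows, columns=["neuron", "cluster", "super"])

    def to_table(self, path: str | Path) -> None:
        path = Path(path)
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        self.to_frame().to_csv(path, sep=sep, index=False)

    def derive_hierarchy(self) -> "ClusterPartition":
        """Group labels by their leading character into super-clusters.

        Matches the reference convention where label "11" belongs to
        super-cluster "1".  Only applies when every label has >= 2
        characters; otherwise each label forms its own super-cluster.
        """
        labels = self.labels
        supers: dict[str, set[str]] = {}
        if all(len(str(l)) >= 2 for l in labels):
            for l in labels:
                supers.setdefault(str(l)[0], set()).add(l)
        else:
            for l in labels:
                supers.setdefault(str(l), set()).add(l)
        return replace(self, super_clusters={k: frozenset(v) for k, v in supers.items()})


@dataclass
class GraphStats:
    """Node/edge counts and path statistics of a connectome multigraph."""

    n_nodes: int
    n_edges: int
    n_intra: int | None
    n_inter: int | None
    avg_out_degree: float
    avg_shortest_path: float

    def to_dict(self) -> dict:
        return {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "n_intra": self.n_intra,
            "n_inter": self.n_inter,
            "avg_out_degree": self.avg_out_degree,
            "avg_shortest_path": self.avg_shortest_path,
        }


def _read_table(source: str | Path | pd.DataFrame) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    path = Path(source)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep, comment="#")


def load_connectome(source: str | Path | pd.DataFrame,
                    dialect: EdgeTableDialect = DEFAULT_DIALECT) -> Connectome:
    """Parse a delimited edge table into a :class:`Connectome`.

    Chemical rows become one directed edge each.  Gap-junction rows are
    expanded into the reciprocal directed pair when the dialect stores
    them once, or validated as reciprocal when stored twice.
    """
    table = _read_table(source)
    required = [dialect.pre, dialect.post, dialect.kind, dialect.multiplicity]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise FormatError(f"edge table is missing column(s): {', '.join(missing)}")

    mult = table[dialect.multiplicity]
    numeric = pd.to_numeric(mult, errors="coerce")
    bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"row {row}: multiplicity {mult.iloc[row]!r} is not a positive integer")

    kinds = table[dialect.kind].astype(str)
    known = {dialect.chemical_value, dialect.gap_value}
    unknown = ~kinds.isin(known)
    if unknown.any():
        row = int(np.flatnonzero(unknown.to_numpy())[0])
        raise FormatError(
            f"row {row}: connection type {kinds.iloc[row]!r} not in {sorted(known)}")

    pre_names = table[dialect.pre].astype(str).tolist()
    post_names = table[dialect.post].astype(str).tolist()
    order: dict[str, int] = {}
    for a, b in zip(pre_names, post_names):
        order.setdefault(a, len(order))
        order.setdefault(b, len(order))
    neurons = list(order)

    pre, post, kind, mults = [], [], [], []
    counts = numeric.astype(int).tolist()
    for a, b, k, m in zip(pre_names, post_names, kinds.tolist(), counts):
        i, j = order[a], order[b]
        if k == dialect.gap_value:
            pre.append(i); post.append(j); kind.append(GAP); mults.append(m)
            if dialect.gap_stored_once and i != j:
                pre.append(j); post.append(i); kind.append(GAP); mults.append(m)
        else:
            pre.append(i); post.append(j); kind.append(CHEMICAL); mults.append(m)

    c = Connectome(neurons, np.array(pre, dtype=np.int64),
                   np.array(post, dtype=np.int64),
                   np.array(kind, dtype=object),
                   np.array(mults, dtype=np.int64))
    c.validate()
    logger.info("loaded connectome: %d neurons, %d directed edges",
                c.n_neurons, c.n_edges)
    return c


def filter_neurons(c: Connectome, exclude: Iterable[str]) -> Connectome:
    """Remove neurons (and all incident edges), preserving the order of the rest.

    Names not present in the connectome are ignored with a warning.
    """
    exclude = set(exclude)
    present = set(c.neurons)
    absent = exclude - present
    if absent:
        logger.warning("excluded neurons not found in connectome: %s",
                       ", ".join(sorted(absent)))
    keep_names = [n for n in c.neurons if n not in exclude]
    if len(keep_names) == len(c.neurons):
        return Connectome(list(c.neurons), c.pre.copy(), c.post.copy(),
                          c.kind.copy(), c.multiplicity.copy())
    remap = {c.index[n]: i for i, n in enumerate(keep_names)}
    keep_edge = np.array([i in remap and j in remap
                          for i, j in zip(c.pre, c.post)], dtype=bool)
    pre = np.array([remap[i] for i in c.pre[keep_edge]], dtype=np.int64)
    post = np.array([remap[j] for j in c.post[keep_edge]], dtype=np.int64)
    return Connectome(keep_names, pre, post, c.kind[keep_edge],
                      c.multiplicity[keep_edge])


def load_exclusions(source: str | Path | None = None) -> set[str]:
    """Read an exclusion list (one neuron name per line, ``#`` comments).

    With no argument, returns the packaged default: the pharyngeal
    neurons (a separate, nearly independent neural system) plus VC6,
    CANR and CANL, which lack obvious connections.
    """
    if source is None:
        text = (resources.files("selfopt.data") / "default_exclusions.txt").read_text()
    else:
        text = Path(source).read_text()
    names = set()
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            names.add(line)
    return names


def load_partition(source: str | Path | pd.DataFrame) -> ClusterPartition:
    """Parse a neuron→cluster table (columns ``neuron``, ``cluster``, and
    optionally a third super-cluster column)."""
    table = _read_table(source)
    if table.empty and table.shape[1] == 0:
        return ClusterPartition({})
    cols = list(table.columns)
    if len(cols) < 2:
        raise FormatError("partition table needs columns: neuron, cluster")
    neuron_col, cluster_col = cols[0], cols[1]
    if "neuron" in cols:
        neuron_col = "neuron"
    if "cluster" in cols:
        cluster_col = "cluster"
    assignment: dict[str, str] = {}
    for row, (n, c) in enumerate(zip(table[neuron_col].astype(str),
                                     table[cluster_col].astype(str))):
        if n in assignment and assignment[n] != c:
            raise ConsistencyError(
                f"row {row}: neuron {n!r} assigned to both "
                f"{assignment[n]!r} and {c!r}")
        assignment[n] = c
    part = ClusterPartition(assignment)
    extra = [c for c in cols if c not in (neuron_col, cluster_col)]
    if extra:
        supers: dict[str, set[str]] = {}
        for c, s in zip(table[cluster_col].astype(str), table[extra[0]].astype(str)):
            supers.setdefault(s, set()).add(c)
        part.super_clusters = {k: frozenset(v) for k, v in supers.items()}
    return part


def graph_stats(c: Connectome, p: ClusterPartition | None = None) -> GraphStats:
    """Table-style statistics of the multigraph.

    Parallel edges count individually toward ``n_edges``; the average
    shortest path is computed on the simple directed graph (parallel
    edges collapsed), unweighted, averaged over ordered reachable pairs
    only.  With no reachable pair the value is NaN.
    """
    n_intra = n_inter = None
    if p is not None:
        labels = p.labels_for(c.neurons)
        if c.n_edges:
            same = labels[c.pre] == labels[c.post]
            n_intra, n_inter = int(same.sum()), int((~same).sum())
        else:
            n_intra = n_inter = 0
    G = nx.DiGraph()
    G.add_nodes_from(range(c.n_neurons))
    G.add_edges_from(zip(c.pre.tolist(), c.post.tolist()))
    total = pairs = 0
    for src, lengths in nx.all_pairs_shortest_path_length(G):
        for dst, d in lengths.items():
            if dst != src:
                total += d
                pairs += 1
    asp = total / pairs if pairs else float("nan")
    deg = c.n_edges / c.n_neurons if c.n_neurons else float("nan")
    return GraphStats(c.n_neurons, c.n_edges, n_intra, n_inter, deg, asp)
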