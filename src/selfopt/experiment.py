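"""Three-phase reset–convergence protocol with replicate averaging.

One *reset–convergence cycle* is: draw a fresh random ±1 state, relax it
by asynchronous updates, record the constraint-satisfaction energy of
the final state against the original weights (whole network and any
monitored cluster scopes), and — in the learning phase only — reinforce
the final state Hebbianly.

The full protocol runs three phases of cycles (before / learn / after,
1,000 each by default): the flanking phases probe the attractor
landscape without changing weights, so comparing their energy
distributions measures how much the learned layer has reshaped the
dynamics toward states that satisfy the *original* constraints better —
the self-optimization effect.  Everything is replicated over a list of
seeds and is fully deterministic given that list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import ClusterPartition, Connectome
from .dynamics import (INTER, _relax_matrix, _scope_mask, _violations,
                       aggregate_matrix, energy, random_state)
from .learning import LearningConfig, hebbian_step
from .network import InhibitionScheme, SignedNetwork, assign_inhibition, normalize_weights

PHASES = ("before", "learn", "after")


@dataclass
class ProtocolConfig:
    """Everything that defines one experiment.

    ``cycles`` are the per-phase cycle counts (before, learn, after);
    ``updates_per_neuron`` sets the relaxation budget per cycle at
    ``updates_per_neuron × n`` random single-neuron updates; ``scopes``
    lists extra monitored scopes as (name, label-set-or-INTER) pairs —
    the whole network is always monitored under the name "whole".
    ``redraw_inhibition`` redraws the inhibitory sign pattern for every
    replicate seed (otherwise all replicates share the first draw).
    """

    cycles: tuple[int, int, int] = (1000, 1000, 1000)
    updates_per_neuron: int = 10
    learning: LearningConfig = field(default_factory=LearningConfig)
    inhibition: InhibitionScheme | None = None
    seeds: Sequence[int] = tuple(range(10))
    scopes: Sequence[tuple[str, object]] = ()
    redraw_inhibition: bool = True
    store_states: bool = False
    all_positive_first_state: bool = False

    def __post_init__(self) -> None:
        if len(self.cycles) != 3 or any(c < 0 for c in self.cycles):
            raise ValueError("cycles must be three non-negative counts")
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replicate seeds must be distinct")
        if self.updates_per_neuron < 0:
            raise ValueError("updates_per_neuron must be >= 0")


def default_cluster_scopes(partition: ClusterPartition,
                           include_inter: bool = True) -> list[tuple[str, object]]:
    """Per-cluster scopes, hierarchical super-cluster scopes, and the
    inter-cluster edge scope, in a stable order."""
    scopes: list[tuple[str, object]] = [(l, frozenset({l}))
                                        for l in sorted(partition.labels)]
    for name in sorted(partition.super_clusters):
        members = partition.super_clusters[name]
        if len(members) > 1:
            scopes.append(("+".join(sorted(members)), frozenset(members)))
    if include_inter:
        scopes.append(("inter", INTER))
    return scopes


@dataclass
class ExperimentTrace:
    """Per-cycle energies for every replicate, phase and monitored scope.

    ``frame`` has one row per replicate × cycle × scope with columns
    replicate, seed, cycle, phase, scope, energy, is_fixed_point.
    ``states`` (optional) holds the final relaxed state of every cycle.
    """

    frame: pd.DataFrame
    phase_lengths: tuple[int, int, int]
    scope_names: list[str]
    seeds: tuple
    states: pd.DataFrame | None = None

    def aggregate(self) -> pd.DataFrame:
        """Per-cycle mean and SD of energy over replicates, per scope."""
        g = self.frame.groupby(["scope", "cycle"])["energy"]
        out = g.agg(mean="mean", sd=lambda x: float(np.std(x))).reset_index()
        phase = np.empty(len(out), dtype=object)
        bounds = np.cumsum(self.phase_lengths)
        for i, c in enumerate(out["cycle"]):
            phase[i] = PHASES[int(np.searchsorted(bounds, c, side="right"))]
        out["phase"] = phase
        return out

    def phase_summary(self, phase: str, scope: str = "whole",
                      over: str = "all") -> tuple[float, float]:
        """Mean and population SD of energies in one phase for one scope.

        ``over`` chooses the reduction: "all" pools every cycle ×
        replicate value; "replicates" summarizes per-replicate means;
        "cycles" summarizes per-cycle (replicate-averaged) means.
        """
        sel = self.frame[(self.frame["phase"] == phase)
                         & (self.frame["scope"] == scope)]
        if sel.empty:
            raise ValueError(f"no cycles recorded for phase {phase!r}, "
                             f"scope {scope!r}")
        if over == "replicates":
            vals = sel.groupby("replicate")["energy"].mean().to_numpy()
        elif over == "cycles":
            vals = sel.groupby("cycle")["energy"].mean().to_numpy()
        elif over == "all":
            vals = sel["energy"].to_numpy()
        else:
            raise ValueError(f"unknown reduction {over!r}")
        return float(np.mean(vals)), float(np.std(vals))

    def summary_table(self) -> pd.DataFrame:
        rows = []
        for scope in self.scope_names:
            for phase, length in zip(PHASES, self.phase_lengths):
                if length == 0:
                    continue
                mean, sd = self.phase_summary(phase, scope)
                rows.append((scope, phase, mean, sd))
        return pd.DataFrame(rows, columns=["scope", "phase", "mean", "sd"])

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def phase_summary(trace: ExperimentTrace, phase: str, scope: str = "whole",
                  over: str = "all") -> tuple[float, float]:
    return trace.phase_summary(phase, scope, over)


def _as_network(source: Connectome | SignedNetwork, cutoff: int = 44) -> SignedNetwork:
    if isinstance(source, Connectome):
        return normalize_weights(source, cutoff)
    return source.copy()


def run_cycle(net: SignedNetwork, cfg: ProtocolConfig, phase: str,
              rng: int | np.random.Generator,
              partition: ClusterPartition | None = None) -> dict[str, dict]:
    """One reset–convergence cycle; mutates ``net`` iff phase == "learn".

    Returns, per monitored scope, the original-weight energy of the
    final state, the fixed-point flag, and the state itself.
    """
    if phase not in PHASES:
        raise ValueError(f"unknown phase {phase!r}")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    s = random_state(net.n, rng)
    A = aggregate_matrix(net, use_behavioral=True, clip=cfg.learning.clip_behavioral)
    _relax_matrix(A, s, rng.integers(0, net.n, cfg.updates_per_neuron * net.n).tolist())
    fp = bool(not _violations(A, s).any())
    records = {}
    for name, scope in [("whole", None), *cfg.scopes]:
        records[name] = {"energy": energy(net, s, scope, partition),
                         "is_fixed_point": fp, "state": s.copy()}
    if phase == "learn":
        hebbian_step(net, s, cfg.learning)
    return records


def run_experiment(source: Connectome | SignedNetwork,
                   partition: ClusterPartition | None,
                   cfg: ProtocolConfig) -> ExperimentTrace:
    """Run the three-phase protocol for every replicate seed.

    Per replicate: (re)draw the inhibitory sign pattern, zero the
    learned layer, and run the before/learn/after phases, recording the
    original-weight energy of every cycle's final state for the whole
    network and each monitored scope.
    """
    base = _as_network(source)
    monitors = [("whole", None), *cfg.scopes]
    scope_idx = []
    for name, scope in monitors:
        m = _scope_mask(base, scope, partition)
        idx = np.arange(base.n_edges) if isinstance(m, slice) else np.flatnonzero(m)
        scope_idx.append((name, idx))

    total = sum(cfg.cycles)
    n_scope = len(monitors)
    reps, seeds_col, cycles_col, phases_col = [], [], [], []
    scopes_col, energies, fps = [], [], []
    state_rows = []

    first_sign_seed = None
    for rep, seed in enumerate(cfg.seeds):
        dyn_ss, sign_ss = np.random.SeedSequence(seed).spawn(2)
        rng = np.random.default_rng(dyn_ss)
        net = base.copy()
        net.reset_learning()
        if cfg.inhibition is not None:
            if cfg.redraw_inhibition or first_sign_seed is None:
                sign_rng = np.random.default_rng(sign_ss)
                if first_sign_seed is None:
                    first_sign_seed = sign_ss
            else:
                sign_rng = np.random.default_rng(first_sign_seed)
            net = assign_inhibition(net, cfg.inhibition, partition, sign_rng)
        w_o = net.w_original
        n = net.n
        n_upd = cfg.updates_per_neuron * n
        A = aggregate_matrix(net, clip=cfg.learning.clip_behavioral)
        cycle = 0
        for phase, length in zip(PHASES, cfg.cycles):
            for _ in range(length):
                if cycle == 0 and cfg.all_positive_first_state:
                    s = np.ones(n)
                else:
                    s = random_state(n, rng)
                _relax_matrix(A, s, rng.integers(0, n, n_upd).tolist())
                fp = bool(not _violations(A, s).any())
                prod = s[net.pre] * s[net.post]
                for name, idx in scope_idx:
                    reps.append(rep)
                    seeds_col.append(seed)
                    cycles_col.append(cycle)
                    phases_col.append(phase)
                    scopes_col.append(name)
                    energies.append(float(-(w_o[idx] * prod[idx]).sum()))
                    fps.append(fp)
                if cfg.store_states:
                    state_rows.append((rep, cycle, phase, s.astype(np.int8)))
                if phase == "learn":
                    hebbian_step(net, s, cfg.learning)
                    A = aggregate_matrix(net, clip=cfg.learning.clip_behavioral)
                cycle += 1
        assert cycle == total

    frame = pd.DataFrame({
        "replicate": np.array(reps, dtype=np.int64),
        "seed": np.array(seeds_col, dtype=np.int64),
        "cycle": np.array(cycles_col, dtype=np.int64),
        "phase": pd.Categorical(phases_col, categories=list(PHASES)),
        "scope": scopes_col,
        "energy": np.array(energies),
        "is_fixed_point": np.array(fps, dtype=bool),
    })
    states = None
    if cfg.store_states:
        states = pd.DataFrame(state_rows,
                              columns=["replicate", "cycle", "phase", "state"])
    assert len(frame) == total * n_scope * len(cfg.seeds)
    return ExperimentTrace(frame, tuple(cfg.cycles), [n for n, _ in scope_idx],
                           tuple(cfg.seeds), states)


def attractor_census(trace: ExperimentTrace,
                     net: SignedNetwork | None = None) -> pd.DataFrame:
    """Group identical final states across all cycles and replicates.

    Reports each distinct state's visit count, its original-weight
    energy (when a network is supplied), the phases it appeared in, and
    whether it was *previously unseen* — absent from the before-phase
    set, the signature of generalization to new attractors.
    """
    if trace.states is None:
        raise ValueError("final states were not stored; set store_states=True")
    groups: dict[bytes, dict] = {}
    for _, row in trace.states.iterrows():
        key = row["state"].tobytes()
        g = groups.setdefault(key, {"state": row["state"], "count": 0,
                                    "phases": set()})
        g["count"] += 1
        g["phases"].add(str(row["phase"]))
    before = {k for k, g in groups.items() if "before" in g["phases"]}
    rows = []
    for key, g in groups.items():
        s = g["state"].astype(np.float64)
        e = energy(net, s) if net is not None else float("nan")
        rows.append((tuple(int(v) for v in g["state"]), g["count"], e,
                     ",".join(sorted(g["phases"])), key not in before))
    out = pd.DataFrame(rows, columns=["state", "count", "energy", "phases",
                                      "previously_unseen"])
    return out.sort_values(["count", "energy"],
                           ascending=[False, True]).reset_index(drop=True)
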