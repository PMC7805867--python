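"""Model/Results front end for the self-optimization protocol.

:class:`SelfOptimization` bundles a connectome, a cluster partition and
a protocol configuration; :meth:`SelfOptimization.fit` runs the
replicated three-phase experiment and returns a
:class:`SelfOptimizationResults` carrying the trace, phase summaries, a
``summary()`` table, the attractor census and simple trace plots.

    >>> from selfopt import SelfOptimization, make_fixture
    >>> c, p = make_fixture("two_cluster_small")
    >>> res = SelfOptimization(c, p, rate=1e-3, cycles=(50, 50, 50),
    ...                        cutoff=3).fit(seeds=range(5))
    >>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .connectome import (DEFAULT_DIALECT, ClusterPartition, Connectome,
                         EdgeTableDialect, filter_neurons, graph_stats,
                         load_connectome, load_exclusions, load_partition)
from .experiment import (ExperimentTrace, ProtocolConfig, attractor_census,
                         default_cluster_scopes, run_experiment)
from .learning import LearningConfig
from .network import InhibitionScheme, SignedNetwork, normalize_weights


class SelfOptimization:
    """Self-optimization of Hopfield dynamics on a connectome multigraph.

    Parameters
    ----------
    connectome : Connectome or SignedNetwork
        The wiring multigraph.  A raw :class:`Connectome` is normalized
        with the given ``cutoff``; a prebuilt :class:`SignedNetwork` is
        used as-is.
    partition : ClusterPartition, optional
        Cluster assignment; required for cluster-restricted inhibition
        and per-cluster energy monitoring.
    inhibition : InhibitionScheme or str, optional
        ``"uniform"``, ``"inter_cluster"``, ``"intra_cluster"`` (30% of
        all edges), a full scheme, or None for all-excitatory weights.
    rate : float
        Hebbian learning rate (per edge, per cycle).
    scopes : "clusters" | list[(name, labels-or-"inter")] | None
        Monitored energy scopes besides the whole network.  The default
        monitors every cluster, every hierarchical super-cluster and the
        inter-cluster edges when a partition is supplied.
    """

    def __init__(self, connectome: Connectome | SignedNetwork,
                 partition: ClusterPartition | None = None, *,
                 inhibition: InhibitionScheme | str | None = None,
                 rate: float = 1e-5, clip_behavioral: bool = True,
                 cycles: tuple[int, int, int] = (1000, 1000, 1000),
                 updates_per_neuron: int = 10,
                 scopes: str | Sequence | None = "clusters",
                 cutoff: int = 44, redraw_inhibition: bool = True,
                 store_states: bool = False,
                 all_positive_first_state: bool = False,
                 seeds: Sequence[int] = tuple(range(10))):
        self.connectome = connectome if isinstance(connectome, Connectome) else None
        self.partition = partition
        if isinstance(connectome, Connectome):
            self.network = normalize_weights(connectome, cutoff)
        else:
            self.network = connectome
        if isinstance(inhibition, str):
            inhibition = InhibitionScheme(mode=inhibition, fraction=0.3)
        if scopes == "clusters":
            scope_list = (default_cluster_scopes(partition)
                          if partition is not None else [])
        elif scopes is None:
            scope_list = []
        else:
            scope_list = list(scopes)
        self.config = ProtocolConfig(
            cycles=tuple(cycles), updates_per_neuron=updates_per_neuron,
            learning=LearningConfig(rate, clip_behavioral),
            inhibition=inhibition, seeds=tuple(seeds),
            scopes=tuple(scope_list), redraw_inhibition=redraw_inhibition,
            store_states=store_states,
            all_positive_first_state=all_positive_first_state)

    @classmethod
    def from_tables(cls, edges: str | Path, partition: str | Path | None = None,
                    exclude: str | set | None = "default",
                    dialect: EdgeTableDialect = DEFAULT_DIALECT,
                    **kwargs) -> "SelfOptimization":
        """Build the model from delimited edge and partition tables.

        ``exclude="default"`` applies the packaged exclusion list
        (pharyngeal neurons plus VC6/CANR/CANL); pass a set of names, a
        path, or None to override.
        """
        c = load_connectome(edges, dialect)
        if exclude == "default":
            c = filter_neurons(c, load_exclusions())
        elif isinstance(exclude, (str, Path)):
            c = filter_neurons(c, load_exclusions(exclude))
        elif exclude:
            c = filter_neurons(c, set(exclude))
        p = load_partition(partition) if partition is not None else None
        if p is not None and not p.super_clusters:
            p = p.derive_hierarchy()
        return cls(c, p, **kwargs)

    def fit(self, seeds: Sequence[int] | None = None) -> "SelfOptimizationResults":
        """Run the replicated three-phase protocol and collect results."""
        cfg = self.config
        if seeds is not None:
            cfg = replace(cfg, seeds=tuple(seeds))
            self.config = cfg
        trace = run_experiment(self.network, self.partition, cfg)
        return SelfOptimizationResults(self, trace)

    def stats(self):
        """Graph statistics of the underlying connectome (needs one)."""
        if self.connectome is None:
            raise ValueError("model was built from a SignedNetwork; "
                             "graph statistics need the raw connectome")
        return graph_stats(self.connectome, self.partition)


class SelfOptimizationResults:
    """Fitted protocol: per-cycle traces plus phase-level summaries."""

    def __init__(self, model: SelfOptimization, trace: ExperimentTrace):
        self.model = model
        self.trace = trace

    @property
    def phase_table(self) -> pd.DataFrame:
        """Mean and population SD of energy per scope × phase."""
        return self.trace.summary_table()

    def phase_summary(self, phase: str, scope: str = "whole",
                      over: str = "all") -> tuple[float, float]:
        return self.trace.phase_summary(phase, scope, over)

    def improvement(self, scope: str = "whole") -> float:
        """Before-phase mean energy minus after-phase mean energy.

        Positive values mean the after-phase attractors satisfy the
        original constraints better (lower energy) than before learning.
        """
        before, _ = self.trace.phase_summary("before", scope)
        after, _ = self.trace.phase_summary("after", scope)
        return before - after

    def census(self, net: SignedNetwork | None = None) -> pd.DataFrame:
        """Attractor census over stored final states.

        Energies are evaluated against ``net`` when given; otherwise the
        model's base network is used if no inhibition was applied (with
        per-replicate sign redraws there is no single reference sign
        pattern, so energies are then left NaN).
        """
        if net is None and self.model.config.inhibition is None:
            net = self.model.network
        return attractor_census(self.trace, net)

    def summary(self) -> str:
        """Human-readable report in the spirit of a model-results table."""
        net = self.model.network
        cfg = self.model.config
        inh = cfg.inhibition
        inh_txt = ("none (all excitatory)" if inh is None else
                   f"{inh.mode}, {inh.fraction:.0%} of "
                   f"{'all edges' if inh.fraction_of == 'total' else 'the pool'}")
        lines = [
            "          Self-Optimization of Attractor Dynamics",
            "=" * 60,
            f"Neurons:            {net.n:<10d} Edges:          {net.n_edges}",
            f"Inhibition:         {inh_txt}",
            f"Learning rate:      {cfg.learning.rate:<10.3g} "
            f"Clamp [-1,1]:   {cfg.learning.clip_behavioral}",
            f"Cycles (B/L/A):     {cfg.cycles[0]}/{cfg.cycles[1]}/{cfg.cycles[2]}"
            f"     Updates/cycle: {cfg.updates_per_neuron} x n",
            f"Replicates:         {len(cfg.seeds)}",
            "-" * 60,
            "Energy vs. original weights (mean, population SD over",
            "all cycle x replicate values in each phase):",
            "",
        ]
        table = self.phase_table
        if not table.empty:
            wide = table.pivot(index="scope", columns="phase", values=["mean", "sd"])
            wide = wide.reindex(self.trace.scope_names)
            lines.append(wide.round(4).to_string())
        else:
            lines.append("(no cycles recorded)")
        lines.append("=" * 60)
        return "\n".join(lines)

    def plot_energy(self, scope: str = "whole", ax=None, show_sd: bool = True):
        """Replicate-averaged energy per cycle with phase boundaries."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        agg = self.trace.aggregate()
        agg = agg[agg["scope"] == scope]
        ax.plot(agg["cycle"], agg["mean"], lw=0.8, label=f"{scope} (mean)")
        if show_sd:
            ax.fill_between(agg["cycle"], agg["mean"] - agg["sd"],
                            agg["mean"] + agg["sd"], alpha=0.25, lw=0)
        for b in np.cumsum(self.trace.phase_lengths)[:-1]:
            ax.axvline(b, color="k", ls="--", lw=0.8)
        ax.set_xlabel("reset-convergence cycle")
        ax.set_ylabel("energy (original weights)")
        ax.legend(loc="best", fontsize="small")
        return ax
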