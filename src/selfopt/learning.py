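"""Hebbian reinforcement of visited attractors, on the learned-weight layer.

After each relaxation the visited state is reinforced: every edge
(j→i, k) receives ``w_delta += rate · s_i · s_j``.  The original weights
are never touched, so the constraint-satisfaction energy of any fixed
state is invariant under learning.  Because the increment depends on the
*product* of endpoint states, a state and its global flip −s are
reinforced identically (spin-flip symmetry).

One exact consequence used throughout the tests: a single step lowers
the behavioral energy of the reinforced state by ``rate × M`` (M = edge
count) as long as clamping does not bind.
"""

from __future__ import annotations

from dataclasses import dataclass

from .network import SignedNetwork


@dataclass(frozen=True)
class LearningConfig:
    """Hebbian increment scale and clamping policy.

    ``rate`` is the per-edge increment per cycle; ``clip_behavioral``
    clamps the behavioral weight (original + delta) into [−1, 1] during
    dynamics, while ``w_delta`` itself keeps its full history.
    """

    rate: float = 1e-5
    clip_behavioral: bool = True

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("learning rate must be >= 0")


def hebbian_step(net: SignedNetwork, s, cfg: LearningConfig) -> SignedNetwork:
    """Reinforce state s on every edge: w_delta += rate·s_post·s_pre.

    Mutates ``net`` in place and returns it.  Parallel edges are
    reinforced independently.
    """
    if len(s) != net.n:
        raise ValueError("state length does not match network size")
    net.w_delta += cfg.rate * s[net.post] * s[net.pre]
    return net


def scale_learning_rate(base_rate: float, base_edges: int, target_edges: int) -> float:
    """Edge-proportional learning rate: keeps rate × edges constant.

    Smaller subnetworks learn faster so that the total weight change per
    cycle is comparable across network sizes.
    """
    if base_edges <= 0 or target_edges <= 0:
        raise ValueError("edge counts must be positive")
    return base_rate * base_edges / target_edges
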