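"""Per-node gene counts, per-edge gain/loss tallies, and overestimation
summaries — the statistics used to compare the two reconstruction engines.

Counts are discrete for Dollo parsimony (a character is either present or
absent at a node) and *expected* for maximum likelihood, where each
character contributes its marginal posterior probability of presence
("treating probabilities as expected values"). Gains and losses are tallied
on edges by comparing each node with its parent; a character whose single
Dollo gain falls at the root is booked as a gain at the root node itself,
which has no parent edge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dollo import DolloStates
from .ml_ancestral import PosteriorMatrix
from .phylo_io import RootedTree, node_depth

#: Default flagging threshold for "strongly overestimated" nodes: a node is
#: reported when its count exceeds the truth by at least this many genes in
#: at least one replicate.
OVERESTIMATE_THRESHOLD = 105


def expected_counts(posteriors: PosteriorMatrix | np.ndarray) -> np.ndarray:
    """Per-node expected character count: the sum over characters of the
    posterior probability of presence. Applied to a 0/1 state matrix this
    reduces to the plain per-node count, so it serves both engines."""
    probs = posteriors.probs if isinstance(posteriors, PosteriorMatrix) \
        else np.asarray(posteriors)
    if probs.size and (probs.min() < 0 or probs.max() > 1):
        raise ValueError("posterior probabilities must lie in [0, 1]")
    return probs.sum(axis=1, dtype=float)


def dollo_counts(states: DolloStates) -> np.ndarray:
    """Per-node character count of a Dollo reconstruction."""
    return states.states.sum(axis=1).astype(float)


@dataclass
class GainLossTable:
    """Per-node count, gains and losses (on the edge leading to the node),
    and depth (internal nodes strictly between the node and the root)."""

    counts: np.ndarray
    gains: np.ndarray
    losses: np.ndarray
    depth: np.ndarray

    def to_frame(self, tree: RootedTree | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "node": np.arange(len(self.counts)),
            "depth": self.depth,
            "count": self.counts,
            "gains": self.gains,
            "losses": self.losses,
        })
        if tree is not None:
            df["is_tip"] = [tree.is_tip(v) for v in range(tree.n_nodes)]
            df["label"] = [tree.labels[v] or "" for v in range(tree.n_nodes)]
        return df

    @property
    def total_gains(self) -> float:
        return float(self.gains.sum())

    @property
    def total_losses(self) -> float:
        return float(self.losses.sum())


def _depth_array(tree: RootedTree) -> np.ndarray:
    d = node_depth(tree)
    return np.array([d[v] for v in range(tree.n_nodes)])


def gains_losses_dollo(tree: RootedTree, states: DolloStates) -> GainLossTable:
    """Tally Dollo gains and losses: a 0->1 edge adds one gain at the child,
    a 1->0 edge one loss; a character present on both sides of the root is
    gained at the root node itself. Every character present in at least one
    tip has exactly one gain in total."""
    n = tree.n_nodes
    gains = np.zeros(n)
    losses = np.zeros(n)
    for v in range(n):
        gains[v] = float((states.origin == v).sum())
    s = states.states
    for u, v in tree.edges():
        losses[v] = float(((s[u] == 1) & (s[v] == 0)).sum())
    return GainLossTable(counts=dollo_counts(states), gains=gains,
                         losses=losses, depth=_depth_array(tree))


GAIN_LOSS_MODES = ("expected-difference", "event-count")


def gains_losses_ml(tree: RootedTree, posteriors: PosteriorMatrix,
                    mode: str = "expected-difference") -> GainLossTable:
    """Tally maximum-likelihood gains and losses from marginal posteriors.

    A character whose presence probability rises from parent to child
    contributes toward the gains leading to the child; a drop contributes
    toward losses. ``expected-difference`` (default) adds the probability
    difference itself, which preserves the count-balance identity
    count(child) = count(parent) + gains - losses; ``event-count`` adds 1
    per qualifying character regardless of the size of the change. The root
    has no parent edge and receives no gains or losses.
    """
    if mode not in GAIN_LOSS_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of "
                         f"{GAIN_LOSS_MODES}")
    n = tree.n_nodes
    gains = np.zeros(n)
    losses = np.zeros(n)
    p = posteriors.probs
    for u, v in tree.edges():
        diff = p[v] - p[u]
        if mode == "expected-difference":
            gains[v] = float(np.clip(diff, 0, None).sum())
            losses[v] = float(np.clip(-diff, 0, None).sum())
        else:
            gains[v] = float((diff > 0).sum())
            losses[v] = float((diff < 0).sum())
    return GainLossTable(counts=expected_counts(posteriors), gains=gains,
                         losses=losses, depth=_depth_array(tree))


@dataclass
class OverestimationSummary:
    """Where and by how much inferred counts exceed the known truth."""

    per_node: pd.DataFrame
    per_depth: pd.DataFrame
    threshold: float

    @property
    def flagged_nodes(self) -> list[int]:
        """Nodes overestimated by at least the threshold in >=1 replicate."""
        sel = self.per_node[self.per_node["exceeds_threshold"]]
        return [int(v) for v in sel["node"]]


def overestimation_summary(counts: np.ndarray, truth: float,
                           depths: dict[int, int] | np.ndarray,
                           threshold: float = OVERESTIMATE_THRESHOLD
                           ) -> OverestimationSummary:
    """Summarize per-node overestimation against a known true count.

    ``counts`` is (n_nodes,) for a single replicate or
    (n_replicates, n_nodes); the per-node summary reports the maximum
    overestimate across replicates, flags any node above the truth, and
    marks nodes whose maximum overestimate reaches ``threshold``. A second
    table aggregates mean and max overestimate by node depth, the axis
    along which Dollo's inflation grows.
    """
    counts = np.atleast_2d(np.asarray(counts, dtype=float))
    if isinstance(depths, dict):
        depths = np.array([depths[v] for v in range(counts.shape[1])])
    else:
        depths = np.asarray(depths)
    if counts.shape[1] != len(depths):
        raise ValueError("counts and depths cover different node sets")
    over = counts - float(truth)
    max_over = over.max(axis=0)
    mean_over = over.mean(axis=0)
    per_node = pd.DataFrame({
        "node": np.arange(counts.shape[1]),
        "depth": depths,
        "max_overestimate": max_over,
        "mean_overestimate": mean_over,
        "overestimated": max_over > 0,
        "exceeds_threshold": max_over >= threshold,
    })
    per_depth = (per_node.groupby("depth")
                 .agg(mean_overestimate=("mean_overestimate", "mean"),
                      max_overestimate=("max_overestimate", "max"),
                      n_nodes=("node", "size"))
                 .reset_index())
    return OverestimationSummary(per_node=per_node, per_depth=per_depth,
                                 threshold=threshold)


def gain_loss_quartiles(tables: list[GainLossTable]) -> dict[str, float]:
    """Quartiles of the pooled non-root gain and loss values, the reporting
    cut used to separate minor from major gain/loss events."""
    pooled: list[np.ndarray] = []
    for t in tables:
        pooled.append(t.gains)
        pooled.append(t.losses)
    allvals = np.concatenate(pooled) if pooled else np.array([0.0])
    q1, q2, q3 = np.percentile(allvals, [25, 50, 75])
    return {"q1": float(q1), "q2": float(q2), "q3": float(q3)}
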