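"""Generalized (Sankoff) parsimony with arbitrary step matrices.

A single multistate character is optimized on a rooted tree by dynamic
programming: for node *v* and state *s*, the minimum cost of the subtree
rooted at *v* given that *v* is in state *s* is

    C_v(s) = sum over children c of  min_t [ cost(s -> t) + C_c(t) ],

with C_tip(s) = 0 for admissible tip states and infinity otherwise.  The
tree's minimum total cost is min_s C_root(s).  Polytomies are handled
naturally (the sum runs over all children), and the step matrix may be
asymmetric and real-valued — zeros arise from the generalist host-range
rule.  A second, top-down pass recovers for every node the set of states
attainable in at least one minimum-cost reconstruction (the MPR set);
ambiguity is reported as a set, never resolved arbitrarily.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ShiftCountSummary",
    "sankoff_min_cost",
    "ancestral_states",
    "count_shifts_over_sample",
    "required_speciation_events",
]


@dataclass
class ShiftCountSummary:
    """Per-tree minimum step counts over a tree sample."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.size == 0:
            raise ValueError("empty tree sample")

    @property
    def n_trees(self) -> int:
        return int(self.counts.size)

    @property
    def min(self) -> float:
        return float(self.counts.min())

    @property
    def max(self) -> float:
        return float(self.counts.max())

    @property
    def mean(self) -> float:
        return float(self.counts.mean())

    def as_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "min": self.min,
            "max": self.max,
            "mean": self.mean,
        }


def _tip_set_arrays(
    tree: dendropy.Tree,
    tip_sets: Mapping[str, Iterable[int]],
    k: int,
) -> dict[dendropy.Node, np.ndarray]:
    """Per-tip cost vectors: 0 for admissible states, +inf otherwise."""
    out = {}
    missing = []
    for leaf in tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in tip_sets:
            missing.append(label)
            continue
        states = list(tip_sets[label])
        if not states:
            raise ValueError(f"tip {label!r} has an empty admissible state set")
        if min(states) < 0 or max(states) >= k:
            raise ValueError(
                f"tip {label!r} has state indices outside the catalog (k={k})"
            )
        vec = np.full(k, np.inf)
        vec[states] = 0.0
        out[leaf] = vec
    if missing:
        raise KeyError(f"tree tips absent from tip state sets: {sorted(missing)}")
    return out


def _down_pass(
    tree: dendropy.Tree,
    tip_sets: Mapping[str, Iterable[int]],
    costs: np.ndarray,
) -> dict[dendropy.Node, np.ndarray]:
    costs = np.asarray(costs, dtype=float)
    if costs.ndim != 2 or costs.shape[0] != costs.shape[1]:
        raise ValueError("step matrix must be square")
    k = costs.shape[0]
    tip_vecs = _tip_set_arrays(tree, tip_sets, k)
    table: dict[dendropy.Node, np.ndarray] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            table[node] = tip_vecs[node]
        else:
            total = np.zeros(k)
            for child in node.child_nodes():
                # min over child states t of cost(s->t) + C_child(t)
                total += (costs + table[child][None, :]).min(axis=1)
            table[node] = total
    return table


def sankoff_min_cost(
    tree: dendropy.Tree,
    tip_sets: Mapping[str, Iterable[int]],
    costs: np.ndarray,
) -> float:
    """Minimum total transition cost of the character on the tree."""
    table = _down_pass(tree, tip_sets, costs)
    return float(table[tree.seed_node].min())


def ancestral_states(
    tree: dendropy.Tree,
    tip_sets: Mapping[str, Iterable[int]],
    costs: np.ndarray,
) -> dict[dendropy.Node, frozenset[int]]:
    """MPR state sets: per node, all states attainable in some optimum.

    The top-down pass keeps, for each node, every state *s* for which some
    attainable parent state *p* satisfies
    ``cost(p, s) + C_node(s) == min_t [cost(p, t) + C_node(t)]``; subtree
    choices are independent given the parent state, so this is exact.
    Nodes whose set has more than one element are ambiguous.
    """
    costs = np.asarray(costs, dtype=float)
    table = _down_pass(tree, tip_sets, costs)
    sets: dict[dendropy.Node, frozenset[int]] = {}
    root_vec = table[tree.seed_node]
    best = root_vec.min()
    sets[tree.seed_node] = frozenset(np.flatnonzero(root_vec == best))
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        parent_states = sets[node.parent_node]
        vec = table[node]
        attain: set[int] = set()
        for p in parent_states:
            through = costs[p, :] + vec
            attain.update(np.flatnonzero(through == through.min()))
        sets[node] = frozenset(attain)
    return sets


def count_shifts_over_sample(
    trees: Iterable[dendropy.Tree],
    tip_sets: Mapping[str, Iterable[int]],
    costs: np.ndarray,
) -> ShiftCountSummary:
    """Minimum step count of the character on each tree of a sample.

    Applying the optimization across a posterior tree sample quantifies
    how robust the shift count is to phylogenetic uncertainty.
    """
    counts = [sankoff_min_cost(tree, tip_sets, costs) for tree in trees]
    summary = ShiftCountSummary(np.array(counts))
    logger.info(
        "shift counts over %d trees: min=%g mean=%g max=%g",
        summary.n_trees, summary.min, summary.mean, summary.max,
    )
    return summary


def required_speciation_events(n_ingroup_tips: int) -> int:
    """Number of past lineage splits needed to produce n extant species.

    A strictly bifurcating history producing *n* species contains exactly
    *n - 1* speciation events, regardless of topology.
    """
    if n_ingroup_tips < 1:
        raise ValueError("need at least one species")
    return n_ingroup_tips - 1
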