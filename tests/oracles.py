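"""Independent brute-force oracles used to validate the dynamic programs.

These deliberately share no code with the package: the parsimony oracle
enumerates every ancestral-state assignment, and the logistic oracle is a
grid search over the likelihood surface.
"""

from __future__ import annotations

import itertools
import random

import dendropy
import numpy as np


def brute_force_sankoff(tree, tip_sets, costs):
    """Exhaustive minimum over all node-state assignments.

    Returns ``(min_cost, mpr_sets)`` where ``mpr_sets`` maps each node to
    the set of states it takes in at least one minimum-cost assignment.
    Tips are restricted to their admissible sets, internal nodes range
    over the full catalog.
    """
    costs = np.asarray(costs, dtype=float)
    k = costs.shape[0]
    nodes = list(tree.preorder_node_iter())
    allowed = []
    for nd in nodes:
        if nd.is_leaf():
            allowed.append(sorted(tip_sets[nd.taxon.label]))
        else:
            allowed.append(list(range(k)))
    assignments = np.array(list(itertools.product(*allowed)))
    index = {nd: i for i, nd in enumerate(nodes)}
    total = np.zeros(len(assignments))
    for nd in nodes:
        if nd.parent_node is None:
            continue
        total += costs[assignments[:, index[nd.parent_node]], assignments[:, index[nd]]]
    best = total.min()
    optimal = assignments[total == best]
    mpr = {nd: frozenset(np.unique(optimal[:, index[nd]])) for nd in nodes}
    return float(best), mpr


def grid_search_logistic(ages, labels, b0_range, b1_range, steps=201):
    """Coarse-to-fine grid maximizer of the Bernoulli log-likelihood."""
    ages = np.asarray(ages, dtype=float)
    labels = np.asarray(labels, dtype=float)

    def ll(b0, b1):
        eta = b0 + b1 * ages
        return np.sum(labels * eta - np.logaddexp(0.0, eta))

    lo0, hi0 = b0_range
    lo1, hi1 = b1_range
    best = None
    for _ in range(6):  # refine the grid six times
        g0 = np.linspace(lo0, hi0, steps)
        g1 = np.linspace(lo1, hi1, steps)
        vals = np.array([[ll(a, b) for b in g1] for a in g0])
        i, j = np.unravel_index(np.argmax(vals), vals.shape)
        best = (g0[i], g1[j])
        w0 = (hi0 - lo0) / (steps - 1)
        w1 = (hi1 - lo1) / (steps - 1)
        lo0, hi0 = best[0] - 2 * w0, best[0] + 2 * w0
        lo1, hi1 = best[1] - 2 * w1, best[1] + 2 * w1
    return best


def random_tree(rng: random.Random, n_tips: int, polytomy_prob: float = 0.0):
    """Random rooted tree built by joining subtrees; optional polytomies."""
    ns = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n_tips):
        taxon = ns.new_taxon(label=f"t{i}")
        nd = dendropy.Node(taxon=taxon)
        nd.edge.length = rng.uniform(0.1, 1.0)
        nodes.append(nd)
    while len(nodes) > 1:
        n_join = 2
        if len(nodes) > 2 and rng.random() < polytomy_prob:
            n_join = 3
        picks = rng.sample(nodes, n_join)
        for p in picks:
            nodes.remove(p)
        parent = dendropy.Node()
        parent.edge.length = rng.uniform(0.1, 1.0)
        for p in picks:
            parent.add_child(p)
        nodes.append(parent)
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = nodes[0]
    tree.seed_node.edge.length = None
    tree.is_rooted = True
    return tree


def random_instance(rng: random.Random, max_tips: int = 7, max_states: int = 5,
                    polytomy_prob: float = 0.2, unknown_prob: float = 0.15):
    """A random (tree, tip state sets, asymmetric cost matrix) triple."""
    n = rng.randint(3, max_tips)
    k = rng.randint(2, max_states)
    tree = random_tree(rng, n, polytomy_prob=polytomy_prob)
    tip_sets = {}
    for leaf in tree.leaf_node_iter():
        if rng.random() < unknown_prob:
            size = rng.randint(2, k)
            tip_sets[leaf.taxon.label] = set(rng.sample(range(k), size))
        else:
            tip_sets[leaf.taxon.label] = {rng.randrange(k)}
    costs = np.array([[rng.choice([0.0, 0.5, 1.0, 2.0, 3.0]) for _ in range(k)]
                      for _ in range(k)])
    np.fill_diagonal(costs, 0.0)
    return tree, tip_sets, costs
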