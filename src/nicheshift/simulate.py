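"""Synthetic phylogenies and niche data with cladogenetic and anagenetic shifts.

The generator emulates the structure of a dated herbivore phylogeny with
species-level niche data: an ultrametric birth–death tree rescaled to
root height 1, niches drawn from a feeding-habit x host-taxon pool with a
minority of two-host generalists, and niche evolution with two kinds of
change:

* *cladogenetic* — with probability ``p_eco`` a speciation event is
  ecological: one daughter lineage is forced into a niche that does not
  overlap its sister's niche at the moment of splitting;
* *anagenetic* — along every branch, shift events arrive as a Poisson
  process with rate ``ana_rate`` per unit branch length, each replacing
  the current niche with a fresh draw (a post-speciational host or habit
  shift).

Because only cladogenetic changes count as ecological speciation, the
fraction of niche-different sister pairs at split age zero equals
``p_eco`` up to sampling noise, while the raw (uncorrected) fraction is
inflated by anagenetic shifts — the discrepancy the age-corrected
sister-pair regression is designed to remove.

A "posterior" tree sample is emulated by applying random
nearest-neighbor-interchange (NNI) moves to the true tree; this exercises
the counting-over-samples machinery without running an MCMC.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .niche import NicheState, write_niche_table
from .treeio import write_trees

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "simulate_tree",
    "simulate_niche_evolution",
    "attach_outgroups",
    "nni_perturb",
    "generate_dataset",
]

DEFAULT_HABITS = (
    "external_folivory",
    "galling",
    "leaf_folding",
    "catkin_feeding",
    "berry_mining",
    "needle_feeding",
)

# A pool of common boreal host-plant genera; 20 hosts x 6 habits gives a
# niche space comfortably larger than the ~40-60 distinct niches realised
# among ~125 species.
DEFAULT_HOSTS = (
    "Salix", "Betula", "Alnus", "Populus", "Picea", "Larix", "Pinus",
    "Vaccinium", "Spiraea", "Rosa", "Rubus", "Sorbus", "Prunus", "Ribes",
    "Corylus", "Quercus", "Acer", "Tilia", "Ulmus", "Filipendula",
)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Defaults mirror a sparsely sampled boreal sawfly radiation: 125
    ingroup species, pure-birth branching, one in five splits ecological,
    one anagenetic niche shift expected per unit of relative time, and a
    modest fraction of two-host generalists.
    """

    n_tips: int = 125
    birth_rate: float = 1.0
    death_rate: float = 0.0
    p_eco: float = 0.2
    ana_rate: float = 1.0
    host_pool: tuple[str, ...] = DEFAULT_HOSTS
    habit_pool: tuple[str, ...] = DEFAULT_HABITS
    p_generalist: float = 0.15
    n_outgroups: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ValueError("n_tips must be >= 2")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("rates must be positive (birth) / nonnegative (death)")
        if not (0.0 <= self.p_eco <= 1.0 and 0.0 <= self.p_generalist <= 1.0):
            raise ValueError("p_eco and p_generalist must lie in [0, 1]")
        if self.ana_rate < 0:
            raise ValueError("ana_rate must be nonnegative")
        if not self.host_pool or not self.habit_pool:
            raise ValueError("host and habit pools must be nonempty")


def _rescale_to_unit_height(tree: dendropy.Tree) -> None:
    depths = {leaf: leaf.distance_from_root() for leaf in tree.leaf_node_iter()}
    h = max(depths.values())
    if h <= 0:
        raise ValueError("simulated tree has zero height")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= h
    # snap terminal edges so tip depths are exactly 1 (kills float drift)
    for leaf in tree.leaf_node_iter():
        gap = 1.0 - leaf.distance_from_root()
        leaf.edge.length += gap


def simulate_tree(config: SimulationConfig, rng: random.Random | None = None) -> dendropy.Tree:
    """Constant-rate birth–death tree with ``n_tips`` extant species.

    Extinct lineages are pruned, tips are relabeled ``T001..`` in a fixed
    order, and branch lengths are rescaled so the root height is exactly
    1; the result is ultrametric and reproducible from the seed.
    """
    if rng is None:
        rng = random.Random(config.seed)
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=config.death_rate,
        num_extant_tips=config.n_tips,
        rng=rng,
        repeat_until_success=True,
    )
    tree.is_rooted = True
    width = max(3, len(str(config.n_tips)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"T{i:0{width}d}"
    n = sum(1 for _ in tree.leaf_node_iter())
    if n != config.n_tips:
        raise RuntimeError(f"simulator produced {n} tips, expected {config.n_tips}")
    _rescale_to_unit_height(tree)
    return tree


def _draw_niche(
    config: SimulationConfig,
    rng: random.Random,
    avoid_overlap: NicheState | None = None,
    not_equal: NicheState | None = None,
    max_tries: int = 1000,
) -> NicheState:
    for _ in range(max_tries):
        habit = rng.choice(config.habit_pool)
        if rng.random() < config.p_generalist and len(config.host_pool) >= 2:
            hosts = frozenset(rng.sample(config.host_pool, 2))
        else:
            hosts = frozenset({rng.choice(config.host_pool)})
        state = NicheState(habit, hosts)
        if avoid_overlap is not None and not (
            state.habit != avoid_overlap.habit or not (state.hosts & avoid_overlap.hosts)
        ):
            continue
        if not_equal is not None and state == not_equal:
            continue
        return state
    raise ValueError(
        "host/habit pools too small to draw a suitable niche "
        f"(avoid_overlap={avoid_overlap}, not_equal={not_equal})"
    )


def simulate_niche_evolution(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: random.Random | None = None,
) -> pd.DataFrame:
    """Evolve a niche down the tree and return the species niche table.

    The root receives a random niche.  At each internal node, with
    probability ``p_eco``, one randomly chosen daughter draws a new niche
    guaranteed non-overlapping with its sister's niche at that moment;
    otherwise both daughters inherit.  Along every branch,
    Poisson(``ana_rate`` x length) anagenetic events each replace the
    current niche with a fresh draw (distinct from the current one).
    ``n_outgroups`` unknown-niche outgroup rows (``OUT1..``) are appended.
    """
    if rng is None:
        rng = random.Random(config.seed)

    def evolve_along(state: NicheState, length: float) -> NicheState:
        n_events = _poisson(rng, config.ana_rate * length)
        for _ in range(n_events):
            state = _draw_niche(config, rng, not_equal=state)
        return state

    root = tree.seed_node
    start: dict[dendropy.Node, NicheState] = {root: _draw_niche(config, rng)}
    end: dict[dendropy.Node, NicheState] = {}
    for node in tree.preorder_node_iter():
        length = node.edge.length or 0.0
        if node is root:
            end[node] = start[node]
        else:
            end[node] = evolve_along(start[node], length)
        children = node.child_nodes()
        if not children:
            continue
        for child in children:
            start[child] = end[node]
        if rng.random() < config.p_eco:
            shifted = rng.randrange(len(children))
            sister_state = end[node]
            start[children[shifted]] = _draw_niche(
                config, rng, avoid_overlap=sister_state
            )

    rows = []
    for leaf in sorted(tree.leaf_node_iter(), key=lambda l: l.taxon.label):
        st = end[leaf]
        rows.append(
            {
                "species": leaf.taxon.label,
                "feeding_habit": st.habit,
                "hosts": ";".join(sorted(st.hosts)),
                "outgroup": 0,
            }
        )
    for i in range(1, config.n_outgroups + 1):
        rows.append(
            {"species": f"OUT{i}", "feeding_habit": "", "hosts": "", "outgroup": 1}
        )
    return pd.DataFrame(rows, columns=["species", "feeding_habit", "hosts", "outgroup"])


def _poisson(rng: random.Random, lam: float) -> int:
    """Knuth's algorithm; adequate for the small means used here."""
    if lam <= 0:
        return 0
    L = np.exp(-lam)
    k = 0
    p = 1.0
    while True:
        p *= rng.random()
        if p <= L:
            return k
        k += 1


def attach_outgroups(
    tree: dendropy.Tree, n_outgroups: int, stem_fraction: float = 0.25
) -> dendropy.Tree:
    """Graft a basal grade of outgroup tips below the current root.

    Each successive outgroup subtends the previous root from a stem
    ``stem_fraction`` of the current height long; the tree stays
    ultrametric and is rescaled back to unit root height.  Outgroup tips
    are labeled ``OUT1..`` from the innermost outward.
    """
    ns = tree.taxon_namespace
    for i in range(1, n_outgroups + 1):
        old_root = tree.seed_node
        height = max(l.distance_from_root() for l in tree.leaf_node_iter())
        stem = stem_fraction * height
        new_root = dendropy.Node()
        taxon = ns.new_taxon(label=f"OUT{i}")
        out_tip = dendropy.Node(taxon=taxon)
        out_tip.edge.length = height + stem
        tree.seed_node = new_root
        new_root.add_child(old_root)
        old_root.edge.length = stem
        new_root.add_child(out_tip)
    if n_outgroups > 0:
        _rescale_to_unit_height(tree)
    return tree


def nni_perturb(
    tree: dendropy.Tree, n_moves: int, rng: random.Random
) -> dendropy.Tree:
    """Copy of the tree with ``n_moves`` random NNI rearrangements applied.

    An internal edge (both ends internal, child end not the root) is
    chosen at random and one of the child's subtrees is swapped with the
    child's sibling.  Edge lengths travel with their subtrees, so the
    perturbed tree is generally no longer ultrametric — like individual
    MCMC samples around a summary tree, only the topology is guaranteed.
    """
    tree = tree.clone(depth=1)
    for _ in range(n_moves):
        candidates = [
            nd for nd in tree.preorder_internal_node_iter()
            if nd.parent_node is not None and len(nd.child_nodes()) >= 2
            and len(nd.parent_node.child_nodes()) >= 2
        ]
        if not candidates:
            break
        node = rng.choice(candidates)
        parent = node.parent_node
        siblings = [c for c in parent.child_nodes() if c is not node]
        sibling = rng.choice(siblings)
        child = rng.choice(node.child_nodes())
        parent.remove_child(sibling)
        node.remove_child(child)
        node.add_child(sibling)
        parent.add_child(child)
    return tree


def generate_dataset(
    config: SimulationConfig,
    n_posterior_trees: int = 0,
    out_dir=None,
    n_nni_moves: int = 2,
) -> dict:
    """Simulate a full analysis input set: trees plus niche table.

    Produces the true ("MCC") ultrametric tree with outgroups attached, a
    niche table, and optionally ``n_posterior_trees`` NNI-perturbed
    topologies standing in for a posterior sample.  With ``out_dir`` set,
    writes ``mcc.nwk``, ``posterior.nwk`` (if requested) and
    ``niches.tsv`` and records the paths in the returned dict alongside
    the in-memory objects.
    """
    rng = random.Random(config.seed)
    ingroup = simulate_tree(config, rng=rng)
    table = simulate_niche_evolution(ingroup, config, rng=rng)
    tree = attach_outgroups(ingroup, config.n_outgroups)

    posterior = dendropy.TreeList(taxon_namespace=tree.taxon_namespace)
    for _ in range(n_posterior_trees):
        posterior.append(nni_perturb(tree, n_nni_moves, rng))

    result = {"mcc_tree": tree, "niche_table": table, "posterior": posterior,
              "seed": config.seed}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        mcc_path = out_dir / "mcc.nwk"
        write_trees(tree, mcc_path)
        result["mcc_path"] = mcc_path
        niche_path = out_dir / "niches.tsv"
        write_niche_table(table, niche_path)
        result["niche_path"] = niche_path
        if n_posterior_trees:
            post_path = out_dir / "posterior.nwk"
            write_trees(posterior, post_path)
            result["posterior_path"] = post_path
        logger.info("wrote synthetic dataset (seed=%d) to %s", config.seed, out_dir)
    return result
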