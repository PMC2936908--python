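"""Reading and writing phylogenies, node heights, and terminal sister pairs.

Trees are represented as :class:`dendropy.Tree` objects throughout; this
module wraps parsing (Newick and Nexus with TRANSLATE tables and
BEAST-style ``[&...]`` node annotations), node-height computation on
chronograms, and extraction of terminal sister-species pairs ("cherries")
with their relative split ages.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import dendropy

logger = logging.getLogger(__name__)

__all__ = [
    "TreeParseError",
    "SisterPair",
    "read_trees",
    "read_tree",
    "write_trees",
    "node_heights",
    "relative_node_heights",
    "root_height",
    "extract_sister_pairs",
]

#: relative tip-depth spread above which a tree is reported non-ultrametric
ULTRAMETRIC_RTOL = 1e-6


class TreeParseError(ValueError):
    """Raised when a tree file cannot be parsed or fails validation."""


@dataclass
class SisterPair:
    """A terminal sister-species pair and its relative split age.

    ``split_age`` is the height of the pair's parent node divided by the
    root height, so it lies in [0, 1]: 0 is the present, 1 the root.
    ``niche_different`` is filled in later by the pair-classification step.
    """

    tip_a: str
    tip_b: str
    split_age: float
    niche_different: int | None = None


def _normalize_labels(trees: dendropy.TreeList | dendropy.Tree) -> None:
    # Nexus convention: whitespace in labels becomes underscore; matching
    # stays case-sensitive.
    ns = trees.taxon_namespace
    for taxon in ns:
        taxon.label = re.sub(r"\s+", "_", taxon.label.strip())


def _validate(tree: dendropy.Tree, index: int) -> None:
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeParseError(
            f"tree {index}: duplicate tip labels {sorted(dupes)}"
        )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeParseError(f"tree {index}: negative branch length {edge.length}")


def _infer_schema(path: Path) -> str:
    head = path.read_text(errors="replace").lstrip()[:40].lower()
    return "nexus" if head.startswith("#nexus") else "newick"


def read_trees(path, schema: str | None = None) -> dendropy.TreeList:
    """Read one or more rooted trees from a Newick or Nexus file.

    Nexus TRANSLATE tables are resolved to full tip labels and bracketed
    comment annotations (e.g. BEAST node metadata) are stripped from the
    topology while branch lengths are preserved.  Tree order is preserved.

    Raises :class:`TreeParseError` on malformed input or duplicate tip
    labels, naming the offending tree index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if schema is None:
        schema = _infer_schema(path)
    if schema not in {"newick", "nexus"}:
        raise ValueError(f"unsupported tree schema: {schema!r}")
    try:
        trees = dendropy.TreeList.get(
            path=str(path),
            schema=schema,
            preserve_underscores=True,
            rooting="default-rooted",
        )
    except Exception as exc:  # dendropy raises a zoo of error types
        raise TreeParseError(f"failed to parse {path.name}: {exc}") from exc
    if len(trees) == 0:
        raise TreeParseError(f"{path.name}: no trees found")
    _normalize_labels(trees)
    for i, tree in enumerate(trees):
        _validate(tree, i)
    first = {l.taxon.label for l in trees[0].leaf_node_iter()}
    for i, tree in enumerate(trees[1:], start=1):
        labels = {l.taxon.label for l in tree.leaf_node_iter()}
        if labels != first:
            logger.warning(
                "tree %d has a different tip set from tree 0 (%d vs %d tips)",
                i, len(labels), len(first),
            )
    logger.info("read %d tree(s) with %d tips from %s", len(trees), len(first), path.name)
    return trees


def read_tree(path, schema: str | None = None) -> dendropy.Tree:
    """Read a single tree; errors if the file holds more than one."""
    trees = read_trees(path, schema=schema)
    if len(trees) != 1:
        raise TreeParseError(f"expected a single tree, found {len(trees)}")
    return trees[0]


def write_trees(trees, path, schema: str = "newick") -> None:
    """Write a tree or tree list; branch lengths at full precision."""
    if isinstance(trees, dendropy.Tree):
        tl = dendropy.TreeList(taxon_namespace=trees.taxon_namespace)
        tl.append(trees)
        trees = tl
    trees.write(
        path=str(path),
        schema=schema,
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".17g",
    )


def node_heights(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Height of every node above the tips.

    Tips have height 0.  For internal nodes the height is the mean
    root-ward distance to the node's descendant tips; on an ultrametric
    tree (e.g. a chronogram) all those distances coincide.  When the
    root-to-tip depths spread by more than ``ULTRAMETRIC_RTOL`` relative
    to the maximum depth, a non-ultrametricity warning is logged.
    """
    heights: dict[dendropy.Node, float] = {}
    # (sum of distances to descendant tips, number of descendant tips)
    agg: dict[dendropy.Node, tuple[float, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            agg[node] = (0.0, 1)
            heights[node] = 0.0
        else:
            total = 0.0
            count = 0
            for child in node.child_nodes():
                s, n = agg[child]
                bl = child.edge.length or 0.0
                total += s + n * bl
                count += n
            agg[node] = (total, count)
            heights[node] = total / count

    tip_depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
    dmax = max(tip_depths)
    if dmax > 0 and (dmax - min(tip_depths)) / dmax > ULTRAMETRIC_RTOL:
        logger.warning(
            "tree is not ultrametric (tip depths %.6g..%.6g); node heights "
            "are means over descendant tips", min(tip_depths), dmax,
        )
    return heights


def root_height(tree: dendropy.Tree) -> float:
    return node_heights(tree)[tree.seed_node]


def relative_node_heights(tree: dendropy.Tree) -> dict[dendropy.Node, float]:
    """Node heights divided by root height, in [0, 1]; root maps to 1.

    Raises ``ValueError`` when the root height is zero (a star tree of
    zero-length branches has no meaningful relative heights).
    """
    heights = node_heights(tree)
    h_root = heights[tree.seed_node]
    if h_root <= 0:
        raise ValueError("root height is zero; relative node heights undefined")
    return {node: h / h_root for node, h in heights.items()}


def extract_sister_pairs(tree: dendropy.Tree) -> list[SisterPair]:
    """All terminal sister-species pairs (cherries) with relative split ages.

    A cherry is an internal node whose children are exactly two tips; its
    split age is the node's relative height.  Polytomies of three or more
    tip children are skipped with a warning rather than decomposed into
    pairs.  Pairs are returned sorted by split age, then labels, for
    reproducibility.
    """
    rel = relative_node_heights(tree)
    pairs: list[SisterPair] = []
    for node in tree.preorder_internal_node_iter():
        children = node.child_nodes()
        tips = [c for c in children if c.is_leaf()]
        if len(children) == 2 and len(tips) == 2:
            a, b = sorted(t.taxon.label for t in tips)
            pairs.append(SisterPair(tip_a=a, tip_b=b, split_age=rel[node]))
        elif len(tips) >= 3:
            logger.warning(
                "skipping polytomy with %d tip children (%s...)",
                len(tips), tips[0].taxon.label,
            )
    pairs.sort(key=lambda p: (p.split_age, p.tip_a, p.tip_b))
    logger.info("extracted %d terminal sister pairs", len(pairs))
    return pairs
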