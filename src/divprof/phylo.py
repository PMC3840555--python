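"""Phylogenetic trees: Newick I/O, patristic distances, tree-derived
similarity matrices, pruning and ultrametricity.

Trees are held as rooted :class:`dendropy.Tree` objects with uniquely
labelled tips and non-negative branch lengths.  Taxon similarity is derived
from patristic distance d_ij (total branch length on the tip-to-tip path)
through one of two transforms:

* ``exponential`` (default): Z_ij = exp(−d_ij / s); ``scale="auto"`` sets s
  to the mean off-diagonal patristic distance, so a typical pair of taxa has
  similarity 1/e regardless of the tree's depth units.
* ``linear``: Z_ij = max(0, 1 − d_ij / d_max).

Both map d = 0 to similarity 1 and are monotone decreasing in distance.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .profiles import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "load_tree",
    "tree_from_newick",
    "tree_to_newick",
    "write_tree",
    "tip_labels",
    "validate_tree",
    "patristic_matrix",
    "similarity_from_tree",
    "is_ultrametric",
    "prune_to_community",
]


def tree_from_newick(newick: str) -> dendropy.Tree:
    """Parse a single rooted tree from a Newick string.

    Unrooted trees ("[&U]" or a basal trichotomy read as unrooted by the
    parser) are midpoint-rooted, since balance and UniFrac statistics need a
    root; this is logged.  Duplicate tip labels are rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            rooting="default-rooted",
        )
    except Exception as exc:  # malformed newick, duplicate taxa, ...
        raise ValueError(f"could not parse newick: {exc}") from exc
    if not tree.is_rooted:
        logger.info("input tree is unrooted; applying midpoint rooting")
        tree.reroot_at_midpoint(update_bipartitions=False)
        tree.is_rooted = True
    validate_tree(tree)
    return tree


def load_tree(path) -> dendropy.Tree:
    """Read a single Newick tree from a file path."""
    with open(path) as fh:
        return tree_from_newick(fh.read())


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Serialize with branch lengths at 12 significant digits."""
    return tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".12g",
    ).strip() + "\n"


def write_tree(tree: dendropy.Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree_to_newick(tree))


def tip_labels(tree: dendropy.Tree) -> list:
    """Tip labels in tree (postorder leaf) order."""
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def validate_tree(tree: dendropy.Tree) -> None:
    """Check tips are labelled and unique and branch lengths non-negative."""
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise ValueError("tree contains an unlabelled tip")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError(f"negative branch length {edge.length}")


def _edge_len(node: dendropy.Node) -> float:
    return node.edge.length if node.edge.length is not None else 0.0


def patristic_matrix(tree: dendropy.Tree):
    """All-pairs patristic distances over tips.

    Returns ``(labels, D)`` with D[i, j] the branch-length sum on the path
    between tips i and j.  Computed as depth_i + depth_j − 2·depth(LCA) with
    a single postorder pass, merging tip-index blocks at each internal node,
    so large trees (thousands of tips) stay fast.
    """
    validate_tree(tree)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    index = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    D = np.zeros((n, n))

    depth = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth[id(node.parent_node)] if node.parent_node else 0.0
        depth[id(node)] = parent_depth + (_edge_len(node) if node.parent_node else 0.0)

    tip_depth = np.array([depth[id(lf)] for lf in leaves])

    # postorder: tips below each node; cross-merge child blocks at their LCA
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = np.array([index[id(node)]], dtype=int)
            continue
        blocks = [below.pop(id(c)) for c in node.child_nodes()]
        node_depth = depth[id(node)]
        for a in range(len(blocks)):
            for b in range(a + 1, len(blocks)):
                ia, ib = blocks[a], blocks[b]
                d = tip_depth[ia][:, None] + tip_depth[ib][None, :] - 2.0 * node_depth
                D[np.ix_(ia, ib)] = d
                D[np.ix_(ib, ia)] = d.T
        below[id(node)] = np.concatenate(blocks)
    return labels, D


def similarity_from_tree(
    tree: dendropy.Tree,
    transform: str = "exponential",
    scale="auto",
) -> SimilarityMatrix:
    """Build a taxon similarity matrix from patristic distances.

    Parameters
    ----------
    transform:
        ``"exponential"``: Z_ij = exp(−d_ij/s).  ``"linear"``:
        Z_ij = max(0, 1 − d_ij/d_max).
    scale:
        Positive decay scale s for the exponential transform, or ``"auto"``
        (mean off-diagonal patristic distance).  Ignored by ``linear``.
    """
    labels, D = patristic_matrix(tree)
    return similarity_from_distances(labels, D, transform=transform, scale=scale)


def similarity_from_distances(labels, D, transform="exponential", scale="auto") -> SimilarityMatrix:
    """As :func:`similarity_from_tree` but from a precomputed distance matrix."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if transform in ("exponential", "exp"):
        if scale == "auto":
            if n < 2:
                s = 1.0
            else:
                off = D.sum() / (n * (n - 1))
                s = off if off > 0 else 1.0
        else:
            s = float(scale)
            if s <= 0:
                raise ValueError("scale must be positive")
        Z = np.exp(-D / s)
    elif transform == "linear":
        d_max = D.max()
        if d_max <= 0:
            raise ValueError("linear transform undefined: all patristic distances are 0")
        Z = np.clip(1.0 - D / d_max, 0.0, 1.0)
    else:
        raise ValueError(f"unknown transform {transform!r}")
    np.fill_diagonal(Z, 1.0)
    return SimilarityMatrix(labels, Z)


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    """True iff all root-to-tip path lengths are equal within rel_tol."""
    depths = []
    depth = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth[id(node.parent_node)] if node.parent_node else 0.0
        depth[id(node)] = parent_depth + (_edge_len(node) if node.parent_node else 0.0)
        if node.is_leaf():
            depths.append(depth[id(node)])
    depths = np.array(depths)
    top = depths.max()
    if top == 0:
        return True
    return bool((depths.max() - depths.min()) <= rel_tol * top)


def prune_to_community(tree: dendropy.Tree, taxon_ids: Iterable[str]) -> dendropy.Tree:
    """Induced subtree on the named tips.

    Pairwise path lengths between retained tips are preserved exactly:
    degree-2 internal nodes left by the pruning are collapsed with their
    branch lengths summed.  Requires at least 2 tips, all present in the tree.
    """
    wanted = [str(t) for t in taxon_ids]
    if len(wanted) < 2:
        raise ValueError("need at least 2 taxa to prune to")
    have = set(tip_labels(tree))
    missing = [t for t in wanted if t not in have]
    if missing:
        raise KeyError(f"taxa not in tree: {missing[:5]}")
    sub = tree.extract_tree_with_taxa_labels(
        labels=set(wanted), suppress_unifurcations=True
    )
    sub.is_rooted = True
    return sub
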