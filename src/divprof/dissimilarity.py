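"""Pairwise community dissimilarity (Jaccard, UniFrac) and Ward clustering.

Four metrics, all in [0, 1], zero on identical samples, symmetric:

* unweighted Jaccard: 1 − |A∩B| / |A∪B| on presence sets;
* abundance-weighted Jaccard (Ružička): 1 − Σ min(a_i, b_i) / Σ max(a_i, b_i),
  which reduces to classical Jaccard on presence/absence data;
* unweighted UniFrac: fraction of the branch length leading to either
  sample's taxa that leads exclusively to one sample's taxa;
* weighted UniFrac (normalized): Σ l_e |p^A_e − p^B_e| / Σ l_e (p^A_e + p^B_e)
  over edges e, where p^X_e is the fraction of sample X's abundance in the
  subtree below e.  The normalization keeps all four metrics on a shared
  [0, 1] scale so dendrogram heights are comparable.

Hierarchical clustering uses Ward's minimum-variance linkage in the
"ward.D2" convention (Lance–Williams recurrence on squared dissimilarities).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "SampleTable",
    "DissimilarityMatrix",
    "Dendrogram",
    "jaccard",
    "unifrac",
    "pairwise_dissimilarity",
    "ward_cluster",
]


@dataclass(frozen=True)
class SampleTable:
    """Taxa × samples abundance matrix with unique ids on both axes."""

    taxon_ids: tuple
    sample_ids: tuple
    matrix: np.ndarray  # shape (n_taxa, n_samples)

    def __init__(self, taxon_ids, sample_ids, matrix):
        t = tuple(str(x) for x in taxon_ids)
        s = tuple(str(x) for x in sample_ids)
        M = np.asarray(matrix, dtype=float)
        if M.shape != (len(t), len(s)):
            raise ValueError(f"matrix shape {M.shape} != ({len(t)}, {len(s)})")
        if len(set(t)) != len(t) or len(set(s)) != len(s):
            raise ValueError("taxon and sample ids must be unique")
        if np.any(M < 0) or not np.all(np.isfinite(M)):
            raise ValueError("abundances must be finite and non-negative")
        empty = [s[j] for j in range(len(s)) if not np.any(M[:, j] > 0)]
        if empty:
            raise ValueError(f"samples with no positive abundance: {empty}")
        object.__setattr__(self, "taxon_ids", t)
        object.__setattr__(self, "sample_ids", s)
        object.__setattr__(self, "matrix", M)

    def sample(self, sample_id: str) -> np.ndarray:
        return self.matrix[:, self.sample_ids.index(str(sample_id))]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.taxon_ids),
                            columns=list(self.sample_ids))


@dataclass(frozen=True)
class DissimilarityMatrix:
    sample_ids: tuple
    values: np.ndarray

    def __post_init__(self):
        V = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if V.shape != (n, n):
            raise ValueError("dissimilarity matrix must be square over sample ids")
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if np.any(np.abs(np.diag(V)) > 1e-12):
            raise ValueError("dissimilarity matrix diagonal must be 0")
        if np.any(V < -1e-12) or np.any(V > 1 + 1e-12):
            raise ValueError("dissimilarities must lie in [0, 1]")
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "values", np.clip((V + V.T) / 2.0, 0.0, 1.0))

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.sample_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


def jaccard(a, b, weighted: bool = False) -> float:
    """Jaccard dissimilarity between two abundance vectors on shared taxa."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("samples must be equal-length vectors on a shared taxon order")
    if not (np.any(a > 0) or np.any(b > 0)):
        raise ValueError("both samples are empty")
    if weighted:
        num = np.minimum(a, b).sum()
        den = np.maximum(a, b).sum()
        return float(1.0 - num / den)
    pa, pb = a > 0, b > 0
    union = np.count_nonzero(pa | pb)
    inter = np.count_nonzero(pa & pb)
    return float(1.0 - inter / union)


def _edge_partition(tree: dendropy.Tree, taxon_ids: Sequence[str], a, b):
    """Per-edge (length, fraction of a below, fraction of b below)."""
    index = {str(t): i for i, t in enumerate(taxon_ids)}
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ta, tb = a.sum(), b.sum()
    if ta <= 0 or tb <= 0:
        raise ValueError("both samples must have positive total abundance")

    present = {t for t, v in zip(taxon_ids, a) if v > 0}
    present |= {t for t, v in zip(taxon_ids, b) if v > 0}
    tips_in_tree = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = sorted(present - tips_in_tree)
    if missing:
        raise KeyError(f"present taxa absent from tree: {missing[:5]}")

    rows = []  # (length, frac_a_below, frac_b_below)
    below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = index.get(node.taxon.label)
            wa = a[i] / ta if i is not None else 0.0
            wb = b[i] / tb if i is not None else 0.0
        else:
            wa = sum(below[id(c)][0] for c in node.child_nodes())
            wb = sum(below[id(c)][1] for c in node.child_nodes())
        below[id(node)] = (wa, wb)
        if node.parent_node is not None:
            length = node.edge.length if node.edge.length is not None else 0.0
            rows.append((length, wa, wb))
    return np.array(rows)


def unifrac(tree: dendropy.Tree, a, b, taxon_ids: Sequence[str], weighted: bool = False) -> float:
    """UniFrac dissimilarity between two samples on a shared tree.

    ``a`` and ``b`` are abundance vectors aligned with ``taxon_ids``; every
    present taxon must be a tip of ``tree``.
    """
    rows = _edge_partition(tree, taxon_ids, a, b)
    lengths, fa, fb = rows[:, 0], rows[:, 1], rows[:, 2]
    if weighted:
        den = (lengths * (fa + fb)).sum()
        if den <= 0:
            raise ValueError("zero total branch length under the samples")
        return float((lengths * np.abs(fa - fb)).sum() / den)
    in_a, in_b = fa > 0, fb > 0
    observed = (lengths * (in_a | in_b)).sum()
    if observed <= 0:
        raise ValueError("zero total branch length under the samples")
    unique = (lengths * (in_a ^ in_b)).sum()
    return float(unique / observed)


def pairwise_dissimilarity(
    table: SampleTable,
    metric: str = "jaccard",
    weighted: bool = False,
    tree: Optional[dendropy.Tree] = None,
) -> DissimilarityMatrix:
    """All-pairs dissimilarity over the samples of a table."""
    if metric == "jaccard":
        fn = lambda a, b: jaccard(a, b, weighted=weighted)
    elif metric == "unifrac":
        if tree is None:
            raise ValueError("unifrac requires a tree")
        fn = lambda a, b: unifrac(tree, a, b, table.taxon_ids, weighted=weighted)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    n = len(table.sample_ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = fn(table.matrix[:, i], table.matrix[:, j])
    return DissimilarityMatrix(sample_ids=table.sample_ids, values=D)


@dataclass(frozen=True)
class Dendrogram:
    """Agglomeration history: scipy linkage matrix plus leaf labels."""

    labels: tuple
    linkage: np.ndarray  # (n-1, 4) scipy format; heights non-decreasing

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2].copy()

    def to_newick(self) -> str:
        root, _ = hierarchy.to_tree(self.linkage, rd=True)

        def fmt(node, parent_height):
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                return f"{self.labels[node.id]}:{parent_height:.12g}"
            left = fmt(node.left, node.dist)
            right = fmt(node.right, node.dist)
            return f"({left},{right}):{length:.12g}"

        left = fmt(root.left, root.dist)
        right = fmt(root.right, root.dist)
        return f"({left},{right});\n"


def ward_cluster(D: DissimilarityMatrix) -> Dendrogram:
    """Ward minimum-variance clustering of a dissimilarity matrix.

    Uses the "ward.D2" convention: the Lance–Williams recurrence applied to
    the dissimilarities as Euclidean-like distances.  Deterministic for a
    given matrix.
    """
    n = len(D.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples to cluster")
    condensed = squareform(D.values, checks=False)
    link = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(labels=D.sample_ids, linkage=link)
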