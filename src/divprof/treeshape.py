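"""Tree-balance statistics: Colless' I and its Yule normalization.

Colless' I sums, over the internal nodes of a strictly bifurcating rooted
tree, the absolute difference in tip counts of the two child subtrees.  It
is a topology-only statistic (branch lengths are irrelevant) ranging from 0
for a fully balanced tree on 2^k tips to (n−1)(n−2)/2 for the caterpillar.

The Yule normalization centres by the expectation under the Yule
(pure-birth) model and scales by n:

    I_Yule = (I_C − E_Yule[I_C]) / n,
    E_Yule[I_C] = n·ln(n) + n·(γ − 1 − ln 2)

with γ the Euler–Mascheroni constant.  High values mean imbalanced,
pectinate trees; it is comparable across tree sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = [
    "PolytomyError",
    "TreeBalanceReport",
    "colless_index",
    "colless_yule_normalized",
    "yule_expected_colless",
    "tree_balance_report",
]


class PolytomyError(ValueError):
    """Raised for non-bifurcating trees when no resolution is requested."""


@dataclass(frozen=True)
class TreeBalanceReport:
    n_tips: int
    colless_raw: int
    colless_yule: float


def _resolved_copy(tree: dendropy.Tree, seed: int) -> dendropy.Tree:
    import random

    t = tree.clone(depth=1)
    t.resolve_polytomies(rng=random.Random(seed))
    return t


def colless_index(tree: dendropy.Tree, resolve_polytomies_seed: int | None = None) -> int:
    """Raw Colless' I: Σ |L − R| over internal nodes.

    Polytomies raise :class:`PolytomyError` unless a resolution seed is
    given, in which case they are randomly resolved first (logged by the
    caller via the recorded seed).
    """
    tips = {}
    internal = []
    for node in tree.postorder_node_iter():
        children = node.child_nodes()
        if not children:
            tips[id(node)] = 1
            continue
        if len(children) != 2:
            if resolve_polytomies_seed is None:
                raise PolytomyError(
                    f"node with {len(children)} children; pass a resolution seed "
                    "to resolve polytomies randomly"
                )
            return colless_index(_resolved_copy(tree, resolve_polytomies_seed))
        tips[id(node)] = sum(tips[id(c)] for c in children)
        internal.append(abs(tips[id(children[0])] - tips[id(children[1])]))
    n = tips[id(tree.seed_node)]
    if n < 2:
        raise ValueError("tree must have at least 2 tips")
    return int(sum(internal))


def yule_expected_colless(n: int) -> float:
    """E[I_C] under the Yule model for an n-tip tree."""
    return n * np.log(n) + n * (np.euler_gamma - 1.0 - np.log(2.0))


def colless_yule_normalized(
    tree: dendropy.Tree, resolve_polytomies_seed: int | None = None
) -> float:
    """(I_C − E_Yule[I_C]) / n."""
    if resolve_polytomies_seed is not None:
        tree = _resolved_copy(tree, resolve_polytomies_seed)
    ic = colless_index(tree)
    n = sum(1 for _ in tree.leaf_node_iter())
    return float((ic - yule_expected_colless(n)) / n)


def tree_balance_report(
    tree: dendropy.Tree, resolve_polytomies_seed: int | None = None
) -> TreeBalanceReport:
    if resolve_polytomies_seed is not None:
        tree = _resolved_copy(tree, resolve_polytomies_seed)
    ic = colless_index(tree)
    n = sum(1 for _ in tree.leaf_node_iter())
    return TreeBalanceReport(
        n_tips=n,
        colless_raw=ic,
        colless_yule=float((ic - yule_expected_colless(n)) / n),
    )
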