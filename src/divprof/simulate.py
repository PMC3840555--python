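"""Simulated microbial communities and phylogenies.

The generator produces the study conditions for the naïve-vs-phylogenetic
agreement experiment: communities of S OTUs drawn from one of four
rank-abundance families (log normal, geometric, log series parameterized by
Fisher's alpha, uniform), placed on random beta-splitting tree topologies
spanning balanced to caterpillar shapes, with either ultrametric (depth 1)
or non-ultrametric (i.i.d. exponential) branch lengths.

Every stochastic operation is a pure function of (inputs, seed): passing
the same seed reproduces output bitwise.  Seeds are spawned from a master
seed with :class:`numpy.random.SeedSequence` using fixed child indices.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional

import dendropy
import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .community import Community
from .phylo import prune_to_community, tip_labels
from .treeshape import colless_yule_normalized

__all__ = [
    "RankAbundanceSpec",
    "SimulatedPool",
    "PoolPair",
    "simulate_abundances",
    "fishers_alpha",
    "simulate_topology",
    "assign_branch_lengths",
    "simulate_pool",
    "simulate_pool_pair",
    "sample_otus",
    "rarefy",
]

FAMILIES = ("lognormal", "geometric", "logseries", "uniform")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class RankAbundanceSpec:
    """One rank-abundance family with its parameters.

    families and parameters:

    * ``lognormal``: i.i.d. exp(Normal(meanlog, sdlog)) abundances.
    * ``geometric``: abundance of rank r ∝ k(1−k)^(r−1), retention k ∈ (0,1).
    * ``logseries``: Fisher's log series with diversity parameter
      ``fishers_alpha`` and community size ``total_individuals`` N; the
      series parameter is x = N/(N+α).  With ``n_taxa`` set, draws n_taxa
      i.i.d. logarithmic(x) abundances (fixed richness); with ``n_taxa``
      None, realizes the full Fisher ensemble, so the species count itself
      is random with mean α·ln(1 + N/α).
    * ``uniform``: all abundances equal.
    """

    family: str
    n_taxa: Optional[int] = None
    meanlog: float = 0.0
    sdlog: float = 1.0
    k: float = 0.5
    fishers_alpha: float = 1.0
    total_individuals: int = 100_000

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {FAMILIES}")
        if self.family != "logseries" or self.n_taxa is not None:
            if self.n_taxa is None or self.n_taxa < 2:
                raise ValueError("n_taxa must be an integer >= 2")
        if self.family == "geometric" and not (0.0 < self.k < 1.0):
            raise ValueError("geometric retention k must lie in (0, 1)")
        if self.family == "lognormal" and self.sdlog < 0:
            raise ValueError("sdlog must be non-negative")
        if self.family == "logseries":
            if self.fishers_alpha <= 0:
                raise ValueError("fishers_alpha must be positive")
            if self.total_individuals < 1:
                raise ValueError("total_individuals must be >= 1")


def simulate_abundances(spec: RankAbundanceSpec, seed) -> np.ndarray:
    """Draw one abundance vector from a rank-abundance spec.

    Geometric and uniform families are deterministic given the spec (the
    randomness of *which taxon* gets which rank is applied at pool level).
    """
    rng = _rng(seed)
    if spec.family == "uniform":
        return np.ones(spec.n_taxa)
    if spec.family == "geometric":
        r = np.arange(1, spec.n_taxa + 1)
        return spec.k * (1.0 - spec.k) ** (r - 1)
    if spec.family == "lognormal":
        return np.exp(rng.normal(spec.meanlog, spec.sdlog, size=spec.n_taxa))
    # log series
    alpha, N = spec.fishers_alpha, spec.total_individuals
    x = N / (N + alpha)
    if spec.n_taxa is not None:
        return rng.logseries(x, size=spec.n_taxa).astype(float)
    # Fisher ensemble: Poisson number of species, logarithmic abundances
    s = rng.poisson(alpha * math.log1p(N / alpha))
    while s == 0:
        s = rng.poisson(alpha * math.log1p(N / alpha))
    return rng.logseries(x, size=s).astype(float)


def fishers_alpha(S: float, N: float) -> float:
    """Fisher's alpha solving S = α·ln(1 + N/α) by bracketed root-finding.

    Returns ``inf`` for the all-singletons boundary S = N (α diverges);
    raises for S > N or non-positive inputs.
    """
    if S < 1 or N < S:
        raise ValueError(f"need 1 <= S <= N, got S={S}, N={N}")
    if S == N:
        return math.inf

    def f(a):
        return a * math.log1p(N / a) - S

    lo = 1e-12
    hi = max(10.0, 10.0 * N * N / (N - S))
    while f(hi) < 0:  # pragma: no cover - bracket is generous
        hi *= 10.0
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200))


def _split_size(m: int, imbalance_param: float, rng: np.random.Generator) -> int:
    """Size of the first daughter clade when m tips split in two.

    Aldous beta-splitting: weight of split (i, m−i) ∝
    Γ(β+1+i)Γ(β+1+m−i) / (i!(m−i)!).  β → ∞ is the deterministic balanced
    split, β = −2 the caterpillar limit, β = 0 is Yule-like.
    """
    if math.isinf(imbalance_param) and imbalance_param > 0:
        return m // 2
    if imbalance_param == -2 or (math.isinf(imbalance_param) and imbalance_param < 0):
        return 1
    if imbalance_param < -2:
        raise ValueError("imbalance_param must be > -2 (or the sentinels -2/inf)")
    b = imbalance_param
    i = np.arange(1, m)
    logw = (
        gammaln(b + 1 + i)
        + gammaln(b + 1 + (m - i))
        - gammaln(i + 1)
        - gammaln(m - i + 1)
    )
    logw -= logw.max()
    w = np.exp(logw)
    return int(rng.choice(i, p=w / w.sum()))


def simulate_topology(n_tips: int, imbalance_param: float, seed) -> dendropy.Tree:
    """Random bifurcating topology on n_tips by recursive beta-splitting.

    Tips are labelled ``t0001 …`` in construction order.  Branch lengths are
    not assigned (see :func:`assign_branch_lengths`).
    """
    if n_tips < 2:
        raise ValueError("n_tips must be >= 2")
    rng = _rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    tree.is_rooted = True
    width = max(4, len(str(n_tips)))
    counter = itertools.count(1)
    stack = [(tree.seed_node, n_tips)]
    while stack:
        node, m = stack.pop()
        if m == 1:
            node.taxon = tns.new_taxon(f"t{next(counter):0{width}d}")
            continue
        i = _split_size(m, imbalance_param, rng)
        left, right = node.new_child(), node.new_child()
        stack.append((right, m - i))
        stack.append((left, i))
    return tree


def _copy_topology(tree: dendropy.Tree) -> dendropy.Tree:
    # iterative copy: dendropy's clone() recurses and overflows on deep
    # (caterpillar-like) trees with thousands of tips
    out = dendropy.Tree(taxon_namespace=tree.taxon_namespace)
    out.is_rooted = True
    stack = [(tree.seed_node, out.seed_node)]
    while stack:
        src, dst = stack.pop()
        dst.taxon = src.taxon
        dst.edge.length = src.edge.length
        for child in src.child_nodes():
            stack.append((child, dst.new_child()))
    return out


def assign_branch_lengths(tree: dendropy.Tree, mode: str, seed) -> dendropy.Tree:
    """Attach branch lengths to a topology (the input is not modified).

    ``ultrametric``: the root sits at age 1, each internal node's age is
    uniform on (0, parent age), tips at age 0 — every root-to-tip path has
    length exactly 1.  ``nonultrametric``: i.i.d. Exponential(1) length on
    every edge.
    """
    if mode not in ("ultrametric", "nonultrametric"):
        raise ValueError(f"mode must be 'ultrametric' or 'nonultrametric', got {mode!r}")
    rng = _rng(seed)
    out = _copy_topology(tree)
    if mode == "nonultrametric":
        for node in out.preorder_node_iter():
            if node.parent_node is not None:
                node.edge.length = float(rng.exponential(1.0))
        return out
    age = {id(out.seed_node): 1.0}
    for node in out.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent_age = age[id(node.parent_node)]
        node_age = 0.0 if node.is_leaf() else float(rng.uniform(0.0, parent_age))
        age[id(node)] = node_age
        node.edge.length = parent_age - node_age
    return out


@dataclass
class SimulatedPool:
    """A simulated OTU pool: community + matching tree + realized statistics."""

    community: Community
    tree: dendropy.Tree
    colless_yule: float
    realized_fishers_alpha: float
    seed: int
    config: dict = field(default_factory=dict)


def _realized_alpha(abund: np.ndarray) -> float:
    # Fisher's alpha is defined for counts; continuous abundance vectors
    # (lognormal, normalized geometric) get NaN rather than a fake value
    if not np.allclose(abund, np.round(abund)):
        return math.nan
    S = int(np.count_nonzero(abund > 0))
    N = float(np.round(abund.sum()))
    if N <= S:
        return math.inf
    return fishers_alpha(S, N)


def simulate_pool(
    spec: RankAbundanceSpec,
    imbalance_param: float,
    mode: str = "ultrametric",
    seed: int = 0,
) -> SimulatedPool:
    """Simulate one pool: topology, branch lengths, one abundance draw.

    Abundances are assigned to tips in a random permutation so that the
    deterministic families (geometric, uniform) still place their ranks
    randomly on the tree.
    """
    ss = np.random.SeedSequence(seed)
    r_topo, r_len, r_ab = (np.random.default_rng(c) for c in ss.spawn(3))
    topo = simulate_topology(spec.n_taxa, imbalance_param, r_topo)
    tree = assign_branch_lengths(topo, mode, r_len)
    abund = r_ab.permutation(simulate_abundances(spec, r_ab))
    labels = tip_labels(tree)
    community = Community(labels, abund, label=f"pool-seed{seed}")
    return SimulatedPool(
        community=community,
        tree=tree,
        colless_yule=colless_yule_normalized(tree),
        realized_fishers_alpha=_realized_alpha(abund),
        seed=seed,
        config={
            "family": spec.family,
            "spec": spec,
            "imbalance_param": imbalance_param,
            "mode": mode,
        },
    )


@dataclass
class PoolPair:
    """Two communities drawn from one spec on a shared simulated phylogeny."""

    tree: dendropy.Tree
    taxon_ids: tuple
    community_a: Community
    community_b: Community
    colless_yule: float
    realized_fishers_alpha: float
    mode: str
    spec: RankAbundanceSpec
    imbalance_param: float
    seed: int
    _patristic: Optional[np.ndarray] = None

    def patristic(self) -> np.ndarray:
        """Pool-wide patristic distance matrix (computed once, cached)."""
        if self._patristic is None:
            from .phylo import patristic_matrix

            labels, D = patristic_matrix(self.tree)
            order = {t: i for i, t in enumerate(labels)}
            idx = np.array([order[t] for t in self.taxon_ids])
            self._patristic = D[np.ix_(idx, idx)]
        return self._patristic


def simulate_pool_pair(
    spec: RankAbundanceSpec,
    imbalance_param: float,
    mode: str = "ultrametric",
    seed: int = 0,
) -> PoolPair:
    """One shared tree, two independent abundance draws from the same spec."""
    ss = np.random.SeedSequence(seed)
    r_topo, r_len, r_a, r_b = (np.random.default_rng(c) for c in ss.spawn(4))
    topo = simulate_topology(spec.n_taxa, imbalance_param, r_topo)
    tree = assign_branch_lengths(topo, mode, r_len)
    labels = tuple(tip_labels(tree))
    ab_a = r_a.permutation(simulate_abundances(spec, r_a))
    ab_b = r_b.permutation(simulate_abundances(spec, r_b))
    return PoolPair(
        tree=tree,
        taxon_ids=labels,
        community_a=Community(labels, ab_a, label="A"),
        community_b=Community(labels, ab_b, label="B"),
        colless_yule=colless_yule_normalized(tree),
        realized_fishers_alpha=_realized_alpha(ab_a),
        mode=mode,
        spec=spec,
        imbalance_param=imbalance_param,
        seed=seed,
    )


def sample_otus(pool: SimulatedPool, n: int, seed):
    """Uniform sample of n OTUs (without replacement) with its pruned tree.

    Pool abundances of the drawn OTUs are renormalized to sum to 1.
    """
    labels = pool.community.taxon_ids
    if not (2 <= n <= len(labels)):
        raise ValueError(f"n must be in [2, {len(labels)}], got {n}")
    rng = _rng(seed)
    idx = np.sort(rng.choice(len(labels), size=n, replace=False))
    chosen = [labels[i] for i in idx]
    abund = pool.community.abundances[idx]
    abund = abund / abund.sum()
    sub_tree = prune_to_community(pool.tree, chosen)
    return Community(chosen, abund, label=pool.community.label), sub_tree


def rarefy(counts, depth: int, seed) -> np.ndarray:
    """Subsample integer counts without replacement to exactly ``depth``.

    Multivariate-hypergeometric draw; returns a vector of the same length
    summing to ``depth``.
    """
    counts = np.asarray(counts)
    if not np.issubdtype(counts.dtype, np.integer):
        as_int = counts.astype(np.int64)
        if not np.allclose(as_int, counts):
            raise ValueError("rarefy requires integer counts")
        counts = as_int
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    total = int(counts.sum())
    if not (1 <= depth <= total):
        raise ValueError(f"depth must be in [1, {total}], got {depth}")
    if depth == total:
        return counts.copy()
    rng = _rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)
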