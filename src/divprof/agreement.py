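"""Do naïve and phylogenetic diversity profiles rank two samples the same way?

The experiment: draw two communities from the same rank-abundance family on
a shared simulated phylogeny; repeatedly (100 times by default) subsample
each community, and at each sensitivity value q record whether the naïve
(identity-Z Hill number) and the similarity-based (tree-derived Z) profiles
agree on which subsample is more diverse.  The per-q agreement proportion is
collected across a grid of conditions (abundance family × branch-length mode
× tree imbalance × subsample size), and summarized by its pooled mean and
empirical 2.5–97.5 percentile interval.

Subsampling draws n reads multinomially from a community's relative
abundances, so observed richness varies between subsamples the way it does
between sequencing libraries.  (Uniform draws of n distinct OTUs are also
available — ``sampling="otus"`` — but make both subsamples' richness equal
by construction, which degenerates the q = 0 comparison to a permanent tie.)

Each subsample's similarity matrix is rebuilt from its own pruned tree with
the "auto" exponential scale.  Because pruning preserves patristic
distances, this equals exp(−D_sub/s_sub) on the pool distance sub-matrix
with a per-subsample scale, which is how it is computed.

Ties: if both metrics tie the comparison counts as agreement; a tie in only
one metric counts as disagreement.
"""

from __future__ import annotations

import itertools
import logging
import math
import time
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .community import Community
from .phylo import similarity_from_tree
from .profiles import diversity, effective_number
from .simulate import RankAbundanceSpec, PoolPair, simulate_pool_pair

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_Q_VALUES",
    "AgreementResult",
    "GridCondition",
    "GridSummary",
    "compare_pair",
    "agreement_proportion",
    "default_grid",
    "run_grid",
    "imbalance_sweep",
    "skew_sweep",
    "two_proportion_z_test",
    "minimal_significant_difference",
]

#: q values tracked in the experiment: richness-like, near-Shannon, and two
#: abundance-dominated orders.
DEFAULT_Q_VALUES = (0.0, 1.1, 3.1, 5.1)

DEFAULT_POOL_SIZE = 2048
DEFAULT_SAMPLE_SIZES = (64, 128, 256, 512)
DEFAULT_N_ITERATIONS = 100

#: Imbalance levels for the beta-splitting simulator: balanced, Yule-like,
#: strongly imbalanced.  Realized Colless-Yule values are always recorded.
DEFAULT_IMBALANCE_LEVELS = (10.0, 0.0, -1.8)


def default_family_specs(pool_size: int = DEFAULT_POOL_SIZE) -> dict:
    """The four abundance families at their study parameterizations."""
    return {
        "uniform": RankAbundanceSpec("uniform", n_taxa=pool_size),
        "lognormal": RankAbundanceSpec("lognormal", n_taxa=pool_size, meanlog=0.0, sdlog=1.5),
        "geometric": RankAbundanceSpec("geometric", n_taxa=pool_size, k=0.01),
        "logseries": RankAbundanceSpec(
            "logseries", n_taxa=pool_size, fishers_alpha=1.0, total_individuals=100_000
        ),
    }


def compare_pair(
    sample_a: Community,
    tree_a,
    sample_b: Community,
    tree_b,
    q: float,
    transform: str = "exponential",
    scale="auto",
    identity_z: bool = False,
) -> dict:
    """Compare two samples at one q under both metrics.

    Each sample's similarity matrix is built from its own tree.  Returns
    ``naive_winner``/``similarity_winner`` ("A", "B" or "tie") and ``agree``.
    """
    d_naive = {}
    d_sim = {}
    for name, comm, tree in (("A", sample_a, tree_a), ("B", sample_b, tree_b)):
        present = comm.present()
        p = present.abundances / present.abundances.sum()
        d_naive[name] = diversity(p, None, q)
        if identity_z:
            d_sim[name] = d_naive[name]
        else:
            Z = similarity_from_tree(tree, transform=transform, scale=scale)
            d_sim[name] = diversity(p, Z.restrict(present.taxon_ids), q)

    def winner(d):
        if d["A"] == d["B"]:
            return "tie"
        return "A" if d["A"] > d["B"] else "B"

    nw, sw = winner(d_naive), winner(d_sim)
    return {
        "naive_winner": nw,
        "similarity_winner": sw,
        "agree": nw == sw,
        "naive": d_naive,
        "similarity": d_sim,
    }


@dataclass(frozen=True)
class AgreementResult:
    """Per-q agreement proportions for one grid condition."""

    q_values: tuple
    proportions: tuple
    n_iterations: int
    condition: dict = field(default_factory=dict)


def _subsample_indices(rng, p_full, n_sample, sampling):
    """Observed (indices, relative abundances) of one subsample."""
    if sampling == "individuals":
        counts = rng.multinomial(n_sample, p_full)
        idx = np.nonzero(counts)[0]
        obs = counts[idx].astype(float)
    elif sampling == "otus":
        idx = np.sort(rng.choice(p_full.size, size=n_sample, replace=False))
        obs = p_full[idx]
    else:
        raise ValueError(f"unknown sampling mode {sampling!r}")
    return idx, obs / obs.sum()


def agreement_proportion(
    pool: PoolPair,
    n_sample: int,
    q_values: Sequence[float] = DEFAULT_Q_VALUES,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    seed: int = 0,
    sampling: str = "individuals",
    identity_z: bool = False,
) -> AgreementResult:
    """Agreement proportions over repeated subsampling of one pool pair.

    For every iteration an independent subsample is taken from each of the
    pool's two communities; naïve and tree-similarity diversities are
    compared at every q.  Deterministic given the seed.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if not (2 <= n_sample <= len(pool.taxon_ids)):
        raise ValueError(f"n_sample must be in [2, {len(pool.taxon_ids)}]")
    q_values = tuple(float(q) for q in q_values)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    D = pool.patristic()
    p_a = pool.community_a.abundances / pool.community_a.abundances.sum()
    p_b = pool.community_b.abundances / pool.community_b.abundances.sum()

    agreements = np.zeros(len(q_values), dtype=int)
    for _ in range(n_iterations):
        div = {}
        for key, p_full in (("A", p_a), ("B", p_b)):
            idx, p_obs = _subsample_indices(rng, p_full, n_sample, sampling)
            m = idx.size
            if identity_z or m < 2:
                zp = p_obs
            else:
                # Z from the pruned tree == exp(-D_sub/s_sub): pruning
                # preserves patristic distances, s is per-subsample "auto"
                sub = D[np.ix_(idx, idx)]
                s = sub.sum() / (m * (m - 1))
                Z_vals = np.exp(-sub / (s if s > 0 else 1.0))
                np.fill_diagonal(Z_vals, 1.0)
                zp = Z_vals @ p_obs
            naive = np.array([effective_number(p_obs, p_obs, q) for q in q_values])
            sim = np.array([effective_number(p_obs, zp, q) for q in q_values])
            div[key] = (naive, sim)
        na, sa = div["A"]
        nb, sb = div["B"]
        naive_sign = np.sign(na - nb)
        sim_sign = np.sign(sa - sb)
        agreements += naive_sign == sim_sign
    return AgreementResult(
        q_values=q_values,
        proportions=tuple(agreements / n_iterations),
        n_iterations=n_iterations,
        condition={"n_sample": n_sample, "sampling": sampling, "seed": seed,
                   "identity_z": identity_z},
    )


@dataclass(frozen=True)
class GridCondition:
    family: str
    spec: RankAbundanceSpec
    mode: str
    imbalance_param: float
    n_sample: int


def default_grid(
    pool_size: int = DEFAULT_POOL_SIZE,
    sample_sizes: Sequence[int] = DEFAULT_SAMPLE_SIZES,
    imbalance_levels: Sequence[float] = DEFAULT_IMBALANCE_LEVELS,
) -> list:
    """The reconstructed study grid: 4 families × 2 branch-length modes ×
    3 imbalance levels × 4 subsample sizes (96 conditions)."""
    specs = default_family_specs(pool_size)
    grid = []
    for family, mode, imb, n in itertools.product(
        sorted(specs), ("ultrametric", "nonultrametric"), imbalance_levels, sample_sizes
    ):
        grid.append(GridCondition(family, specs[family], mode, imb, n))
    return grid


@dataclass(frozen=True)
class GridSummary:
    """Full per-condition agreement table with pooled summaries."""

    table: pd.DataFrame  # one row per condition × q
    mean_agreement: float
    percentile_low: float
    percentile_high: float

    @property
    def n_proportions(self) -> int:
        return len(self.table)


def run_grid(
    grid: Sequence[GridCondition],
    seed: int = 0,
    q_values: Sequence[float] = DEFAULT_Q_VALUES,
    n_iterations: int = DEFAULT_N_ITERATIONS,
    sampling: str = "individuals",
    identity_z: bool = False,
) -> GridSummary:
    """Run every condition of a grid and pool the agreement proportions.

    A pool pair is simulated once per (family, mode, imbalance) and shared
    by that trio's subsample sizes, so sample-size trends are measured on
    the same communities.  Per-condition seeds are spawned from the master
    seed by fixed child index, so any condition can be re-run alone.
    """
    if len(grid) == 0:
        raise ValueError("empty grid")
    ss = np.random.SeedSequence(seed)
    pool_keys = []
    for cond in grid:
        key = (cond.family, cond.mode, cond.imbalance_param)
        if key not in pool_keys:
            pool_keys.append(key)
    pool_children = ss.spawn(len(pool_keys) + len(grid))
    pools = {}
    rows = []
    for i, cond in enumerate(grid):
        key = (cond.family, cond.mode, cond.imbalance_param)
        if key not in pools:
            k = pool_keys.index(key)
            pool_seed = int(pool_children[k].generate_state(1)[0] % (2**31))
            t0 = time.perf_counter()
            pools[key] = simulate_pool_pair(
                cond.spec, cond.imbalance_param, cond.mode, seed=pool_seed
            )
            pools[key].patristic()
            logger.info(
                "pool %s: colless_yule=%.2f (%.1fs)",
                key, pools[key].colless_yule, time.perf_counter() - t0,
            )
        pool = pools[key]
        cond_seed = int(pool_children[len(pool_keys) + i].generate_state(1)[0] % (2**31))
        res = agreement_proportion(
            pool, cond.n_sample, q_values, n_iterations, seed=cond_seed,
            sampling=sampling, identity_z=identity_z,
        )
        for q, prop in zip(res.q_values, res.proportions):
            rows.append({
                "family": cond.family,
                "mode": cond.mode,
                "imbalance_param": cond.imbalance_param,
                "colless_yule": pool.colless_yule,
                "realized_fishers_alpha": pool.realized_fishers_alpha,
                "n_sample": cond.n_sample,
                "q": q,
                "agreement": prop,
                "n_iterations": n_iterations,
                "seed": cond_seed,
            })
    table = pd.DataFrame(rows)
    props = table["agreement"].to_numpy()
    lo, hi = np.percentile(props, [2.5, 97.5])
    return GridSummary(
        table=table,
        mean_agreement=float(props.mean()),
        percentile_low=float(lo),
        percentile_high=float(hi),
    )


def imbalance_sweep(
    imbalance_levels: Sequence[float] = (10.0, 0.0, -0.5, -1.0, -1.3),
    n_pools: int = 10,
    n_sample: int = 256,
    pool_size: int = DEFAULT_POOL_SIZE,
    mode: str = "ultrametric",
    seed0: int = 0,
) -> pd.DataFrame:
    """Agreement vs tree imbalance at otherwise fixed study conditions.

    Log-series (Fisher's alpha 1) communities, n_sample reads per
    subsample, ``n_pools`` replicate pool pairs per imbalance level; the
    default levels span realized Colless-Yule values from about −4
    (balanced) to about +30 (strongly imbalanced), the range real OTU trees
    occupy.  Returns one row per (level, replicate) with the realized
    imbalance and mean agreement over q.
    """
    spec = default_family_specs(pool_size)["logseries"]
    rows = []
    for beta in imbalance_levels:
        for s in range(n_pools):
            pool = simulate_pool_pair(spec, beta, mode, seed=seed0 + s)
            res = agreement_proportion(pool, n_sample, seed=seed0 + s + 100)
            rows.append({
                "imbalance_param": beta,
                "colless_yule": pool.colless_yule,
                "agreement": float(np.mean(res.proportions)),
            })
    return pd.DataFrame(rows)


def skew_sweep(
    alphas: Sequence[float] = (0.25, 1.0, 4.0, 16.0),
    n_pools: int = 10,
    n_sample: int = 256,
    pool_size: int = DEFAULT_POOL_SIZE,
    imbalance_param: float = -1.0,
    mode: str = "ultrametric",
    seed0: int = 0,
) -> pd.DataFrame:
    """Agreement vs abundance-distribution skew (log-series Fisher's alpha).

    Larger alpha means a more even community (less skew).  Fixed moderate
    imbalance (realized Colless-Yule near 9–13, the regime of the study's
    real trees).  One row per (alpha, replicate).
    """
    rows = []
    for alpha in alphas:
        spec = RankAbundanceSpec(
            "logseries", n_taxa=pool_size, fishers_alpha=alpha,
            total_individuals=100_000,
        )
        for s in range(n_pools):
            pool = simulate_pool_pair(spec, imbalance_param, mode, seed=seed0 + s)
            res = agreement_proportion(pool, n_sample, seed=seed0 + s + 100)
            rows.append({
                "fishers_alpha": alpha,
                "realized_fishers_alpha": pool.realized_fishers_alpha,
                "agreement": float(np.mean(res.proportions)),
            })
    return pd.DataFrame(rows)


def two_proportion_z_test(k1: int, n1: int, k2: int, n2: int) -> dict:
    """Two-sided Z test for equality of two population proportions.

    Pooled statistic z = (p̂1 − p̂2) / sqrt(p̄(1−p̄)(1/n1 + 1/n2)).  When the
    pooled proportion is 0 or 1 the statistic is degenerate: equal sample
    proportions give p = 1, anything else is a domain error.
    """
    for k, n in ((k1, n1), (k2, n2)):
        if n < 1 or not (0 <= k <= n):
            raise ValueError("need 0 <= k <= n and n >= 1")
    p1, p2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        if p1 == p2:
            return {"z": 0.0, "p_value": 1.0}
        raise ValueError("degenerate pooled proportion with unequal sample proportions")
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    return {"z": float(z), "p_value": float(2.0 * norm.sf(abs(z)))}


def minimal_significant_difference(
    n1: int, n2: int, p_bar: float = 0.5, alpha: float = 0.05
) -> float:
    """Smallest |p̂1 − p̂2| significant at level alpha near pooled p̄."""
    z_crit = norm.isf(alpha / 2.0)
    return float(z_crit * math.sqrt(p_bar * (1.0 - p_bar) * (1.0 / n1 + 1.0 / n2)))
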