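"""Similarity-sensitive diversity profiles (effective numbers).

The diversity of order q of a community with relative abundances p and taxon
similarity matrix Z is

    qD_Z(p) = ( Σ_i p_i (Zp)_i^(q−1) )^(1/(1−q))          q ∉ {1, ∞}
    1D_Z(p) = exp( −Σ_i p_i ln (Zp)_i )                    (limit at q = 1)
    ∞D_Z(p) = 1 / max_{i: p_i>0} (Zp)_i                    (limit at q → ∞)

where (Zp)_i = Σ_j Z_ij p_j is the *ordinariness* of taxon i: the expected
similarity of a randomly chosen individual to taxon i.  The result is an
effective number — the number of equally abundant, completely dissimilar taxa
with the same diversity — and always lies in [1, S].

With the identity similarity matrix (all distinct taxa completely
dissimilar) the profile reduces to the classical Hill numbers: q = 0 is
richness, q = 1 is exp(Shannon H), q = 2 is inverse Simpson, and q → ∞ is
the reciprocal Berger-Parker index.  Raising q shifts weight from rare to
abundant taxa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .community import Community, relative_abundances

__all__ = [
    "SimilarityMatrix",
    "DiversityProfile",
    "ordinariness",
    "diversity",
    "diversity_profile",
    "naive_profile",
    "default_q_grid",
    "Q_INF",
]

#: Sentinel for q = infinity on a profile grid.
Q_INF = math.inf

# branch to the q=1 limit form inside this window around 1
_Q_ONE_TOL = 1e-9

# evaluate large communities in log space (underflow guard for huge S)
_LOG_SPACE_S = 1000


@dataclass(frozen=True)
class SimilarityMatrix:
    """Square matrix Z of pairwise taxon similarities in [0, 1].

    ``Z[i, j]`` scores how similar taxon i is to taxon j: 0 is complete
    dissimilarity, 1 identity.  The diagonal is exactly 1.  Matrices built
    from trees are symmetric; user-supplied matrices need not be.
    """

    taxon_ids: tuple
    values: np.ndarray

    def __init__(self, taxon_ids: Sequence[str], values):
        ids = tuple(str(t) for t in taxon_ids)
        Z = np.asarray(values, dtype=float)
        n = len(ids)
        if len(set(ids)) != n:
            raise ValueError("duplicate taxon ids")
        if Z.shape != (n, n):
            raise ValueError(f"similarity matrix shape {Z.shape} != ({n}, {n})")
        if not np.all(np.isfinite(Z)) or np.any(Z < 0) or np.any(Z > 1):
            raise ValueError("similarity values must lie in [0, 1]")
        if not np.allclose(np.diag(Z), 1.0, atol=1e-12):
            raise ValueError("similarity matrix diagonal must be 1")
        Z = Z.copy()
        np.fill_diagonal(Z, 1.0)
        object.__setattr__(self, "taxon_ids", ids)
        object.__setattr__(self, "values", Z)

    @classmethod
    def identity(cls, taxon_ids: Sequence[str]) -> "SimilarityMatrix":
        """The naïve case: every pair of distinct taxa completely dissimilar."""
        return cls(taxon_ids, np.eye(len(taxon_ids)))

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def is_symmetric(self, atol: float = 1e-12) -> bool:
        return bool(np.allclose(self.values, self.values.T, atol=atol))

    def restrict(self, taxon_ids: Sequence[str]) -> "SimilarityMatrix":
        """Sub-matrix over the given taxa (must all be known), in their order."""
        index = {t: i for i, t in enumerate(self.taxon_ids)}
        try:
            idx = np.array([index[str(t)] for t in taxon_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"taxon {exc.args[0]!r} not in similarity matrix") from exc
        return SimilarityMatrix(taxon_ids, self.values[np.ix_(idx, idx)])


@dataclass(frozen=True)
class DiversityProfile:
    """Effective-number diversities of one community over a grid of q values."""

    q_grid: np.ndarray
    diversities: np.ndarray
    is_naive: bool
    community_label: str = ""

    def __post_init__(self):
        q = np.asarray(self.q_grid, dtype=float)
        d = np.asarray(self.diversities, dtype=float)
        if q.shape != d.shape or q.ndim != 1:
            raise ValueError("q grid and diversities must be equal-length vectors")
        object.__setattr__(self, "q_grid", q)
        object.__setattr__(self, "diversities", d)

    def at(self, q: float) -> float:
        """Diversity at a grid point q (exact match required)."""
        hits = np.nonzero(self.q_grid == q)[0]
        if hits.size == 0:
            raise KeyError(f"q = {q} not on the profile grid")
        return float(self.diversities[hits[0]])


def default_q_grid(q_min: float = 0.0, q_max: float = 5.0, q_step: float = 0.05) -> np.ndarray:
    """The profile grid: 0 ≤ q ≤ 5 in steps of 0.05 by default.

    The dense spacing covers the 1 ≤ q ≤ 2 window usually shown as a plot
    inset without any extra evaluation.
    """
    if q_step <= 0 or q_max < q_min or q_min < 0:
        raise ValueError("require q_min >= 0, q_max >= q_min, q_step > 0")
    n = int(round((q_max - q_min) / q_step))
    grid = q_min + q_step * np.arange(n + 1)
    return np.round(grid, 12)


def _validated_p(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p must be a non-empty vector")
    if np.any(p < 0) or not np.all(np.isfinite(p)):
        raise ValueError("p must be non-negative and finite")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("p must sum to 1")
    return p


def ordinariness(Z: Optional[SimilarityMatrix], p) -> np.ndarray:
    """(Zp)_i = Σ_j Z_ij p_j, the expected similarity of a random individual
    to taxon i.  ``Z=None`` means the identity (naïve) matrix, where the
    ordinariness of a taxon is just its own relative abundance.

    Every entry lies in [p_i, 1] since Z_ii = 1 and 0 ≤ Z_ij ≤ 1.
    """
    p = _validated_p(p)
    if Z is None:
        return p.copy()
    if Z.n_taxa != p.size:
        raise ValueError(f"Z is {Z.n_taxa}x{Z.n_taxa} but p has length {p.size}")
    return Z.values @ p


def effective_number(p: np.ndarray, zp: np.ndarray, q: float) -> float:
    """Effective number from abundances and ordinariness (low-level, no
    validation; assumes p_i > 0 for every entry)."""
    if math.isinf(q):
        return float(1.0 / zp.max())
    if abs(q - 1.0) < _Q_ONE_TOL:
        return float(np.exp(-(p * np.log(zp)).sum()))
    if p.size > _LOG_SPACE_S:
        # log-space evaluation: stable for tens of thousands of taxa
        log_sum = logsumexp(np.log(p) + (q - 1.0) * np.log(zp))
        return float(np.exp(log_sum / (1.0 - q)))
    return float((p * zp ** (q - 1.0)).sum() ** (1.0 / (1.0 - q)))


def diversity(p, Z: Optional[SimilarityMatrix], q: float) -> float:
    """Effective diversity of order q for abundances p under similarity Z.

    ``Z=None`` gives the naïve (Hill number) case.  ``q`` must be ≥ 0;
    ``math.inf`` selects the q → ∞ limit.  Taxa with p_i = 0 are ignored.
    """
    p = _validated_p(p)
    if not (q >= 0):  # also rejects NaN
        raise ValueError(f"q must be >= 0, got {q}")
    mask = p > 0
    zp_full = ordinariness(Z, p)
    return effective_number(p[mask], zp_full[mask], q)


def diversity_profile(
    community: Community,
    Z: Optional[SimilarityMatrix] = None,
    q_grid=None,
) -> DiversityProfile:
    """Diversity profile of a community over a q grid.

    ``Z`` may be None (naïve), or a similarity matrix whose taxa include the
    community's present taxa (it is restricted and reordered to match).
    """
    if q_grid is None:
        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    if q_grid.size == 0:
        raise ValueError("empty q grid")
    finite = q_grid[np.isfinite(q_grid)]
    if np.any(finite < 0) or np.any(np.diff(q_grid) < 0):
        raise ValueError("q grid must be sorted ascending with all values >= 0")

    present = community.present()
    p = relative_abundances(present)
    Zr = None if Z is None else Z.restrict(present.taxon_ids)
    d = np.array([diversity(p, Zr, q) for q in q_grid])
    return DiversityProfile(
        q_grid=q_grid,
        diversities=d,
        is_naive=Z is None,
        community_label=community.label,
    )


def naive_profile(community: Community, q_grid=None) -> DiversityProfile:
    """Profile with the identity similarity matrix (classical Hill numbers)."""
    return diversity_profile(community, Z=None, q_grid=q_grid)
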