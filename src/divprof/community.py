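"""Community abundance vectors and the classical diversity indices.

A :class:`Community` is the unit of every diversity calculation: an ordered
set of taxon labels with non-negative abundances.  Relative abundances are
always computed over *present* taxa only — taxa recorded with zero abundance
carry no information about the sampled community and are dropped (with a log
message) before any profile is evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Community",
    "EmptyCommunityError",
    "relative_abundances",
    "classical_indices",
]


class EmptyCommunityError(ValueError):
    """Raised when a community has no positive abundance."""


@dataclass(frozen=True)
class Community:
    """Taxon labels with matching non-negative abundances.

    Parameters
    ----------
    taxon_ids:
        Unique string labels, one per taxon.
    abundances:
        Non-negative counts or relative abundances, same length and order
        as ``taxon_ids``.  At least one entry must be positive.
    label:
        Optional sample name carried through to profile output.
    """

    taxon_ids: tuple
    abundances: np.ndarray
    label: str = ""

    def __init__(self, taxon_ids: Sequence[str], abundances, label: str = ""):
        ids = tuple(str(t) for t in taxon_ids)
        ab = np.asarray(abundances, dtype=float)
        if ab.ndim != 1 or len(ids) != ab.shape[0]:
            raise ValueError(
                f"{len(ids)} taxon ids but abundance vector of shape {ab.shape}"
            )
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate taxon ids")
        if np.any(ab < 0) or not np.all(np.isfinite(ab)):
            raise ValueError("abundances must be finite and non-negative")
        if not np.any(ab > 0):
            raise EmptyCommunityError("all abundances are zero")
        object.__setattr__(self, "taxon_ids", ids)
        object.__setattr__(self, "abundances", ab)
        object.__setattr__(self, "label", label)

    @property
    def n_taxa(self) -> int:
        """Number of recorded taxa (present or not)."""
        return len(self.taxon_ids)

    @property
    def richness(self) -> int:
        """Number of taxa with positive abundance."""
        return int(np.count_nonzero(self.abundances > 0))

    def present(self) -> "Community":
        """Return the community restricted to taxa with positive abundance."""
        mask = self.abundances > 0
        if mask.all():
            return self
        dropped = int((~mask).sum())
        logger.info("dropping %d zero-abundance taxa from %r", dropped, self.label)
        ids = tuple(t for t, m in zip(self.taxon_ids, mask) if m)
        return Community(ids, self.abundances[mask], label=self.label)


def relative_abundances(community: Community) -> np.ndarray:
    """Relative abundances p over present taxa.

    Zero-abundance taxa are dropped first; the result satisfies
    ``p_i > 0`` and ``sum(p) == 1`` (to machine precision).  Pairs with the
    taxon ordering of ``community.present()``.
    """
    present = community.present()
    a = present.abundances
    return a / a.sum()


def classical_indices(community: Community) -> dict:
    """Classical diversity indices of a community.

    Returns a dict with ``richness`` (S), ``shannon_H`` (−Σ p ln p),
    ``simpson_D`` (Σ p²) and ``berger_parker`` (max p).  Their effective-number
    transforms coincide with the naïve profile at q = 0, 1, 2 and ∞:
    S, exp(H), 1/D and 1/BP respectively.
    """
    p = relative_abundances(community)
    return {
        "richness": int(p.size),
        "shannon_H": float(-(p * np.log(p)).sum()),
        "simpson_D": float((p * p).sum()),
        "berger_parker": float(p.max()),
    }
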