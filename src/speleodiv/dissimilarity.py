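"""Pairwise dissimilarity: incidence-based Jaccard and 3D spatial distance.

All community comparisons in the pipeline are built from the classic
(a, b, c) pair counts of two presence/absence vectors: ``a`` species shared,
``b`` only in the first, ``c`` only in the second. Jaccard dissimilarity is
(b + c) / (a + b + c).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .datamodel import DissimilarityMatrix, IncidenceMatrix, SamplingUnit
from .errors import DegenerateInputError, ValidationError

__all__ = [
    "PairCounts", "pair_counts", "jaccard_dissimilarity", "jaccard_matrix",
    "shared_percentage", "spatial_distance_matrix",
]


@dataclass(frozen=True)
class PairCounts:
    """Set-overlap counts of two communities: shared ``a``, unique ``b``/``c``."""

    a: int
    b: int
    c: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValidationError(f"pair counts must be non-negative, got {self}")

    @property
    def total_species(self) -> int:
        return self.a + self.b + self.c


def pair_counts(x: np.ndarray, y: np.ndarray) -> PairCounts:
    """Exact (a, b, c) overlap counts for two equal-length binary vectors."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValidationError("pair_counts expects strictly binary vectors")
    a = int(np.sum((x == 1) & (y == 1)))
    b = int(np.sum((x == 1) & (y == 0)))
    c = int(np.sum((x == 0) & (y == 1)))
    return PairCounts(a, b, c)


def _require_non_empty(p: PairCounts) -> None:
    if p.total_species == 0:
        raise DegenerateInputError(
            "Jaccard undefined for two empty communities (a = b = c = 0)"
        )


def jaccard_dissimilarity(p: PairCounts) -> float:
    """Jaccard dissimilarity (b + c) / (a + b + c), in [0, 1]."""
    _require_non_empty(p)
    return (p.b + p.c) / p.total_species


def shared_percentage(p: PairCounts) -> int:
    """Percent of the pooled species the pair shares, 100 a / (a + b + c),
    rounded half-up to an integer (so 57.14 -> 57 and 14.71 -> 15)."""
    _require_non_empty(p)
    pct = Decimal(100 * p.a) / Decimal(p.total_species)
    return int(pct.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def jaccard_matrix(m: IncidenceMatrix) -> DissimilarityMatrix:
    """All pairwise Jaccard dissimilarities between sampling units."""
    values = m.values
    richness = values.sum(axis=0)
    empty = [u for u, r in zip(m.unit_ids, richness) if r == 0]
    if empty:
        raise DegenerateInputError(f"empty sampling unit(s) in Jaccard analysis: {empty}")
    shared = values.T.astype(np.int64) @ values.astype(np.int64)  # a for each pair
    union = richness[:, None] + richness[None, :] - shared
    with np.errstate(invalid="ignore"):
        d = 1.0 - shared / union
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(m.unit_ids, d, metric_name="jaccard")


def spatial_distance_matrix(units: Sequence[SamplingUnit]) -> DissimilarityMatrix:
    """Pairwise Euclidean distances (meters) in the massif's 3D frame."""
    coords = np.array([u.coord_xyz for u in units], dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff ** 2).sum(axis=-1))
    return DissimilarityMatrix([u.unit_id for u in units], d, metric_name="euclidean_3d")
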