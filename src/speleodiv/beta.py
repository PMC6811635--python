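"""Beta diversity in the Jaccard family, partitioned additively into
species turnover and nestedness.

For a pair of communities with overlap counts (a, b, c):

    total     = (b + c) / (a + b + c)                      (Jaccard)
    turnover  = 2 min(b, c) / (a + 2 min(b, c))            (replacement)
    nestedness = total - turnover                          (richness-difference residual)

The multiple-site analogue replaces (b, c) by the pairwise sums
``sum_min = sum over site pairs of min(b_ij, b_ji)`` and ``sum_max`` of the
maxima, with ``sum_Si - S_T`` (summed site richness minus pooled richness)
in place of ``a``:

    total     = (sum_min + sum_max) / ((sum_Si - S_T) + sum_min + sum_max)
    turnover  = 2 sum_min / ((sum_Si - S_T) + 2 sum_min)

This is the only partition family that is additive under Jaccard; it
degrades gracefully to the pairwise formulas at n = 2 sites.

The module also builds the study's comparison sets: *vertical* sets pair each
shallow-upper unit with the pooled deep-core strata of a deep cave (one set
per shallow unit x deep cave), plus a single set of all slope units;
*horizontal* sets collect, per depth stratum, every unit labelled with that
stratum regardless of lateral position (slope caves included where their
stratum labels say so).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datamodel import IncidenceMatrix, SamplingUnit, STRATA
from .dissimilarity import PairCounts
from .errors import DegenerateInputError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "BDPartition", "MultiSiteAggregates", "ComparisonSet",
    "pairwise_partition", "multisite_aggregates", "multisite_partition",
    "partition_units", "build_vertical_sets", "build_horizontal_sets",
    "average_bd", "restrict_sets",
]


@dataclass(frozen=True)
class BDPartition:
    """Total beta diversity with its additive turnover and nestedness parts."""

    total: float
    turnover: float
    nestedness: float
    n_sites: int
    family: str = "jaccard"

    def __post_init__(self) -> None:
        if abs(self.turnover + self.nestedness - self.total) > 1e-9:
            raise ValidationError(
                f"partition not additive: {self.turnover} + {self.nestedness} != {self.total}"
            )
        if not (-1e-12 <= self.nestedness and self.nestedness <= self.total <= 1 + 1e-12):
            raise ValidationError(f"partition out of range: {self}")

    def as_dict(self) -> dict:
        return {
            "total": self.total, "turnover": self.turnover,
            "nestedness": self.nestedness, "n_sites": self.n_sites,
            "family": self.family,
        }


@dataclass(frozen=True)
class MultiSiteAggregates:
    """Integer building blocks of the multiple-site partition."""

    S_T: int       # pooled species richness of the site set
    sum_Si: int    # sum of per-site richness
    sum_min: int   # sum over site pairs of min(b_ij, b_ji)
    sum_max: int   # sum over site pairs of max(b_ij, b_ji)

    def __post_init__(self) -> None:
        if min(self.S_T, self.sum_Si, self.sum_min, self.sum_max) < 0:
            raise ValidationError(f"aggregates must be non-negative: {self}")
        if self.sum_Si < self.S_T:
            raise ValidationError(f"sum_Si < S_T impossible: {self}")
        if self.sum_min > self.sum_max:
            raise ValidationError(f"sum_min > sum_max impossible: {self}")


@dataclass(frozen=True)
class ComparisonSet:
    """A named set of sampling units over which one BD value is computed."""

    set_id: str
    setting: str  # "vertical_central" | "vertical_slope" | "horizontal"
    stratum_or_combo: str
    unit_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.unit_ids) < 2:
            raise ValidationError(f"comparison set {self.set_id!r} needs >= 2 units")


def pairwise_partition(p: PairCounts) -> BDPartition:
    """Partition the Jaccard dissimilarity of one community pair."""
    if p.total_species == 0:
        raise DegenerateInputError("partition undefined for two empty communities")
    total = (p.b + p.c) / p.total_species
    mn = min(p.b, p.c)
    turnover = 2 * mn / (p.a + 2 * mn) if mn else 0.0
    return BDPartition(total, turnover, total - turnover, n_sites=2)


def multisite_aggregates(m: IncidenceMatrix, unit_ids: Sequence[str] | None = None) -> MultiSiteAggregates:
    """Exact integer aggregates over all unordered pairs of the chosen units."""
    values = m.values if unit_ids is None else m.data[list(unit_ids)].to_numpy(dtype=np.int8)
    if values.shape[1] < 2:
        raise ValidationError("multisite aggregates need >= 2 units")
    richness = values.sum(axis=0)
    if (richness == 0).any():
        which = [u for u, r in zip(unit_ids or m.unit_ids, richness) if r == 0]
        raise DegenerateInputError(f"empty sampling unit(s) in multisite set: {which}")
    return MultiSiteAggregates(*_aggregates_from_array(values))


def _aggregates_from_array(values: np.ndarray) -> tuple[int, int, int, int]:
    """(S_T, sum_Si, sum_min, sum_max) from a binary species x site array."""
    richness = values.sum(axis=0, dtype=np.int64)
    shared = values.T.astype(np.int64) @ values.astype(np.int64)
    b = richness[:, None] - shared  # b[i, j] = species at i but not j
    iu = np.triu_indices(values.shape[1], k=1)
    bij, bji = b[iu], b.T[iu]
    return (
        int((values.sum(axis=1) > 0).sum()),
        int(richness.sum()),
        int(np.minimum(bij, bji).sum()),
        int(np.maximum(bij, bji).sum()),
    )


def multisite_partition(agg: MultiSiteAggregates) -> BDPartition:
    """Multiple-site Jaccard beta diversity and its additive partition."""
    shared_mass = agg.sum_Si - agg.S_T
    denom = shared_mass + agg.sum_min + agg.sum_max
    if denom == 0:
        # All sites identical with a single species: no beta diversity.
        return BDPartition(0.0, 0.0, 0.0, n_sites=2)
    total = (agg.sum_min + agg.sum_max) / denom
    turnover = 2 * agg.sum_min / (shared_mass + 2 * agg.sum_min) if agg.sum_min else 0.0
    return BDPartition(total, turnover, total - turnover, n_sites=2)


def partition_units(m: IncidenceMatrix, unit_ids: Sequence[str] | None = None) -> BDPartition:
    """Multiple-site partition of a unit set, in one call."""
    ids = list(unit_ids) if unit_ids is not None else m.unit_ids
    part = multisite_partition(multisite_aggregates(m, ids))
    return BDPartition(part.total, part.turnover, part.nestedness, n_sites=len(ids))


def average_bd(partitions: Sequence[BDPartition]) -> BDPartition:
    """Componentwise arithmetic mean of several partitions.

    Additivity survives the mean exactly, because each member is additive.
    """
    if not partitions:
        raise ValidationError("average_bd of an empty list")
    total = float(np.mean([p.total for p in partitions]))
    turnover = float(np.mean([p.turnover for p in partitions]))
    return BDPartition(
        total, turnover, total - turnover,
        n_sites=int(round(np.mean([p.n_sites for p in partitions]))),
    )


def build_vertical_sets(units: Sequence[SamplingUnit]) -> list[ComparisonSet]:
    """Comparison sets for the vertical analysis.

    One set per (shallow-upper unit, deep cave): that shallow unit together
    with all deep-core strata of the cave — e.g. 5 shallow units x 2 deep
    caves -> 10 sets of 6 units. A deep cave is expected to contribute five
    deep strata; fewer triggers a warning, and the set is built from what is
    there. One extra set pools all slope units.
    """
    shallow = [u for u in units if u.zone == "shallow_upper"]
    slope = [u for u in units if u.zone == "slope"]
    deep_by_cave: dict[str, list[SamplingUnit]] = {}
    for u in units:
        if u.zone == "deep_core":
            deep_by_cave.setdefault(u.cave_code, []).append(u)
    sets: list[ComparisonSet] = []
    for cave, deep_units in sorted(deep_by_cave.items()):
        if len(deep_units) != 5:
            logger.warning(
                "deep cave %s has %d deep strata (expected 5); building sets from those",
                cave, len(deep_units),
            )
        deep_ids = tuple(sorted(u.unit_id for u in deep_units))
        for su in sorted(shallow, key=lambda u: u.unit_id):
            sets.append(
                ComparisonSet(
                    set_id=f"vertical:{su.unit_id}+{cave}",
                    setting="vertical_central",
                    stratum_or_combo=f"{su.unit_id}+{cave}",
                    unit_ids=(su.unit_id, *deep_ids),
                )
            )
    if len(slope) >= 2:
        sets.append(
            ComparisonSet(
                set_id="vertical:slope",
                setting="vertical_slope",
                stratum_or_combo="slope",
                unit_ids=tuple(sorted(u.unit_id for u in slope)),
            )
        )
    return sets


def build_horizontal_sets(units: Sequence[SamplingUnit]) -> list[ComparisonSet]:
    """One comparison set per depth stratum, pooling all units carrying that
    stratum label regardless of zone; strata with fewer than two units are
    skipped with a warning."""
    sets = []
    for stratum in STRATA:
        members = sorted(u.unit_id for u in units if u.stratum == stratum)
        if len(members) < 2:
            if members:
                logger.warning("stratum %s has a single unit; skipped", stratum)
            continue
        sets.append(
            ComparisonSet(
                set_id=f"horizontal:{stratum}",
                setting="horizontal",
                stratum_or_combo=stratum,
                unit_ids=tuple(members),
            )
        )
    return sets


def restrict_sets(sets: Sequence[ComparisonSet], available: Sequence[str]) -> list[ComparisonSet]:
    """Rebuild sets from units surviving in the incidence matrix (e.g. after
    empty units were dropped); sets left with < 2 units are removed, with a
    warning either way."""
    available_set = set(available)
    out = []
    for cs in sets:
        kept = tuple(u for u in cs.unit_ids if u in available_set)
        if kept != cs.unit_ids:
            logger.warning(
                "set %s: %d unit(s) missing from matrix", cs.set_id, len(cs.unit_ids) - len(kept)
            )
        if len(kept) >= 2:
            out.append(ComparisonSet(cs.set_id, cs.setting, cs.stratum_or_combo, kept))
    return out
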