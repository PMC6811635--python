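"""From raw trap catches to the matrices the analyses consume.

The chain is: pool the two trapping seasons, correct for unequal sampling
effort (traps x passage length), restrict to obligate subterranean species,
and reduce to presence/absence. Effort correction rescales columns but never
changes which cells are zero, so every incidence-based statistic downstream
is invariant to it.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceMatrix,
    IncidenceMatrix,
    SamplingUnit,
    SpeciesRecord,
    assign_stratum,  # re-exported: part of this stage's surface
)
from .errors import FormatError, ReferenceError_, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "pool_seasons", "normalize_abundance", "filter_obligates",
    "to_incidence", "assign_stratum", "pool_units",
]


def pool_seasons(
    samples: Sequence["object"],
    species_ids: Sequence[str],
    unit_ids: Sequence[str],
) -> AbundanceMatrix:
    """Sum trap catches over the two seasons into a species x unit matrix.

    Parameters
    ----------
    samples
        ``TrapSample`` records; the (unit, season, species) key must be
        unique (duplicates must be pre-aggregated upstream).
    species_ids, unit_ids
        The full ordered label sets; records referencing anything else raise.
        Units with no records at all come out as all-zero columns (flagged
        later by :func:`to_incidence`).
    """
    species_index = {s: i for i, s in enumerate(species_ids)}
    unit_index = {u: j for j, u in enumerate(unit_ids)}
    grid = np.zeros((len(species_ids), len(unit_ids)))
    seen: set[tuple[str, str, str]] = set()
    for rec in samples:
        if rec.species_id not in species_index:
            raise ReferenceError_(f"unknown species_id {rec.species_id!r}")
        if rec.unit_id not in unit_index:
            raise ReferenceError_(f"unknown unit_id {rec.unit_id!r}")
        key = (rec.unit_id, rec.season, rec.species_id)
        if key in seen:
            raise FormatError(f"duplicate trap record for {key}; pre-aggregate per season")
        seen.add(key)
        grid[species_index[rec.species_id], unit_index[rec.unit_id]] += rec.count
    return AbundanceMatrix(
        pd.DataFrame(grid, index=list(species_ids), columns=list(unit_ids)),
        is_normalized=False,
    )


def normalize_abundance(
    matrix: AbundanceMatrix, units: Sequence[SamplingUnit]
) -> AbundanceMatrix:
    """Correct pooled counts for sampling effort.

    Each cell becomes ``count / (n_traps * passage_length_m)`` of its unit:
    individuals per sampled trap per meter of cave passage. The zero pattern
    is untouched, so incidence-based results do not depend on this step.
    """
    if matrix.is_normalized:
        raise ValidationError("matrix is already normalized")
    effort = {u.unit_id: u.n_traps * u.passage_length_m for u in units}
    missing = [u for u in matrix.unit_ids if u not in effort]
    if missing:
        raise ValidationError(f"missing effort data (n_traps, passage_length_m) for unit(s) {missing}")
    scale = np.array([effort[u] for u in matrix.unit_ids])
    return AbundanceMatrix(matrix.data / scale, is_normalized=True)


def filter_obligates(
    matrix: AbundanceMatrix | IncidenceMatrix, species: Sequence[SpeciesRecord]
) -> AbundanceMatrix | IncidenceMatrix:
    """Keep only obligate subterranean species (troglobionts).

    Non-obligates are dropped row-wise; columns are untouched. Every species
    row must be classified — an unclassified species aborts the analysis
    rather than entering it silently.
    """
    eco = {s.species_id: s.eco_class for s in species}
    unknown = [s for s in matrix.species_ids if s not in eco]
    if unknown:
        raise ValidationError(f"species without eco_class: {unknown}")
    keep = [s for s in matrix.species_ids if eco[s] == "obligate"]
    data = matrix.data.loc[keep]
    if isinstance(matrix, IncidenceMatrix):
        return IncidenceMatrix(data)
    return AbundanceMatrix(data, is_normalized=matrix.is_normalized)


def to_incidence(matrix: AbundanceMatrix | IncidenceMatrix, drop_empty_units: bool = False) -> IncidenceMatrix:
    """Reduce abundances to presence/absence (cell > 0 becomes 1).

    With ``drop_empty_units`` all-zero columns are removed (with a logged
    warning); otherwise they are retained and rejected later by any pairwise
    statistic that needs non-empty communities.
    """
    binary = (matrix.data.to_numpy(dtype=float) > 0).astype(np.int8)
    df = pd.DataFrame(binary, index=matrix.species_ids, columns=matrix.unit_ids)
    if drop_empty_units:
        empty = [u for u in df.columns if df[u].sum() == 0]
        if empty:
            logger.warning("dropping %d empty sampling unit(s): %s", len(empty), empty)
            df = df.drop(columns=empty)
    return IncidenceMatrix(df)


def pool_units(matrix: IncidenceMatrix, groups: dict[str, Sequence[str]]) -> IncidenceMatrix:
    """Union member units of each group into one pooled community column.

    Used to form zone-level communities (e.g. all slope units pooled) for
    shared-species summaries.
    """
    cols = {}
    for name, members in groups.items():
        missing = [u for u in members if u not in matrix.unit_ids]
        if missing:
            raise ReferenceError_(f"group {name!r}: unknown unit(s) {missing}")
        cols[name] = (matrix.data[list(members)].to_numpy().sum(axis=1) > 0).astype(np.int8)
    return IncidenceMatrix(pd.DataFrame(cols, index=matrix.species_ids))
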