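"""Fill-preserving null models and significance of beta-diversity patterns.

The null hypothesis is unrestricted faunal connectivity: species move freely
through the fissure network of the massif, so any arrangement of the observed
number of presences over the species x unit grid is equally likely. The
default randomization therefore keeps only the *fill* (total number of
presences) fixed and scatters the presences uniformly over all cells —
neither per-unit richness nor per-species occurrence counts are constrained.
A stricter variant that preserves per-species occurrence totals (shuffling
each species' occurrences over units) is available as ``scheme="per_species"``
but is not the default.

Observed statistics (multiple-site BD total / turnover / nestedness) are
compared against the null ensemble two-sided with the add-one convention:

    p = min(1, 2 * min(#{null >= obs} + 1, #{null <= obs} + 1) / (n_null + 1))

Stars follow the usual figure convention: ``**`` p < 0.01, ``*`` p < 0.05.
One whole-massif matrix is randomized per replicate and every comparison set
is evaluated on that same replicate, preserving correlation across settings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .beta import (
    BDPartition,
    ComparisonSet,
    _aggregates_from_array,
    average_bd,
    multisite_partition,
    MultiSiteAggregates,
)
from .datamodel import IncidenceMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = ["NullEnsemble", "randomize_matrix", "null_test", "run_fig5_battery", "stars"]

STATISTICS = ("total", "turnover", "nestedness")


def stars(p: float) -> str:
    """Significance stars: ``**`` for p < 0.01, ``*`` for p < 0.05, else ``""``."""
    return "**" if p < 0.01 else "*" if p < 0.05 else ""


@dataclass(frozen=True)
class NullEnsemble:
    """Observed statistic, its null distribution and two-sided significance."""

    statistic_name: str
    observed: float
    null_values: np.ndarray
    n_null: int
    p_value: float
    seed: int
    direction: str = "two_sided"

    def __post_init__(self) -> None:
        if len(self.null_values) != self.n_null:
            raise ValidationError("null_values length must equal n_null")
        if not 1 / (self.n_null + 1) - 1e-12 <= self.p_value <= 1 + 1e-12:
            raise ValidationError(f"p-value {self.p_value} outside [1/(n+1), 1]")

    @property
    def stars(self) -> str:
        return stars(self.p_value)

    def summary(self) -> dict:
        nv = np.asarray(self.null_values, dtype=float)
        return {
            "statistic": self.statistic_name,
            "observed": self.observed,
            "null_mean": float(nv.mean()),
            "null_q025": float(np.quantile(nv, 0.025)),
            "null_q975": float(np.quantile(nv, 0.975)),
            "n_null": self.n_null,
            "p_value": self.p_value,
            "direction": self.direction,
            "stars": self.stars,
            "seed": self.seed,
        }


def _random_fill(shape: tuple[int, int], fill: int, rng: np.random.Generator) -> np.ndarray:
    cells = shape[0] * shape[1]
    if fill > cells:
        raise ValidationError(f"fill {fill} exceeds cell count {cells}")
    flat = np.zeros(cells, dtype=np.int8)
    flat[rng.choice(cells, size=fill, replace=False)] = 1
    return flat.reshape(shape)


def _random_per_species(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.zeros_like(values)
    n_units = values.shape[1]
    for i, k in enumerate(values.sum(axis=1)):
        out[i, rng.choice(n_units, size=int(k), replace=False)] = 1
    return out


def randomize_matrix(
    m: IncidenceMatrix,
    rng: np.random.Generator | int,
    scheme: str = "fill",
) -> IncidenceMatrix:
    """One null replicate of an incidence matrix.

    ``scheme="fill"`` (default) keeps only the total number of presences and
    places them uniformly at random over all cells; ``scheme="per_species"``
    keeps each species' number of occupied units and shuffles which units.
    Species and unit labels are retained.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    values = m.values
    if scheme == "fill":
        new = _random_fill(values.shape, int(values.sum()), rng)
    elif scheme == "per_species":
        new = _random_per_species(values, rng)
    else:
        raise ValidationError(f"unknown randomization scheme {scheme!r}")
    return IncidenceMatrix(pd.DataFrame(new, index=m.species_ids, columns=m.unit_ids))


def _set_statistic(values: np.ndarray, col_idx: np.ndarray) -> BDPartition | None:
    """Multisite partition of one column subset, ignoring empty units.

    Returns None when fewer than two units are non-empty (the caller decides
    whether to resample or record a missing replicate)."""
    sub = values[:, col_idx]
    non_empty = sub.sum(axis=0) > 0
    if non_empty.sum() < 2:
        return None
    if not non_empty.all():
        sub = sub[:, non_empty]
    return multisite_partition(MultiSiteAggregates(*_aggregates_from_array(sub)))


def _evaluate(values: np.ndarray, groups: Sequence[Sequence[np.ndarray]]) -> list[BDPartition | None]:
    """Per group of column-index sets: mean partition over the sets (None if
    any set degenerates)."""
    out: list[BDPartition | None] = []
    for col_sets in groups:
        parts = []
        for idx in col_sets:
            part = _set_statistic(values, idx)
            if part is None:
                parts = None
                break
            parts.append(part)
        out.append(average_bd(parts) if parts else None)
    return out


def _column_indices(m: IncidenceMatrix, comparison: ComparisonSet | Sequence[ComparisonSet]) -> list[np.ndarray]:
    sets = [comparison] if isinstance(comparison, ComparisonSet) else list(comparison)
    index = {u: i for i, u in enumerate(m.unit_ids)}
    out = []
    for cs in sets:
        missing = [u for u in cs.unit_ids if u not in index]
        if missing:
            raise ValidationError(f"set {cs.set_id!r}: unknown unit(s) {missing}")
        out.append(np.array([index[u] for u in cs.unit_ids]))
    return out


def _two_sided_p(observed: float, nulls: np.ndarray) -> float:
    n = len(nulls)
    c_ge = int((nulls >= observed).sum())
    c_le = int((nulls <= observed).sum())
    return min(1.0, 2 * min(c_ge + 1, c_le + 1) / (n + 1))


def null_test(
    m: IncidenceMatrix,
    comparison: ComparisonSet | Sequence[ComparisonSet],
    n_null: int = 9999,
    seed: int = 0,
    scheme: str = "fill",
) -> dict[str, NullEnsemble]:
    """Test one BD setting against the fill-preserving null.

    ``comparison`` is a single set (horizontal stratum, slope) or a list of
    sets whose partitions are averaged (the vertical-central setting, one set
    per shallow unit x deep cave). The whole matrix is randomized per
    replicate, the statistic recomputed, and two-sided add-one p-values are
    returned for total, turnover and nestedness. Replicates in which a set
    loses too many units to evaluate are resampled (count logged).
    """
    col_sets = _column_indices(m, comparison)
    values = m.values
    observed = _evaluate(values, [col_sets])[0]
    if observed is None:
        raise ValidationError("observed comparison set has < 2 non-empty units")
    rng = np.random.default_rng(seed)
    nulls = np.empty((n_null, 3))
    resampled = 0
    i = 0
    while i < n_null:
        replicate = _random_fill(values.shape, int(values.sum()), rng) if scheme == "fill" \
            else _random_per_species(values, rng)
        part = _evaluate(replicate, [col_sets])[0]
        if part is None:
            resampled += 1
            if resampled > 100 * n_null:  # pragma: no cover - pathological fill
                raise ValidationError("null replicates degenerate; fill too sparse")
            continue
        nulls[i] = (part.total, part.turnover, part.nestedness)
        i += 1
    if resampled:
        logger.warning("resampled %d degenerate null replicate(s)", resampled)
    out = {}
    for j, name in enumerate(STATISTICS):
        obs = getattr(observed, name)
        out[name] = NullEnsemble(
            statistic_name=name,
            observed=obs,
            null_values=nulls[:, j].copy(),
            n_null=n_null,
            p_value=_two_sided_p(obs, nulls[:, j]),
            seed=seed,
        )
    return out


def run_fig5_battery(
    m: IncidenceMatrix,
    sets: Sequence[ComparisonSet],
    n_null: int = 9999,
    seed: int = 0,
    scheme: str = "fill",
) -> pd.DataFrame:
    """Observed-vs-null table over every BD setting.

    Horizontal sets and the slope set are tested individually; all
    vertical-central sets are averaged into one setting. One randomized
    massif matrix per replicate serves every setting, so the table's rows
    share their null stream. Returns one row per setting x statistic with
    the observed value, null mean and 2.5/97.5 percentiles, p and stars.
    """
    settings: list[tuple[str, list[ComparisonSet]]] = []
    central = [cs for cs in sets if cs.setting == "vertical_central"]
    if central:
        settings.append(("vertical_central", central))
    for cs in sets:
        if cs.setting != "vertical_central":
            settings.append((cs.set_id, [cs]))

    groups = [_column_indices(m, group) for _, group in settings]
    values = m.values
    observed = _evaluate(values, groups)
    for (name, _), obs in zip(settings, observed):
        if obs is None:
            raise ValidationError(f"setting {name!r} has < 2 non-empty units in observed data")

    rng = np.random.default_rng(seed)
    nulls = np.full((len(settings), n_null, 3), np.nan)
    for r in range(n_null):
        replicate = _random_fill(values.shape, int(values.sum()), rng) if scheme == "fill" \
            else _random_per_species(values, rng)
        for s, part in enumerate(_evaluate(replicate, groups)):
            if part is not None:
                nulls[s, r] = (part.total, part.turnover, part.nestedness)

    rows = []
    for s, ((name, group), obs) in enumerate(zip(settings, observed)):
        for j, stat in enumerate(STATISTICS):
            null_j = nulls[s, :, j]
            null_j = null_j[~np.isnan(null_j)]
            dropped = n_null - len(null_j)
            if dropped:
                logger.warning("setting %s: %d degenerate null replicate(s) dropped", name, dropped)
            obs_value = getattr(obs, stat)
            p = _two_sided_p(obs_value, null_j)
            rows.append(
                {
                    "setting": name,
                    "n_sets": len(group),
                    "statistic": stat,
                    "observed": obs_value,
                    "null_mean": float(null_j.mean()),
                    "null_q025": float(np.quantile(null_j, 0.025)),
                    "null_q975": float(np.quantile(null_j, 0.975)),
                    "n_null": int(len(null_j)),
                    "p_value": p,
                    "stars": stars(p),
                    "seed": seed,
                }
            )
    return pd.DataFrame(rows)
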