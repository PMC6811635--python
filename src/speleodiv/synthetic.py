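"""Synthetic cave-community data with the structure each connectivity
hypothesis implies.

The generator emulates a stratified survey of one karst massif: 20 sampling
units — five slope caves, five shallow-upper units and ten deep-core units
(five depth strata in each of two deep caves) — and 34 obligate subterranean
species, plus trapping effort, passage lengths and 3D coordinates. Four
scenarios shape where species occur:

``bfn_random``
    The null hypothesis itself: a fixed number of presences scattered
    uniformly over the species x unit grid (unrestricted connectivity).
``deep_turnover``
    A fraction ``effect_size`` of the species are endemic to the deep core,
    split between the two deep caves, so communities in the same deep
    stratum differ by species replacement.
``nested_central``
    Shallow-upper communities are drawn (with probability ``effect_size``
    per species) from the pooled species set of their deep cave, making them
    subsamples of the deep-core fauna.
``slope_distinct``
    Slope caves draw from a species pool disjoint (at ``effect_size`` = 1)
    from the rest of the massif, mimicking an ecologically distinct slope
    fauna.

Default occupancy (0.3) is calibrated so per-unit richness spans roughly
4-18 species, the range of the study system it emulates. All randomness
descends from one seed through spawned child generators, so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    AbundanceMatrix,
    IncidenceMatrix,
    STRATA,
    SamplingUnit,
    SpeciesRecord,
    TrapSample,
    assign_stratum,
)
from .errors import ValidationError

__all__ = ["ScenarioSpec", "ScenarioData", "generate_scenario", "generate_trap_samples", "SCENARIOS"]

SCENARIOS = ("bfn_random", "deep_turnover", "nested_central", "slope_distinct")

# Depth-stratum midpoints (m below the cave entrance) used for stratum units.
_STRATUM_MIDPOINTS = {"0-50": 25.0, "50-100": 75.0, "100-200": 150.0,
                      "200-330": 265.0, "330-500": 415.0, ">500": 600.0}


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of one synthetic dataset."""

    scenario: str = "bfn_random"
    n_species: int = 34          # obligate subterranean species
    n_non_obligate: int = 26     # extra surface-associated species (dropped by the obligate filter)
    n_shallow: int = 5
    n_deep_caves: int = 2
    n_strata_per_deep_cave: int = 5
    n_slope: int = 5
    occupancy: float = 0.3       # per-cell presence probability of the unstructured background
    fill: int | None = None      # exact fill for bfn_random; defaults to round(occupancy * cells)
    effect_size: float = 0.6     # strength of the scenario's structure, in [0, 1]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if not 0.0 <= self.effect_size <= 1.0:
            raise ValidationError("effect_size must lie in [0, 1]")
        if self.n_shallow < self.n_deep_caves:
            raise ValidationError("need at least one shallow unit per deep cave")
        if not 0 < self.occupancy < 1:
            raise ValidationError("occupancy must lie in (0, 1)")

    @property
    def n_units(self) -> int:
        return self.n_shallow + self.n_deep_caves * self.n_strata_per_deep_cave + self.n_slope


@dataclass
class ScenarioData:
    """One generated dataset: analysis-ready incidence plus its provenance."""

    incidence: IncidenceMatrix       # obligate species only
    abundance: AbundanceMatrix       # raw counts, all species
    units: list[SamplingUnit]
    species: list[SpeciesRecord]
    spec: ScenarioSpec = field(repr=False, default=None)  # type: ignore[assignment]


def _make_units(spec: ScenarioSpec, rng: np.random.Generator) -> list[SamplingUnit]:
    units: list[SamplingUnit] = []
    massif_top = 1200.0  # m a.s.l., nominal altitude of the plateau

    def effort() -> tuple[int, float]:
        return int(rng.integers(6, 76)), float(np.round(rng.uniform(20, 500), 1))

    deep_strata = STRATA[1:1 + spec.n_strata_per_deep_cave]
    # Deep caves: entrance (0-50) unit in the shallow upper zone + deep strata.
    for c in range(spec.n_deep_caves):
        cave = f"C{c + 1}"
        x, y = float(rng.uniform(0, 3000)), float(rng.uniform(0, 3000))
        entrance_alt = massif_top + float(rng.uniform(-60, 60))
        n_traps, length = effort()
        units.append(SamplingUnit(f"{cave}_0-50", cave, "shallow_upper", 25.0,
                                  (x, y, entrance_alt - 25.0), n_traps, length, "0-50"))
        for stratum in deep_strata:
            depth = _STRATUM_MIDPOINTS[stratum]
            n_traps, length = effort()
            units.append(SamplingUnit(f"{cave}_{stratum}", cave, "deep_core", depth,
                                      (x, y, entrance_alt - depth), n_traps, length, stratum))
    # Remaining shallow-upper units: entire small plateau caves.
    for c in range(spec.n_deep_caves, spec.n_shallow):
        cave = f"C{c + 1}"
        x, y = float(rng.uniform(0, 3000)), float(rng.uniform(0, 3000))
        entrance_alt = massif_top + float(rng.uniform(-60, 60))
        n_traps, length = effort()
        units.append(SamplingUnit(cave, cave, "shallow_upper", 25.0,
                                  (x, y, entrance_alt - 25.0), n_traps, length, "0-50"))
    # Slope caves: laterally offset, entrances well below the massif top.
    # Their massif-level stratum label maps entrance depth below the top onto
    # the same six strata used for the central caves.
    for s in range(spec.n_slope):
        cave = f"S{s + 1}"
        x, y = float(rng.uniform(5000, 8000)), float(rng.uniform(0, 3000))
        entrance_below_top = float(rng.uniform(250, 950))
        own_depth = float(np.round(rng.uniform(5, 40), 1))
        n_traps, length = effort()
        units.append(SamplingUnit(cave, cave, "slope", own_depth,
                                  (x, y, massif_top - entrance_below_top - own_depth),
                                  n_traps, length, assign_stratum(entrance_below_top)))
    return units


def _unit_roles(units: Sequence[SamplingUnit]) -> dict[str, list[int]]:
    roles = {"slope": [], "shallow_upper": [], "deep_core": []}
    for j, u in enumerate(units):
        roles[u.zone].append(j)
    return roles


def _incidence(spec: ScenarioSpec, units: Sequence[SamplingUnit],
               rng: np.random.Generator) -> np.ndarray:
    S, U = spec.n_species, len(units)
    p0, e = spec.occupancy, spec.effect_size
    roles = _unit_roles(units)
    deep_by_cave: dict[str, list[int]] = {}
    for j in roles["deep_core"]:
        deep_by_cave.setdefault(units[j].cave_code, []).append(j)
    caves = sorted(deep_by_cave)

    if spec.scenario == "bfn_random":
        fill = spec.fill if spec.fill is not None else int(round(p0 * S * U))
        if fill > S * U:
            raise ValidationError(f"fill {fill} exceeds {S}x{U} grid")
        flat = np.zeros(S * U, dtype=np.int8)
        flat[rng.choice(S * U, size=fill, replace=False)] = 1
        return flat.reshape((S, U))

    grid = (rng.random((S, U)) < p0).astype(np.int8)

    if spec.scenario == "deep_turnover":
        n_endemic = int(round(e * S))
        endemics = np.arange(n_endemic)
        for rank, i in enumerate(endemics):
            grid[i, :] = 0
            cave = caves[rank % len(caves)]
            for j in deep_by_cave[cave]:
                grid[i, j] = 1 if rng.random() < 0.95 else 0

    elif spec.scenario == "nested_central":
        # Vertical coherence in the central massif: each deep cave carries a
        # species pool that thins upward as nested subsets (species ranges
        # extend from the deep core toward the entrance), and every
        # shallow-upper community is a subsample of its cave's deep pool.
        # effect_size mixes this coherent pattern with the unstructured
        # background cell-by-cell.
        coherent = np.zeros_like(grid)
        retention = 0.85
        for cave in caves:
            pool = rng.random(S) < min(0.95, p0 * 1.8)
            ordered = sorted(deep_by_cave[cave], key=lambda k: -units[k].depth_m)
            current = pool.copy()
            for j in ordered:  # deepest first, thinning upward
                coherent[current, j] = 1
                current &= rng.random(S) < retention
        for rank, j in enumerate(sorted(roles["shallow_upper"], key=lambda k: units[k].unit_id)):
            cave = caves[rank % len(caves)]
            deep_pool = np.flatnonzero(coherent[:, deep_by_cave[cave]].sum(axis=1) > 0)
            take = rng.random(len(deep_pool)) < min(1.0, p0 * S / max(1, len(deep_pool)))
            coherent[deep_pool[take], j] = 1
        central = np.array([u.zone != "slope" for u in units])
        mask = (rng.random((S, U)) < e) & central[None, :]
        grid = np.where(mask, coherent, grid).astype(np.int8)

    elif spec.scenario == "slope_distinct":
        k = max(2, int(round(S / 3)))
        slope_pool = np.zeros(S, dtype=bool)
        slope_pool[:k] = True
        p_in = min(0.9, p0 * S / k)
        p_out = min(0.9, p0 * S / (S - k))
        p_slope = e * np.where(slope_pool, p_in, 0.0) + (1 - e) * p0
        p_rest = e * np.where(slope_pool, 0.0, p_out) + (1 - e) * p0
        for j in range(U):
            p_col = p_slope if units[j].zone == "slope" else p_rest
            grid[:, j] = (rng.random(S) < p_col).astype(np.int8)

    # Structured scenarios must not emit empty communities; plant one
    # scenario-consistent presence where sampling left a unit empty.
    for j in np.flatnonzero(grid.sum(axis=0) == 0):
        if spec.scenario == "slope_distinct" and units[j].zone == "slope":
            candidates = np.arange(max(2, int(round(S / 3))))
        elif spec.scenario == "deep_turnover":
            candidates = np.arange(int(round(e * S)), S)
        else:
            candidates = np.arange(S)
        grid[rng.choice(candidates), j] = 1
    return grid


def generate_scenario(spec: ScenarioSpec) -> ScenarioData:
    """Generate one synthetic dataset under the given scenario.

    Returns the obligate-only incidence matrix, a raw-count abundance matrix
    over all species (obligate and non-obligate), the sampling-unit metadata
    and the species table. ``pool_seasons`` of
    :func:`generate_trap_samples` output recovers the abundance matrix
    exactly.
    """
    seq = np.random.SeedSequence(spec.seed)
    rng_units, rng_inc, rng_ab = [np.random.default_rng(s) for s in seq.spawn(3)]
    units = _make_units(spec, rng_units)
    grid = _incidence(spec, units, rng_inc)

    obligate_ids = [f"ob{i + 1:02d}" for i in range(spec.n_species)]
    species = [SpeciesRecord(sid, f"Troglobiont sp. {i + 1}", "obligate")
               for i, sid in enumerate(obligate_ids)]
    unit_ids = [u.unit_id for u in units]
    incidence = IncidenceMatrix(pd.DataFrame(grid, index=obligate_ids, columns=unit_ids))

    # Raw counts: 1 + Poisson for occupied cells; non-obligates are surface
    # associates, mostly absent from the deep core.
    counts = np.where(grid > 0, 1 + rng_ab.poisson(3.0, size=grid.shape), 0)
    rows = [counts]
    all_species = list(species)
    if spec.n_non_obligate:
        non_ids = [f"no{i + 1:02d}" for i in range(spec.n_non_obligate)]
        all_species += [SpeciesRecord(sid, f"Edaphic sp. {i + 1}", "non_obligate")
                        for i, sid in enumerate(non_ids)]
        p_non = np.array([0.02 if u.zone == "deep_core" else 0.25 for u in units])
        non_grid = (rng_ab.random((spec.n_non_obligate, len(units))) < p_non).astype(np.int8)
        rows.append(np.where(non_grid > 0, 1 + rng_ab.poisson(5.0, size=non_grid.shape), 0))
        obligate_ids = obligate_ids + non_ids
    abundance = AbundanceMatrix(
        pd.DataFrame(np.vstack(rows), index=[s.species_id for s in all_species], columns=unit_ids),
        is_normalized=False,
    )
    return ScenarioData(incidence, abundance, units, all_species, spec)


def generate_trap_samples(matrix: AbundanceMatrix, seed: int = 0) -> list[TrapSample]:
    """Split each pooled cell count across the two trapping seasons.

    Counts are split Binomial(n, 1/2), so pooling the output recovers the
    matrix cell-exactly; zero cells emit no records.
    """
    if matrix.is_normalized:
        raise ValidationError("trap samples are raw counts; pass the unnormalized matrix")
    rng = np.random.default_rng(seed)
    samples: list[TrapSample] = []
    values = matrix.values.astype(int)
    for i, sid in enumerate(matrix.species_ids):
        for j, uid in enumerate(matrix.unit_ids):
            n = int(values[i, j])
            if n == 0:
                continue
            spring = int(rng.binomial(n, 0.5))
            if spring:
                samples.append(TrapSample(uid, "spring_summer", sid, spring))
            if n - spring:
                samples.append(TrapSample(uid, "winter", sid, n - spring))
    return samples
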