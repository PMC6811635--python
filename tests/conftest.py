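from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from speleodiv import IncidenceMatrix, SamplingUnit


def make_incidence(values, species=None, units=None) -> IncidenceMatrix:
    values = np.asarray(values, dtype=np.int8)
    species = species or [f"sp{i + 1}" for i in range(values.shape[0])]
    units = units or [f"U{j + 1}" for j in range(values.shape[1])]
    return IncidenceMatrix(pd.DataFrame(values, index=species, columns=units))


def random_incidence(rng: np.random.Generator, n_species: int, n_units: int,
                     p: float = 0.4, non_empty: bool = True) -> IncidenceMatrix:
    while True:
        values = (rng.random((n_species, n_units)) < p).astype(np.int8)
        if not non_empty or (values.sum(axis=0) > 0).all():
            return make_incidence(values)


@pytest.fixture
def three_site_toy() -> IncidenceMatrix:
    """S1={1,2}, S2={2,3}, S3={3,4}: d12=d23=2/3, d13=1; multisite BD 0.8
    all-turnover."""
    return make_incidence(
        [[1, 0, 0], [1, 1, 0], [0, 1, 1], [0, 0, 1]],
        species=["t1", "t2", "t3", "t4"], units=["S1", "S2", "S3"],
    )


@pytest.fixture
def toy_units() -> list[SamplingUnit]:
    def unit(uid, cave, zone, depth, xyz, stratum=None):
        return SamplingUnit(uid, cave, zone, depth, xyz, 10, 100.0, stratum)

    units = [
        unit("C1_0-50", "C1", "shallow_upper", 25, (0, 0, 1175)),
        unit("C1_50-100", "C1", "deep_core", 75, (0, 0, 1125)),
        unit("C1_100-200", "C1", "deep_core", 150, (0, 0, 1050)),
        unit("C1_200-330", "C1", "deep_core", 265, (0, 0, 935)),
        unit("C1_330-500", "C1", "deep_core", 415, (0, 0, 785)),
        unit("C1_>500", "C1", "deep_core", 600, (0, 0, 600)),
        unit("C2_0-50", "C2", "shallow_upper", 25, (900, 0, 1175)),
        unit("C2_50-100", "C2", "deep_core", 75, (900, 0, 1125)),
        unit("C2_100-200", "C2", "deep_core", 150, (900, 0, 1050)),
        unit("C2_200-330", "C2", "deep_core", 265, (900, 0, 935)),
        unit("C2_330-500", "C2", "deep_core", 415, (900, 0, 785)),
        unit("C2_>500", "C2", "deep_core", 600, (900, 0, 600)),
        unit("C3", "C3", "shallow_upper", 20, (500, 800, 1180)),
        unit("C4", "C4", "shallow_upper", 30, (1500, 300, 1170)),
        unit("C5", "C5", "shallow_upper", 25, (2000, 900, 1175)),
        unit("S1", "S1", "slope", 15, (6000, 100, 900), "200-330"),
        unit("S2", "S2", "slope", 20, (6500, 500, 780), "330-500"),
        unit("S3", "S3", "slope", 10, (7000, 900, 600), ">500"),
        unit("S4", "S4", "slope", 30, (7500, 1300, 550), ">500"),
        unit("S5", "S5", "slope", 25, (6200, 1700, 950), "200-330"),
    ]
    return units
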