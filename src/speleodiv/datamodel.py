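"""Core domain types for subterranean community analysis.

The data model mirrors a stratified cave-sampling design: a karst massif is
divided into three zones (*slope*, *shallow_upper*, *deep_core*) and six depth
strata below the cave entrance; a *sampling unit* is either an entire small
cave or one depth stratum of a deep cave. Species are classified as obligate
subterranean (troglobionts) or non-obligate; only obligates enter the
quantitative analyses.

Matrices are stored species x unit. :class:`AbundanceMatrix` holds raw or
effort-normalized counts, :class:`IncidenceMatrix` strictly binary
presence/absence, :class:`DissimilarityMatrix` a symmetric pairwise table, and
:class:`Dendrogram` an ultrametric UPGMA tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError

ZONES = ("slope", "shallow_upper", "deep_core")
ECO_CLASSES = ("obligate", "non_obligate")
SEASONS = ("spring_summer", "winter")

#: Depth strata (meters below the cave entrance), half-open [lower, upper).
STRATA = ("0-50", "50-100", "100-200", "200-330", "330-500", ">500")
STRATUM_BOUNDS = (0.0, 50.0, 100.0, 200.0, 330.0, 500.0, np.inf)


def assign_stratum(depth_m: float) -> str:
    """Map a depth below the cave entrance onto one of the six depth strata.

    Intervals are half-open ``[lower, upper)`` so the strata partition
    ``[0, inf)``; ``">500"`` is ``[500, inf)``.

    Parameters
    ----------
    depth_m
        Vertical distance below the cave entrance, in meters. Must be >= 0.
    """
    if not np.isfinite(depth_m) or depth_m < 0:
        raise ValidationError(f"depth must be a finite non-negative number of meters, got {depth_m!r}")
    for label, lo, hi in zip(STRATA, STRATUM_BOUNDS, STRATUM_BOUNDS[1:]):
        if lo <= depth_m < hi:
            return label
    raise AssertionError("unreachable: strata partition [0, inf)")  # pragma: no cover


def zone_of_stratum(stratum: str) -> str:
    """Zone implied by a stratum for central-massif units: the entrance
    stratum (0-50 m) belongs to the shallow upper zone, everything deeper to
    the deep core."""
    if stratum not in STRATA:
        raise ValidationError(f"unknown stratum {stratum!r}; expected one of {STRATA}")
    return "shallow_upper" if stratum == "0-50" else "deep_core"


@dataclass(frozen=True)
class SpeciesRecord:
    """One species with its ecological classification."""

    species_id: str
    name: str
    eco_class: str  # "obligate" | "non_obligate"

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValidationError("species_id must be a non-empty string")
        if self.eco_class not in ECO_CLASSES:
            raise ValidationError(
                f"species {self.species_id!r}: eco_class {self.eco_class!r} "
                f"not in {ECO_CLASSES} (unknowns may not enter quantitative analyses)"
            )


@dataclass(frozen=True)
class SamplingUnit:
    """One community sample: a whole small cave or one depth stratum of a
    deep cave, with its position and trapping effort.

    ``depth_m`` is the vertical distance below the unit's own cave entrance
    (midpoint of the stratum for stratum units). ``stratum`` may differ from
    ``assign_stratum(depth_m)`` when supplied explicitly: slope caves are
    placed into massif-level depth strata by a rule external to this type
    (e.g. entrance depth below the massif top), so an explicit label wins.
    """

    unit_id: str
    cave_code: str
    zone: str  # "slope" | "shallow_upper" | "deep_core"
    depth_m: float
    coord_xyz: tuple[float, float, float]
    n_traps: int
    passage_length_m: float
    stratum: str | None = None

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValidationError(
                f"unit {self.unit_id!r}: zone {self.zone!r} not one of {ZONES}"
            )
        if self.depth_m < 0:
            raise ValidationError(f"unit {self.unit_id!r}: negative depth {self.depth_m}")
        if len(self.coord_xyz) != 3 or not all(np.isfinite(v) for v in self.coord_xyz):
            raise ValidationError(f"unit {self.unit_id!r}: coord_xyz must be a finite (x, y, z) triple")
        if self.n_traps < 1:
            raise ValidationError(f"unit {self.unit_id!r}: n_traps must be >= 1, got {self.n_traps}")
        if self.passage_length_m <= 0:
            raise ValidationError(
                f"unit {self.unit_id!r}: passage_length_m must be > 0, got {self.passage_length_m}"
            )
        if self.stratum is None:
            object.__setattr__(self, "stratum", assign_stratum(self.depth_m))
        elif self.stratum not in STRATA:
            raise ValidationError(
                f"unit {self.unit_id!r}: stratum {self.stratum!r} not one of {STRATA}"
            )
        # Zone/stratum consistency is enforced for central-massif units only;
        # slope caves legitimately carry deep stratum labels.
        if self.zone != "slope" and zone_of_stratum(self.stratum) != self.zone:
            raise ValidationError(
                f"unit {self.unit_id!r}: zone {self.zone!r} inconsistent with "
                f"stratum {self.stratum!r} (0-50 => shallow_upper, deeper => deep_core)"
            )


@dataclass(frozen=True)
class TrapSample:
    """Aggregated trap catch of one species in one unit and season."""

    unit_id: str
    season: str  # "spring_summer" | "winter"
    species_id: str
    count: int

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValidationError(f"season {self.season!r} not one of {SEASONS}")
        if self.count < 0:
            raise ValidationError(
                f"({self.unit_id}, {self.season}, {self.species_id}): negative count {self.count}"
            )


def _check_labels(labels: Sequence[str], what: str) -> list[str]:
    labels = [str(x) for x in labels]
    if len(set(labels)) != len(labels):
        dup = sorted({x for x in labels if labels.count(x) > 1})
        raise ValidationError(f"duplicate {what} id(s): {dup}")
    return labels


@dataclass
class AbundanceMatrix:
    """Species x sampling-unit table of counts (raw integers) or
    effort-normalized densities (individuals per trap per meter)."""

    data: pd.DataFrame  # index: species_ids, columns: unit_ids
    is_normalized: bool = False

    def __post_init__(self) -> None:
        _check_labels(self.data.index, "species")
        _check_labels(self.data.columns, "unit")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValidationError("abundance matrix contains non-finite entries")
        if (values < 0).any():
            raise ValidationError("abundance matrix contains negative entries")

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass
class IncidenceMatrix:
    """Strictly binary species x unit presence/absence table."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        _check_labels(self.data.index, "species")
        _check_labels(self.data.columns, "unit")
        values = self.data.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValidationError("incidence matrix must be strictly binary (0/1)")
        self.data = self.data.astype(np.int8)

    @property
    def species_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def unit_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=np.int8)

    @property
    def fill(self) -> int:
        """Total number of presences."""
        return int(self.data.to_numpy().sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def column(self, unit_id: str) -> np.ndarray:
        return self.data[unit_id].to_numpy(dtype=np.int8)


@dataclass
class DissimilarityMatrix:
    """Symmetric pairwise table: community dissimilarity in [0, 1] or
    spatial distance in meters."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self) -> None:
        self.labels = _check_labels(self.labels, "unit")
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(f"values shape {self.values.shape} does not match {n} labels")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("dissimilarity matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValidationError("dissimilarity matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValidationError("dissimilarity matrix diagonal is not zero")
        if (self.values < -1e-12).any():
            raise ValidationError("dissimilarity matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def submatrix(self, labels: Sequence[str]) -> "DissimilarityMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DissimilarityMatrix(list(labels), self.values[np.ix_(idx, idx)], self.metric_name)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class DendrogramNode:
    """Node of an ultrametric tree; leaves have height 0 and a label."""

    height: float
    label: str | None = None
    children: list["DendrogramNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> Iterator["DendrogramNode"]:
        if self.is_leaf:
            yield self
        else:
            for child in self.children:
                yield from child.leaves()


@dataclass
class Dendrogram:
    """Rooted ultrametric tree from UPGMA clustering.

    Merge heights are half the average inter-cluster dissimilarity at the
    merge, so the cophenetic distance between two leaves is twice the height
    of their lowest common ancestor.
    """

    root: DendrogramNode

    def __post_init__(self) -> None:
        labels = [leaf.label for leaf in self.root.leaves()]
        if any(l is None or l == "" for l in labels):
            raise ValidationError("every dendrogram leaf must be labelled")
        _check_labels([str(l) for l in labels], "leaf")
        self._check_monotone(self.root)

    @staticmethod
    def _check_monotone(node: DendrogramNode) -> None:
        for child in node.children:
            if child.height > node.height + 1e-9:
                raise ValidationError(
                    f"merge heights must be non-decreasing toward the root "
                    f"(child {child.height} > parent {node.height})"
                )
            Dendrogram._check_monotone(child)

    @property
    def leaf_names(self) -> list[str]:
        return [str(leaf.label) for leaf in self.root.leaves()]

    def cophenetic_matrix(self) -> DissimilarityMatrix:
        """Pairwise cophenetic dissimilarities (2 x height of the LCA)."""
        names = sorted(self.leaf_names)
        index = {name: i for i, name in enumerate(names)}
        n = len(names)
        out = np.zeros((n, n))

        def visit(node: DendrogramNode) -> list[str]:
            if node.is_leaf:
                return [str(node.label)]
            groups = [visit(child) for child in node.children]
            for i, left in enumerate(groups):
                for right in groups[i + 1:]:
                    for a in left:
                        for b in right:
                            out[index[a], index[b]] = out[index[b], index[a]] = 2.0 * node.height
            return [name for grp in groups for name in grp]

        visit(self.root)
        return DissimilarityMatrix(names, out, metric_name="cophenetic")
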