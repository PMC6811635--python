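"""Community comparison: ANOSIM, Mantel (Spearman) and UPGMA clustering.

ANOSIM contrasts mean between-group vs within-group dissimilarity *ranks*,

    R = (rbar_between - rbar_within) / (n (n - 1) / 4),

which confines R to [-1, 1]; R near 1 means all between-group dissimilarities
rank above all within-group ones. Significance comes from permuting group
labels over units. The Mantel test correlates the off-diagonal entries of two
distance matrices (here with Spearman rank correlation, robust to non-linear
distance-decay), permuting the row/column order of one matrix jointly. Both
tests use midranks for ties and the add-one permutation p-value
(count + 1) / (n_perm + 1), one-sided for a statistic at least as large as
observed. UPGMA builds the ultrametric dendrogram by repeatedly merging the
cluster pair with the smallest size-weighted mean dissimilarity, at height
half that mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.stats import rankdata

from .datamodel import Dendrogram, DendrogramNode, DissimilarityMatrix
from .errors import DegenerateInputError, ValidationError

__all__ = ["AnosimResult", "MantelResult", "anosim", "mantel_spearman", "upgma"]


@dataclass(frozen=True)
class AnosimResult:
    R: float
    p_value: float
    n_permutations: int
    group_labels: dict[str, str]
    seed: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.R <= 1.0 + 1e-9:
            raise ValidationError(f"ANOSIM R out of [-1, 1]: {self.R}")

    def as_dict(self) -> dict:
        return {
            "R": self.R, "p_value": self.p_value,
            "n_permutations": self.n_permutations, "seed": self.seed,
            "group_labels": dict(self.group_labels),
        }


@dataclass(frozen=True)
class MantelResult:
    r: float
    p_value: float
    n_permutations: int
    seed: int
    correlation_method: str = "spearman"

    def __post_init__(self) -> None:
        if not -1.0 - 1e-9 <= self.r <= 1.0 + 1e-9:
            raise ValidationError(f"Mantel r out of [-1, 1]: {self.r}")

    def as_dict(self) -> dict:
        return {
            "r": self.r, "p_value": self.p_value,
            "n_permutations": self.n_permutations, "seed": self.seed,
            "correlation_method": self.correlation_method,
        }


def _anosim_r(rank_square: np.ndarray, grouping: np.ndarray) -> float:
    """R from a square matrix of dissimilarity midranks and integer labels."""
    n = len(grouping)
    iu = np.triu_indices(n, k=1)
    within = grouping[iu[0]] == grouping[iu[1]]
    ranks = rank_square[iu]
    m = n * (n - 1) / 2
    return float((ranks[~within].mean() - ranks[within].mean()) / (m / 2.0))


def anosim(
    d: DissimilarityMatrix,
    groups: Mapping[str, str],
    n_perm: int = 999,
    seed: int = 0,
) -> AnosimResult:
    """Analysis of similarities over the units of ``d``.

    ``groups`` maps every unit id to a group label; at least two groups of at
    least two units each are required. p is one-sided for permuted R >= the
    observed R, with the add-one convention, and reproducible for a fixed
    seed.
    """
    missing = [u for u in d.labels if u not in groups]
    if missing:
        raise ValidationError(f"unit(s) without group label: {missing}")
    labels = [groups[u] for u in d.labels]
    uniq = sorted(set(labels))
    counts = {g: labels.count(g) for g in uniq}
    small = [g for g, k in counts.items() if k < 2]
    if len(uniq) < 2 or small:
        raise ValidationError(
            f"ANOSIM needs >= 2 groups with >= 2 members each; got sizes {counts}"
        )
    grouping = np.array([uniq.index(g) for g in labels])
    n = d.n
    # Midranks of the n(n-1)/2 dissimilarities, placed back in square form so
    # that permuting unit labels is a pure reindexing.
    iu = np.triu_indices(n, k=1)
    ranks = rankdata(d.values[iu])
    rank_square = np.zeros((n, n))
    rank_square[iu] = ranks
    rank_square += rank_square.T

    observed = _anosim_r(rank_square, grouping)
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _anosim_r(rank_square, grouping[perm]) >= observed:
            count_ge += 1
    p = (count_ge + 1) / (n_perm + 1)
    return AnosimResult(observed, p, n_perm, {u: groups[u] for u in d.labels}, seed)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    if denom == 0:
        raise DegenerateInputError("constant distance vector: correlation undefined")
    return float(np.clip((x @ y) / denom, -1.0, 1.0))


def mantel_spearman(
    d1: DissimilarityMatrix,
    d2: DissimilarityMatrix,
    n_perm: int = 999,
    seed: int = 0,
) -> MantelResult:
    """Mantel test with Spearman rank correlation.

    The two matrices must carry the same unit labels in the same order.
    r is the Spearman correlation over the n(n-1)/2 upper-triangle pairs;
    p permutes the row/column order of the second matrix jointly, one-sided
    for permuted r >= observed (add-one convention).
    """
    if d1.labels != d2.labels:
        raise ValidationError("Mantel test: matrices must share labels in identical order")
    n = d1.n
    if n < 4:
        raise ValidationError(f"Mantel test needs >= 4 units, got {n}")
    iu = np.triu_indices(n, k=1)
    # Spearman = Pearson on midranks; ranking commutes with joint row/column
    # permutation, so rank once and reindex per permutation.
    r1 = np.zeros((n, n))
    r1[iu] = rankdata(d1.values[iu])
    r1 += r1.T
    r2 = np.zeros((n, n))
    r2[iu] = rankdata(d2.values[iu])
    r2 += r2.T

    v1 = r1[iu]
    observed = _pearson(v1, r2[iu])
    rng = np.random.default_rng(seed)
    count_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _pearson(v1, r2[np.ix_(perm, perm)][iu])
        if r_perm >= observed:
            count_ge += 1
    p = (count_ge + 1) / (n_perm + 1)
    return MantelResult(observed, p, n_perm, seed)


def upgma(d: DissimilarityMatrix) -> Dendrogram:
    """Average-linkage (UPGMA) agglomerative clustering.

    At every step the pair of clusters with the minimal size-weighted mean
    inter-cluster dissimilarity is merged at height min/2 (so cophenetic
    distances equal the merge-time averages). When several pairs tie for the
    minimum, the pair whose (smallest-leaf-label) pair sorts first
    lexicographically is merged — a platform-independent determinism rule.
    """
    if d.n < 2:
        raise ValidationError("UPGMA needs at least two units")
    if not np.all(np.isfinite(d.values)):
        raise ValidationError("UPGMA: NaN/inf entries in dissimilarity matrix")

    # Active clusters: key = min leaf label (for tie-breaks).
    nodes: dict[str, DendrogramNode] = {
        label: DendrogramNode(height=0.0, label=label) for label in d.labels
    }
    sizes: dict[str, int] = {label: 1 for label in d.labels}
    dist: dict[frozenset[str], float] = {}
    for i, li in enumerate(d.labels):
        for j in range(i + 1, d.n):
            dist[frozenset((li, d.labels[j]))] = float(d.values[i, j])

    while len(nodes) > 1:
        best_pair: tuple[str, str] | None = None
        best = np.inf
        for key, value in dist.items():
            pair = tuple(sorted(key))
            if value < best - 1e-12 or (
                abs(value - best) <= 1e-12 and (best_pair is None or pair < best_pair)
            ):
                best = value
                best_pair = pair  # type: ignore[assignment]
        assert best_pair is not None
        a, b = best_pair
        merged = DendrogramNode(height=best / 2.0, children=[nodes[a], nodes[b]])
        new_key = min(a, b)
        new_size = sizes[a] + sizes[b]
        others = [k for k in nodes if k not in (a, b)]
        new_dist = {
            other: (
                sizes[a] * dist[frozenset((a, other))]
                + sizes[b] * dist[frozenset((b, other))]
            ) / new_size
            for other in others
        }
        for key in [k for k in dist if a in k or b in k]:
            del dist[key]
        del nodes[a], nodes[b], sizes[a], sizes[b]
        nodes[new_key] = merged
        sizes[new_key] = new_size
        for other, value in new_dist.items():
            dist[frozenset((new_key, other))] = value
    (root,) = nodes.values()
    return Dendrogram(root)
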