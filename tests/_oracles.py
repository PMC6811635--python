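"""Independent brute-force oracles used to cross-check the implementation.

Everything here works by explicit set enumeration or exhaustive search on
tiny inputs, deliberately sharing no code with the package internals.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def sets_from_matrix(values: np.ndarray) -> list[set[int]]:
    """Column communities as python sets of species indices."""
    return [set(np.flatnonzero(values[:, j])) for j in range(values.shape[1])]


def jaccard_brute(values: np.ndarray) -> np.ndarray:
    comms = sets_from_matrix(values)
    n = len(comms)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        union = comms[i] | comms[j]
        out[i, j] = out[j, i] = 1 - len(comms[i] & comms[j]) / len(union)
    return out


def multisite_aggregates_brute(values: np.ndarray) -> tuple[int, int, int, int]:
    comms = sets_from_matrix(values)
    pooled = set().union(*comms)
    sum_si = sum(len(c) for c in comms)
    sum_min = sum_max = 0
    for ci, cj in itertools.combinations(comms, 2):
        bij, bji = len(ci - cj), len(cj - ci)
        sum_min += min(bij, bji)
        sum_max += max(bij, bji)
    return len(pooled), sum_si, sum_min, sum_max


def midrank(values: np.ndarray) -> np.ndarray:
    """Average ranks computed by explicit sorting (no scipy)."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values), dtype=float)
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def anosim_r_brute(d: np.ndarray, labels: list[str]) -> float:
    """Clarke's R computed from first principles on a square matrix."""
    n = len(labels)
    pairs = list(itertools.combinations(range(n), 2))
    ranks = midrank(np.array([d[i, j] for i, j in pairs]))
    within = [k for k, (i, j) in enumerate(pairs) if labels[i] == labels[j]]
    between = [k for k in range(len(pairs)) if k not in within]
    return (ranks[between].mean() - ranks[within].mean()) / (n * (n - 1) / 4)


def anosim_p_exhaustive(d: np.ndarray, labels: list[str]) -> float:
    """Exact permutation p over all distinct unit relabellings (R >= observed),
    including the identity (the standard inclusive convention)."""
    observed = anosim_r_brute(d, labels)
    n = len(labels)
    count = total = 0
    for perm in itertools.permutations(range(n)):
        r = anosim_r_brute(d, [labels[i] for i in perm])
        count += r >= observed - 1e-12
        total += 1
    return count / total


def spearman_brute(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def mantel_p_exhaustive(d1: np.ndarray, d2: np.ndarray) -> float:
    """Exact one-sided Mantel p by enumerating all n! joint relabellings of
    the second matrix (r >= observed, identity included)."""
    n = d1.shape[0]
    iu = np.triu_indices(n, k=1)
    observed = spearman_brute(d1[iu], d2[iu])
    count = total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        r = spearman_brute(d1[iu], d2[np.ix_(p, p)][iu])
        count += r >= observed - 1e-12
        total += 1
    return count / total


def upgma_cophenetic_brute(d: np.ndarray, labels: list[str]) -> dict[frozenset[str], float]:
    """Average-linkage clustering computed directly from the definition:
    cluster distance = plain mean of all cross-pair dissimilarities of the
    ORIGINAL matrix; cophenetic distance = that mean at the merge."""
    index = {l: i for i, l in enumerate(labels)}
    clusters: list[list[str]] = [[l] for l in labels]
    coph: dict[frozenset[str], float] = {}
    while len(clusters) > 1:
        best, best_pair = np.inf, None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            mean = np.mean([d[index[x], index[y]] for x in clusters[a] for y in clusters[b]])
            key = tuple(sorted((min(clusters[a]), min(clusters[b]))))
            if mean < best - 1e-12 or (abs(mean - best) <= 1e-12 and key < best_pair[2]):
                best, best_pair = mean, (a, b, key)
        a, b, _ = best_pair
        for x in clusters[a]:
            for y in clusters[b]:
                coph[frozenset((x, y))] = best
        merged = clusters[a] + clusters[b]
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return coph
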