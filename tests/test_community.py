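from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

import skbio
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import mantel as skbio_mantel

from speleodiv import anosim, jaccard_matrix, mantel_spearman, upgma
from speleodiv.datamodel import DissimilarityMatrix
from speleodiv.errors import ValidationError

from conftest import random_incidence
import _oracles


def dm(labels, square):
    return DissimilarityMatrix(list(labels), np.asarray(square, dtype=float))


def random_distance(rng, n):
    square = squareform(rng.random(n * (n - 1) // 2))
    return dm([f"U{i}" for i in range(n)], square)


# --- ANOSIM -----------------------------------------------------------------

FOUR_UNIT_TOY = dm(
    "ABCD",
    [[0.0, 0.1, 0.7, 0.8],
     [0.1, 0.0, 0.9, 0.6],
     [0.7, 0.9, 0.0, 0.2],
     [0.8, 0.6, 0.2, 0.0]],
)
FOUR_UNIT_GROUPS = {"A": "g1", "B": "g1", "C": "g2", "D": "g2"}


class TestAnosim:
    def test_maximal_separation_gives_r_one(self):
        # All between-group dissimilarities rank above all within-group ones:
        # ranks within {1, 2}, between {3, 4, 5, 6};
        # R = (4.5 - 1.5) / (4 * 3 / 4) = 1, the maximum attainable.
        result = anosim(FOUR_UNIT_TOY, FOUR_UNIT_GROUPS, n_perm=99, seed=0)
        assert result.R == pytest.approx(1.0)
        assert result.R == pytest.approx(
            _oracles.anosim_r_brute(FOUR_UNIT_TOY.values, ["g1", "g1", "g2", "g2"]))

    def test_permutation_p_matches_exhaustive_enumeration(self):
        exact = _oracles.anosim_p_exhaustive(
            FOUR_UNIT_TOY.values, ["g1", "g1", "g2", "g2"])
        result = anosim(FOUR_UNIT_TOY, FOUR_UNIT_GROUPS, n_perm=4999, seed=1)
        # add-one sampled p estimates the inclusive exhaustive p
        assert result.p_value == pytest.approx(exact, abs=0.03)

    def test_random_labels_center_r_at_zero(self):
        rng = np.random.default_rng(0)
        values = []
        for _ in range(1000):
            d = random_distance(rng, 8)
            labels = rng.permutation(["g1"] * 4 + ["g2"] * 4)
            groups = dict(zip(d.labels, labels))
            values.append(anosim(d, groups, n_perm=1, seed=0).R)
        assert abs(np.mean(values)) < 0.05

    def test_matches_skbio(self):
        rng = np.random.default_rng(3)
        for seed in range(5):
            m = random_incidence(np.random.default_rng(seed), 12, 8)
            d = jaccard_matrix(m)
            groups = {u: ("a" if i < 4 else "b") for i, u in enumerate(d.labels)}
            ours = anosim(d, groups, n_perm=99, seed=0)
            theirs = skbio_anosim(
                skbio.DistanceMatrix(d.values, d.labels),
                [groups[u] for u in d.labels], permutations=0)
            assert ours.R == pytest.approx(theirs["test statistic"], abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rank_invariance_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        d = random_distance(rng, 7)
        groups = {u: ("g1" if i < 3 else "g2") for i, u in enumerate(d.labels)}
        transformed = dm(d.labels, np.sqrt(d.values))  # strictly monotone
        r1 = anosim(d, groups, n_perm=1, seed=0).R
        r2 = anosim(transformed, groups, n_perm=1, seed=0).R
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError, match="2"):
            anosim(FOUR_UNIT_TOY, {"A": "g1", "B": "g1", "C": "g1", "D": "g2"}, 9, 0)

    def test_missing_label_rejected(self):
        with pytest.raises(ValidationError, match="D"):
            anosim(FOUR_UNIT_TOY, {"A": "g1", "B": "g1", "C": "g2"}, 9, 0)

    def test_deterministic_for_fixed_seed(self):
        a = anosim(FOUR_UNIT_TOY, FOUR_UNIT_GROUPS, n_perm=199, seed=5)
        b = anosim(FOUR_UNIT_TOY, FOUR_UNIT_GROUPS, n_perm=199, seed=5)
        assert (a.R, a.p_value) == (b.R, b.p_value)


# --- Mantel -----------------------------------------------------------------

class TestMantel:
    def test_monotone_transform_gives_r_one(self):
        rng = np.random.default_rng(1)
        d1 = random_distance(rng, 6)
        d2 = dm(d1.labels, d1.values ** 2)
        assert mantel_spearman(d1, d2, n_perm=9, seed=0).r == pytest.approx(1.0)

    def test_p_matches_exhaustive_enumeration_on_4x4_toy(self):
        d1 = dm("ABCD", squareform([1.0, 2.0, 3.0, 4.0, 5.0, 6.0]))
        d2 = dm("ABCD", squareform([2.0, 1.0, 4.0, 3.0, 6.0, 5.0]))
        exact = _oracles.mantel_p_exhaustive(d1.values, d2.values)
        result = mantel_spearman(d1, d2, n_perm=4999, seed=2)
        assert result.p_value == pytest.approx(exact, abs=0.04)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(7)
        d1, d2 = random_distance(rng, 8), random_distance(rng, 8)
        d2 = dm(d1.labels, d2.values)
        assert mantel_spearman(d1, d2, 99, 0).r == pytest.approx(
            mantel_spearman(d2, d1, 99, 0).r, abs=1e-12)

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(9)
        d1, d2 = random_distance(rng, 9), random_distance(rng, 9)
        d2 = dm(d1.labels, d2.values)
        ours = mantel_spearman(d1, d2, n_perm=9, seed=0)
        theirs_r, _, _ = skbio_mantel(
            skbio.DistanceMatrix(d1.values, d1.labels),
            skbio.DistanceMatrix(d2.values, d2.labels),
            method="spearman", permutations=0)
        assert ours.r == pytest.approx(theirs_r, abs=1e-12)

    def test_label_mismatch_and_small_n_rejected(self):
        d1 = random_distance(np.random.default_rng(0), 5)
        d2 = dm([f"V{i}" for i in range(5)], d1.values)
        with pytest.raises(ValidationError):
            mantel_spearman(d1, d2, 9, 0)
        d3 = random_distance(np.random.default_rng(0), 3)
        with pytest.raises(ValidationError):
            mantel_spearman(d3, d3, 9, 0)

    def test_p_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(5)
        d1, d2 = random_distance(rng, 7), random_distance(rng, 7)
        d2 = dm(d1.labels, d2.values)
        assert (mantel_spearman(d1, d2, 499, 11).p_value
                == mantel_spearman(d1, d2, 499, 11).p_value)


# --- UPGMA ------------------------------------------------------------------

class TestUpgma:
    def test_two_leaves_merge_at_half_distance(self):
        tree = upgma(dm("AB", [[0, 1.0], [1.0, 0]]))
        assert tree.root.height == pytest.approx(0.5)

    def test_three_leaf_worked_example(self):
        tree = upgma(dm("ABC", [[0, 2, 4], [2, 0, 6], [4, 6, 0.0]]))
        coph = tree.cophenetic_matrix()
        assert coph.values[coph.labels.index("A"), coph.labels.index("B")] == pytest.approx(2.0)
        assert coph.values[coph.labels.index("A"), coph.labels.index("C")] == pytest.approx(5.0)
        assert tree.root.height == pytest.approx(2.5)

    def test_cophenetics_match_brute_force_average_linkage(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            d = random_distance(rng, 7)
            coph = upgma(d).cophenetic_matrix()
            expected = _oracles.upgma_cophenetic_brute(d.values, d.labels)
            for pair, value in expected.items():
                a, b = sorted(pair)
                got = coph.values[coph.labels.index(a), coph.labels.index(b)]
                assert got == pytest.approx(value, abs=1e-9)

    def test_cophenetics_match_scipy_average_linkage(self):
        rng = np.random.default_rng(22)
        d = random_distance(rng, 8)
        coph = upgma(d).cophenetic_matrix()
        scipy_coph = squareform(cophenet(linkage(squareform(d.values), method="average")))
        order = [d.labels.index(l) for l in coph.labels]
        np.testing.assert_allclose(coph.values, scipy_coph[np.ix_(order, order)], atol=1e-9)

    def test_output_is_ultrametric(self):
        rng = np.random.default_rng(23)
        d = random_distance(rng, 9)
        coph = upgma(d).cophenetic_matrix().values
        n = coph.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    if len({i, j, k}) == 3:
                        assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-9

    def test_relabelling_preserves_topology_and_heights(self):
        rng = np.random.default_rng(24)
        d = random_distance(rng, 6)
        perm = list(np.random.default_rng(1).permutation(d.labels))
        coph1 = upgma(d).cophenetic_matrix()
        coph2 = upgma(d.submatrix(perm)).cophenetic_matrix()
        assert coph1.labels == coph2.labels  # both sorted
        np.testing.assert_allclose(coph1.values, coph2.values, atol=1e-12)

    def test_tie_break_is_lexicographic(self):
        # A-B and C-D tie at 1.0; A-B must merge first, and the tree is the
        # same regardless of input order.
        square = np.array([
            [0.0, 1.0, 2.0, 2.0],
            [1.0, 0.0, 2.0, 2.0],
            [2.0, 2.0, 0.0, 1.0],
            [2.0, 2.0, 1.0, 0.0],
        ])
        t1 = upgma(dm("ABCD", square))
        perm = [3, 2, 1, 0]
        t2 = upgma(dm([list("ABCD")[i] for i in perm], square[np.ix_(perm, perm)]))
        np.testing.assert_allclose(
            t1.cophenetic_matrix().values, t2.cophenetic_matrix().values, atol=1e-12)

    def test_nan_rejected(self):
        square = np.array([[0.0, np.nan], [np.nan, 0.0]])
        with pytest.raises(ValidationError):
            dm("AB", square)
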