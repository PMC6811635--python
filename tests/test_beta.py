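from __future__ import annotations

import subprocess
import textwrap

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from speleodiv import (
    PairCounts,
    average_bd,
    build_horizontal_sets,
    build_vertical_sets,
    multisite_aggregates,
    pair_counts,
    pairwise_partition,
    partition_units,
)
from speleodiv.beta import BDPartition, restrict_sets
from speleodiv.errors import DegenerateInputError, ValidationError

from conftest import make_incidence, random_incidence
import _oracles


class TestPairwisePartition:
    def test_pure_nestedness(self):
        p = pairwise_partition(PairCounts(a=3, b=0, c=4))
        assert p.turnover == 0.0
        assert p.nestedness == pytest.approx(p.total)

    def test_pure_replacement(self):
        p = pairwise_partition(PairCounts(a=0, b=3, c=3))
        assert p.total == pytest.approx(1.0)
        assert p.turnover == pytest.approx(1.0)
        assert p.nestedness == pytest.approx(0.0)

    def test_mixed_example(self):
        p = pairwise_partition(PairCounts(a=2, b=1, c=3))
        assert p.total == pytest.approx(4 / 6)
        assert p.turnover == pytest.approx(0.5)
        assert p.nestedness == pytest.approx(4 / 6 - 0.5)

    def test_empty_pair_rejected(self):
        with pytest.raises(DegenerateInputError):
            pairwise_partition(PairCounts(0, 0, 0))

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    @settings(max_examples=200, deadline=None)
    def test_additivity_machine_exact(self, a, b, c):
        if a + b + c == 0:
            return
        p = pairwise_partition(PairCounts(a, b, c))
        # nestedness is defined as total - turnover; re-adding can differ by
        # at most one ulp
        assert p.turnover + p.nestedness == pytest.approx(p.total, abs=1e-15)
        assert 0 <= p.nestedness + 1e-12 and p.nestedness <= p.total <= 1


class TestMultisiteAggregates:
    def test_three_site_toy(self, three_site_toy):
        agg = multisite_aggregates(three_site_toy)
        assert (agg.S_T, agg.sum_Si, agg.sum_min, agg.sum_max) == (4, 6, 4, 4)

    def test_identical_sites(self):
        m = make_incidence([[1, 1, 1], [1, 1, 1], [0, 0, 0]])
        agg = multisite_aggregates(m)
        assert agg.sum_min == agg.sum_max == 0
        assert agg.sum_Si == 3 * agg.S_T

    def test_two_sites_reduce_to_pair(self):
        m = make_incidence([[1, 0], [1, 1], [0, 1], [0, 1]])
        agg = multisite_aggregates(m)
        p = pair_counts(m.column("U1"), m.column("U2"))
        assert (agg.sum_min, agg.sum_max) == (min(p.b, p.c), max(p.b, p.c))

    def test_empty_unit_rejected(self):
        m = make_incidence([[1, 0], [1, 0]], units=["U1", "hollow"])
        with pytest.raises(DegenerateInputError, match="hollow"):
            multisite_aggregates(m)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_incidence(rng, 12, 6)
        agg = multisite_aggregates(m)
        assert (agg.S_T, agg.sum_Si, agg.sum_min, agg.sum_max) == \
            _oracles.multisite_aggregates_brute(m.values)


class TestMultisitePartition:
    def test_three_site_toy_partition(self, three_site_toy):
        p = partition_units(three_site_toy)
        assert p.total == pytest.approx(0.8)
        assert p.turnover == pytest.approx(0.8)
        assert p.nestedness == pytest.approx(0.0)

    def test_two_site_consistency_with_pairwise(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = random_incidence(rng, 10, 2)
            multi = partition_units(m)
            pw = pairwise_partition(pair_counts(m.column("U1"), m.column("U2")))
            assert multi.total == pytest.approx(pw.total, abs=1e-12)
            assert multi.turnover == pytest.approx(pw.turnover, abs=1e-12)

    def test_nested_chain_all_nestedness(self):
        # S1 contains S2 contains S3: no replacement at all.
        m = make_incidence([[1, 1, 1], [1, 1, 0], [1, 0, 0], [1, 1, 0], [1, 0, 0]])
        p = partition_units(m)
        assert p.turnover == 0.0
        assert p.nestedness == pytest.approx(p.total)
        assert p.total > 0

    def test_degenerate_single_species_identical_sites(self):
        m = make_incidence([[1, 1]])
        p = partition_units(m)
        assert p.total == 0.0

    def test_site_order_invariance(self):
        rng = np.random.default_rng(8)
        m = random_incidence(rng, 14, 6)
        base = partition_units(m)
        perm = list(np.random.default_rng(0).permutation(m.unit_ids))
        again = partition_units(m, perm)
        assert base.total == pytest.approx(again.total, abs=1e-12)
        assert base.turnover == pytest.approx(again.turnover, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_additivity_multisite(self, seed):
        rng = np.random.default_rng(seed)
        m = random_incidence(rng, 12, 5)
        p = partition_units(m)
        assert p.turnover + p.nestedness == pytest.approx(p.total, abs=1e-12)
        assert -1e-12 <= p.nestedness <= p.total <= 1 + 1e-12

    def test_matches_vegan_reference(self, three_site_toy):
        """Cross-check the multiple-site Jaccard partition against vegan's
        nestedbetajac on the worked toy and a random matrix."""
        rng = np.random.default_rng(77)
        m = random_incidence(rng, 12, 6)
        rows = ";".join(",".join(str(v) for v in row) for row in m.values.T)
        script = textwrap.dedent(f"""
            suppressMessages(library(vegan))
            comm <- do.call(rbind, lapply(strsplit(strsplit("{rows}", ";")[[1]], ","),
                                          as.numeric))
            cat(sprintf("%.12f %.12f %.12f", nestedbetajac(comm)[["turnover"]],
                        nestedbetajac(comm)[["nestedness"]], nestedbetajac(comm)[["jaccard"]]))
        """)
        out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, check=True)
        turnover, nestedness, total = map(float, out.stdout.split())
        p = partition_units(m)
        assert p.total == pytest.approx(total, abs=1e-9)
        assert p.turnover == pytest.approx(turnover, abs=1e-9)
        assert p.nestedness == pytest.approx(nestedness, abs=1e-9)


class TestComparisonSets:
    def test_vertical_sets_count_and_size(self, toy_units):
        sets = build_vertical_sets(toy_units)
        central = [s for s in sets if s.setting == "vertical_central"]
        slope = [s for s in sets if s.setting == "vertical_slope"]
        assert len(central) == 10  # 5 shallow units x 2 deep caves
        assert all(len(s.unit_ids) == 6 for s in central)
        assert len(slope) == 1 and len(slope[0].unit_ids) == 5

    def test_single_shallow_single_cave(self, toy_units):
        subset = [u for u in toy_units if u.cave_code == "C1"]
        sets = build_vertical_sets(subset)
        central = [s for s in sets if s.setting == "vertical_central"]
        assert len(central) == 1 and len(central[0].unit_ids) == 6

    def test_incomplete_deep_cave_warns_but_builds(self, toy_units, caplog):
        subset = [u for u in toy_units if u.unit_id != "C1_>500"]
        with caplog.at_level("WARNING"):
            sets = build_vertical_sets(subset)
        assert any("deep cave C1" in r.message for r in caplog.records)
        c1_sets = [s for s in sets if s.stratum_or_combo.endswith("+C1")]
        assert all(len(s.unit_ids) == 5 for s in c1_sets)

    def test_horizontal_sets_membership(self, toy_units):
        sets = {s.stratum_or_combo: s for s in build_horizontal_sets(toy_units)}
        assert set(sets["0-50"].unit_ids) == {"C1_0-50", "C2_0-50", "C3", "C4", "C5"}
        # slope caves join deeper strata through their explicit labels
        assert set(sets[">500"].unit_ids) == {"C1_>500", "C2_>500", "S3", "S4"}
        assert set(sets["200-330"].unit_ids) == {"C1_200-330", "C2_200-330", "S1", "S5"}

    def test_single_unit_stratum_skipped(self, toy_units, caplog):
        subset = [u for u in toy_units if u.unit_id in ("C1_0-50", "C2_0-50", "C1_50-100")]
        with caplog.at_level("WARNING"):
            sets = build_horizontal_sets(subset)
        assert [s.stratum_or_combo for s in sets] == ["0-50"]
        assert any("50-100" in r.message for r in caplog.records)

    def test_restrict_sets_drops_missing_units(self, toy_units, caplog):
        sets = build_horizontal_sets(toy_units)
        with caplog.at_level("WARNING"):
            kept = restrict_sets(sets, [u.unit_id for u in toy_units if u.unit_id != "S3"])
        deep = next(s for s in kept if s.stratum_or_combo == ">500")
        assert "S3" not in deep.unit_ids


class TestAverageBd:
    def test_single_partition_identity(self):
        p = BDPartition(0.8, 0.8, 0.0, 3)
        assert average_bd([p]) == BDPartition(0.8, 0.8, 0.0, 3)

    def test_componentwise_mean_preserves_additivity(self):
        out = average_bd([BDPartition(0.8, 0.8, 0.0, 3), BDPartition(0.4, 0.2, 0.2, 3)])
        assert (out.total, out.turnover) == (pytest.approx(0.6), pytest.approx(0.5))
        assert out.nestedness == pytest.approx(0.1)
        assert out.turnover + out.nestedness == pytest.approx(out.total, abs=1e-15)

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            average_bd([])
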