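"""Revised IFS: curves, inflection detection, intersections, consensus."""

from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from brainmarkers.datamodel import ConsistencyError, FeatureList
from brainmarkers.ifs import (
    ConsensusGeneTable,
    ConsensusRow,
    IFSCurve,
    InflectionPoint,
    consensus_frequency,
    find_inflection_point,
    important_features,
    max_accuracy_point,
    run_ifs,
)
from brainmarkers.mrmr import discretize, mrmr_ranking
from brainmarkers.simulate import GeneratorConfig, generate_cohort, make_curve_fixture


def brute_force_inflection(accs, k_min, k_max):
    """Literal scan of the definition; independent of the implementation."""
    for k in range(k_min, k_max + 1):
        if accs[k - 1] >= accs[k - 2] and accs[k - 1] > accs[k]:
            return k, False
    window = accs[k_min - 1:k_max]
    best = max(window)
    return k_min + window.index(best), True


accuracy_lists = st.lists(
    st.fractions(min_value=0, max_value=1, max_denominator=20),
    min_size=3,
    max_size=40,
)


class TestRunIFS:
    def test_one_point_per_prefix_and_per_test(self, small_cohort):
        datasets, _ = small_cohort
        disc = discretize(datasets[0])
        flist = mrmr_ranking(disc, 12)
        curves = run_ifs(datasets[0], datasets[1:], flist, n_max=12)
        assert len(curves) == 2
        for curve, test_ds in zip(curves, datasets[1:]):
            assert curve.training_individual == datasets[0].individual_id
            assert curve.test_individual == test_ds.individual_id
            assert [p.k for p in curve.points] == list(range(1, 13))

    def test_single_strong_gene_perfect_from_k1(self):
        cfg = GeneratorConfig(
            n_genes=30,
            per_individual_counts=((8, 8, 8), (10, 10, 10)),
            individual_ids=("A", "B"),
            n_planted_per_region=1,
            effect_size=10.0,
            noise_sd=0.1,
            batch_sd=0.05,
            seed=3,
        )
        datasets, _ = generate_cohort(cfg)
        flist = mrmr_ranking(discretize(datasets[0]), 3)
        (curve,) = run_ifs(datasets[0], [datasets[1]], flist, n_max=3)
        assert curve.accuracy(3) == 1

    def test_no_tests_gives_no_curves(self, small_cohort):
        datasets, _ = small_cohort
        flist = mrmr_ranking(discretize(datasets[0]), 5)
        assert run_ifs(datasets[0], [], flist, n_max=5) == []

    def test_missing_gene_named_in_error(self, small_cohort):
        datasets, _ = small_cohort
        flist = FeatureList("mRMR", [("not_a_gene", 1.0)])
        with pytest.raises(ConsistencyError, match="not_a_gene"):
            run_ifs(datasets[0], datasets[1:], flist, n_max=1)

    def test_per_class_accuracies_consistent_with_total(self, small_cohort):
        datasets, _ = small_cohort
        flist = mrmr_ranking(discretize(datasets[0]), 6)
        curves = run_ifs(datasets[0], datasets[1:2], flist, n_max=6)
        counts = datasets[1].region_counts()
        n = datasets[1].n_samples
        for pt in curves[0].points:
            assert 0 <= pt.total <= 1
            weighted = sum(
                pt.per_class[r] * counts[r] for r in counts if pt.per_class[r] is not None
            )
            assert pt.total == Fraction(weighted) / n


class TestInflection:
    def test_first_qualifying_point_wins(self):
        curve = make_curve_fixture([0.5, 0.7, 0.6, 0.8, 0.7])
        pt = find_inflection_point(curve, k_min=2, k_max=4)
        assert (pt.k, pt.fallback_used) == (2, False)
        assert pt.total_accuracy == Fraction(0.7)

    def test_monotone_curve_falls_back_to_argmax(self):
        curve = make_curve_fixture([0.1, 0.2, 0.3, 0.4, 0.5, 0.6])
        pt = find_inflection_point(curve, k_min=2, k_max=5)
        assert (pt.k, pt.fallback_used) == (5, True)

    def test_plateau_then_drop(self):
        curve = make_curve_fixture([0.5, 0.5, 0.4])
        pt = find_inflection_point(curve, k_min=2, k_max=2)
        assert (pt.k, pt.fallback_used) == (2, False)

    def test_short_curve_and_bad_range_rejected(self):
        with pytest.raises(ValueError):
            find_inflection_point(make_curve_fixture([0.5, 0.6]), 2, 2)
        curve = make_curve_fixture([0.5] * 10)
        with pytest.raises(ValueError):
            find_inflection_point(curve, k_min=1, k_max=5)
        with pytest.raises(ValueError):
            find_inflection_point(curve, k_min=2, k_max=10)

    @given(accuracy_lists, st.data())
    def test_matches_brute_force_scan(self, accs, data):
        n = len(accs)
        k_min = data.draw(st.integers(2, n - 1))
        k_max = data.draw(st.integers(k_min, n - 1))
        curve = make_curve_fixture([float(a) for a in accs])
        # rebuild exact fractions on the curve for unambiguous comparisons
        for p, a in zip(curve.points, accs):
            p.total = Fraction(a)
        pt = find_inflection_point(curve, k_min=k_min, k_max=k_max)
        expect_k, expect_fb = brute_force_inflection(accs, k_min, k_max)
        assert (pt.k, pt.fallback_used) == (expect_k, expect_fb)


class TestMaxAccuracy:
    def test_first_max_wins(self):
        assert max_accuracy_point(make_curve_fixture([0.2, 0.9, 0.9]))[0] == 2

    def test_monotone_curve_picks_last(self):
        curve = make_curve_fixture([0.1, 0.5, 0.9])
        assert max_accuracy_point(curve) == (3, Fraction(0.9))

    @given(accuracy_lists)
    def test_agrees_with_linear_scan(self, accs):
        curve = make_curve_fixture([float(a) for a in accs])
        k, best = max_accuracy_point(curve)
        floats = [float(a) for a in accs]
        assert float(best) == max(floats)
        assert k == floats.index(max(floats)) + 1


class TestImportantFeatures:
    LIST = FeatureList("mRMR", [(f"g{i:02d}", 0.0) for i in range(40)])

    @staticmethod
    def points(ks):
        return [InflectionPoint(k=k, total_accuracy=Fraction(1, 2),
                                fallback_used=False) for k in ks]

    def test_intersection_is_shortest_prefix(self):
        got = important_features(self.LIST, self.points([7, 12, 9, 30, 7]))
        assert got == set(self.LIST.prefix(7))

    @pytest.mark.parametrize("ks, expect", [([5], 5), ([9, 9, 9], 9)])
    def test_single_and_tied_inflections(self, ks, expect):
        assert important_features(self.LIST, self.points(ks)) == set(
            self.LIST.prefix(expect)
        )

    def test_empty_inflection_list_rejected(self):
        with pytest.raises(ValueError):
            important_features(self.LIST, [])

    @given(st.lists(st.integers(1, 40), min_size=1, max_size=6))
    def test_nested_prefix_law(self, ks):
        got = important_features(self.LIST, self.points(ks))
        literal = set(self.LIST.prefix(ks[0]))
        for k in ks[1:]:
            literal &= set(self.LIST.prefix(k))
        assert got == literal == set(self.LIST.prefix(min(ks)))


class TestConsensus:
    def test_frequencies_and_sorting(self):
        sets = [
            ("d1", {"NRg", "Xa"}),
            ("d2", {"NRg", "Xb"}),
            ("d3", {"NRg", "Xa"}),
            ("d4", {"NRg"}),
            ("d5", {"NRg", "Xc"}),
            ("d6", {"Za"}),
        ]
        table = consensus_frequency(sets)
        assert table.rows[0].gene_id == "NRg" and table.rows[0].frequency == 5
        assert table.rows[0].contributors == ("d1", "d2", "d3", "d4", "d5")
        assert table.frequency_of("Xa") == 2
        keys = [(-r.frequency, r.gene_id) for r in table.rows]
        assert keys == sorted(keys)

    def test_disjoint_sets_all_frequency_one(self):
        table = consensus_frequency([("a", {"g1"}), ("b", {"g2"})])
        assert all(r.frequency == 1 for r in table.rows)

    def test_identical_sets_reach_maximum(self):
        table = consensus_frequency([(f"d{i}", {"g1", "g2"}) for i in range(6)])
        assert all(r.frequency == 6 for r in table.rows)

    def test_duplicate_training_ids_rejected(self):
        with pytest.raises(ValueError):
            consensus_frequency([("a", {"g"}), ("a", {"h"})])

    def test_table_invariants_enforced(self):
        with pytest.raises(ValueError):
            ConsensusGeneTable(
                rows=[ConsensusRow("g", 2, ("a",))]  # frequency != contributors
            )
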