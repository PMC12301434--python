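import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from uniparental.config import RunConfig
from uniparental.io import MutationRateTable
from uniparental.ystr import (SharingMatrix, diversity_report,
                              haplotype_diversity, individual_distance_matrix,
                              mean_locus_variance, median_filter,
                              pairwise_repeat_distance, pairwise_tmrca,
                              sharing_matrix, tmrca_matrix)

from conftest import make_str_table


def _repeats(rows):
    df = pd.DataFrame(rows, columns=[f"L{i + 1}" for i in range(len(rows[0]))])
    df.index = [f"S{i}" for i in range(len(rows))]
    return df


class TestRepeatDistance:
    def test_sums_absolute_repeat_differences(self):
        assert pairwise_repeat_distance([13, 14, 29], [13, 16, 29]) == 2

    def test_identical_haplotypes_at_distance_zero(self):
        h = list(range(10, 27))
        assert pairwise_repeat_distance(h, h) == 0

    def test_missing_locus_skipped(self):
        assert pairwise_repeat_distance([13, 14], [14, np.nan]) == 1

    def test_no_shared_loci_gives_nan(self, caplog):
        with caplog.at_level("WARNING", logger="uniparental"):
            d = pairwise_repeat_distance([np.nan, 14], [14, np.nan])
        assert math.isnan(d)
        assert "no shared" in caplog.text


class TestPairwiseTmrca:
    def test_identical_haplotypes_give_zero_years(self, flat_rates):
        h = pd.Series({f"L{i + 1}": 15.0 for i in range(17)})
        assert pairwise_tmrca(h, h, flat_rates) == 0.0

    def test_single_step_on_one_of_17_loci(self, flat_rates):
        """One locus differing by one repeat: (0.5/0.002)/17 generations."""
        h1 = pd.Series({f"L{i + 1}": 15.0 for i in range(17)})
        h2 = h1.copy()
        h2["L1"] = 16.0
        t = pairwise_tmrca(h1, h2, flat_rates, generation_time=30.0)
        assert t == pytest.approx(7500 / 17, abs=1e-9)

    def test_uniform_difference_constant_rates(self):
        """Every locus off by one at rate 0.003: (0.5/0.003)*30 years."""
        rates = MutationRateTable({f"L{i + 1}": 0.003 for i in range(17)})
        h1 = pd.Series({f"L{i + 1}": 15.0 for i in range(17)})
        h2 = h1 + 1.0
        assert pairwise_tmrca(h1, h2, rates) == pytest.approx(5000.0)

    def test_missing_loci_excluded_from_mean(self, flat_rates):
        h1 = pd.Series({f"L{i + 1}": 15.0 for i in range(17)})
        h2 = h1.copy()
        h2["L1"] = 16.0
        h2["L2"] = np.nan  # na.rm: mean over the 16 remaining loci
        t = pairwise_tmrca(h1, h2, flat_rates)
        assert t == pytest.approx((0.5 / 0.002) / 16 * 30)

    def test_all_missing_gives_nan(self, flat_rates):
        h1 = pd.Series({f"L{i + 1}": np.nan for i in range(17)})
        h2 = pd.Series({f"L{i + 1}": 15.0 for i in range(17)})
        assert math.isnan(pairwise_tmrca(h1, h2, flat_rates))

    @given(st.lists(st.integers(10, 20), min_size=17, max_size=17),
           st.lists(st.integers(10, 20), min_size=17, max_size=17))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_nonnegative_and_zero_iff_identical(self, a, b):
        rates = MutationRateTable({f"L{i + 1}": 0.002 for i in range(17)})
        loci = [f"L{i + 1}" for i in range(17)]
        h1 = pd.Series(dict(zip(loci, map(float, a))))
        h2 = pd.Series(dict(zip(loci, map(float, b))))
        t = pairwise_tmrca(h1, h2, rates)
        d = pairwise_repeat_distance(h1, h2)
        assert t >= 0
        assert (t == 0) == (d == 0)


class TestDiversity:
    def test_all_distinct_is_one(self):
        rep = _repeats([[10, 11], [10, 12], [11, 11], [12, 12]])
        assert haplotype_diversity(rep) == pytest.approx(1.0)

    def test_monomorphic_pair_is_zero(self):
        rep = _repeats([[10, 11], [10, 11]])
        assert haplotype_diversity(rep) == 0.0

    def test_partial_sharing_hand_value(self):
        """{h1,h1,h2,h3}: sum p^2 = 0.375 -> (0.625)(4/3)."""
        rep = _repeats([[10, 11], [10, 11], [10, 12], [11, 11]])
        assert haplotype_diversity(rep) == pytest.approx(0.625 * 4 / 3)

    def test_single_individual_is_nan(self, caplog):
        with caplog.at_level("WARNING", logger="uniparental"):
            assert math.isnan(haplotype_diversity(_repeats([[10, 11]])))

    def test_missing_is_a_distinct_symbol(self):
        rep = _repeats([[10, np.nan], [10, 11]])
        assert haplotype_diversity(rep) == pytest.approx(1.0)

    @given(st.lists(st.lists(st.integers(10, 13), min_size=3, max_size=3),
                    min_size=2, max_size=12))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_bounded_in_unit_interval(self, rows):
        h = haplotype_diversity(_repeats(rows))
        assert 0.0 <= h <= 1.0 + 1e-12


class TestMeanLocusVariance:
    def test_hand_computed_single_locus(self):
        assert mean_locus_variance(_repeats([[12], [12], [13], [14]])) == \
            pytest.approx(11 / 12)  # var of {12,12,13,14}, divisor n-1

    def test_monomorphic_is_zero(self):
        assert mean_locus_variance(_repeats([[15, 10]] * 4)) == 0.0

    def test_two_values_single_locus(self):
        assert mean_locus_variance(_repeats([[10], [12]])) == pytest.approx(2.0)

    def test_underobserved_locus_excluded(self):
        rep = _repeats([[10, np.nan], [12, 14], [14, np.nan]])
        assert mean_locus_variance(rep) == pytest.approx(4.0)  # locus 2 has n=1


def test_diversity_report_counts_and_sizes():
    table = make_str_table([[10, 11], [10, 11], [10, 12], [12, 12], [12, 12]],
                           ["A", "A", "A", "B", "B"])
    rep = diversity_report(table)
    assert rep.loc["A", "sample_size"] == 3
    assert rep.loc["A", "n_haplotypes"] == 2
    assert rep.loc["B", "haplotype_diversity"] == 0.0
    assert (rep["n_haplotypes"] <= rep["sample_size"]).all()


class TestSharingMatrix:
    def test_identical_criterion_pair_counting(self):
        """A={h1,h1,h2}, B={h1,h3}: 2 matching cross pairs out of 6."""
        table = make_str_table(
            [[10, 11], [10, 11], [10, 12], [10, 11], [13, 13]],
            ["A", "A", "A", "B", "B"])
        sm = sharing_matrix(table, "identical", config=RunConfig(min_pop_size=2))
        assert sm.matrix.loc["A", "B"] == pytest.approx(2 / 6)
        assert sm.matrix.loc["A", "A"] == pytest.approx(1 / 3)  # one within pair

    def test_disjoint_haplotype_sets_share_nothing(self):
        table = make_str_table([[10, 11], [10, 12], [20, 20], [21, 21]],
                               ["A", "A", "B", "B"])
        sm = sharing_matrix(table, "identical", config=RunConfig(min_pop_size=2))
        assert sm.matrix.loc["A", "B"] == 0.0

    def test_vacuous_tmrca_threshold_saturates(self, flat_rates):
        table = make_str_table([[10] * 17, [12] * 17, [20] * 17, [25] * 17],
                               ["A", "A", "B", "B"])
        sm = sharing_matrix(table, "tmrca_lt", threshold=math.inf,
                            rates=flat_rates, config=RunConfig(min_pop_size=2))
        assert (sm.matrix.to_numpy() == 1.0).all()

    def test_tmrca_bin_is_strict_upper_bound(self):
        # all loci off by one at rate 1/128: tMRCA exactly 1920.0 years
        rates = MutationRateTable({f"L{i + 1}": 1 / 128 for i in range(17)})
        h1 = [15] * 17
        h2 = [16] * 17
        table = make_str_table([h1, h2], ["A", "B"])
        cfg = RunConfig(min_pop_size=1)
        at = sharing_matrix(table, "tmrca_lt", threshold=1920.0,
                            rates=rates, config=cfg)
        above = sharing_matrix(table, "tmrca_lt", threshold=1920.0 + 1e-6,
                               rates=rates, config=cfg)
        assert at.matrix.loc["A", "B"] == 0.0  # boundary pair excluded
        assert above.matrix.loc["A", "B"] == 1.0

    def test_small_modern_population_excluded_ancient_exempt(self, caplog):
        table = make_str_table(
            [[10, 11]] * 5 + [[10, 11], [12, 12]] + [[9, 9]],
            ["big"] * 5 + ["small"] * 2 + ["old"],
            eras=["modern"] * 7 + ["ancient"])
        with caplog.at_level("WARNING", logger="uniparental"):
            sm = sharing_matrix(table, "identical", config=RunConfig(min_pop_size=5))
        assert sm.populations == ["big", "old"]
        assert "excluding population small" in caplog.text

    def test_matrix_is_symmetric(self):
        table = make_str_table([[10, 11], [10, 11], [10, 12], [10, 11]],
                               ["A", "A", "B", "B"])
        sm = sharing_matrix(table, "identical", config=RunConfig(min_pop_size=2))
        assert np.allclose(sm.matrix, sm.matrix.T)


class TestMedianFilter:
    def _sm(self, matrix, pops):
        return SharingMatrix(pd.DataFrame(matrix, index=pops, columns=pops),
                             "identical")

    def test_only_strictly_above_median_survives(self):
        m = [[0.9, 0.1, 0.2], [0.1, 0.9, 0.3], [0.2, 0.3, 0.9]]
        out = median_filter(self._sm(m, ["A", "B", "C"]))
        assert out.median_threshold == pytest.approx(0.2)
        assert out.matrix.loc["B", "C"] == 0.3
        assert out.matrix.loc["A", "B"] == 0.0
        assert out.matrix.loc["A", "C"] == 0.0
        assert out.matrix.loc["A", "A"] == 0.9  # diagonal untouched

    def test_single_nonzero_value_filters_itself(self):
        m = [[0.0, 0.2], [0.2, 0.0]]
        out = median_filter(self._sm(m, ["A", "B"]))
        assert out.matrix.loc["A", "B"] == 0.0

    def test_all_equal_values_all_filtered(self):
        m = [[0.0, 0.2, 0.2], [0.2, 0.0, 0.2], [0.2, 0.2, 0.0]]
        out = median_filter(self._sm(m, ["A", "B", "C"]))
        off = ~np.eye(3, dtype=bool)
        assert (out.matrix.to_numpy()[off] == 0.0).all()

    def test_all_zero_matrix_returned_unchanged(self, caplog):
        m = np.zeros((2, 2))
        with caplog.at_level("WARNING", logger="uniparental"):
            out = median_filter(self._sm(m, ["A", "B"]))
        assert (out.matrix.to_numpy() == 0).all()
        assert out.median_threshold is None

    @given(st.lists(st.floats(0, 1), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_never_increases_any_entry(self, vals):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = vals[0]
        m[0, 2] = m[2, 0] = vals[1]
        m[1, 2] = m[2, 1] = vals[2]
        out = median_filter(self._sm(m, ["A", "B", "C"]))
        assert (out.matrix.to_numpy() <= m + 1e-15).all()


class TestIndividualDistanceMatrix:
    def test_shape_symmetry_and_zero_diagonal(self):
        table = make_str_table([[10, 11], [10, 12], [11, 11], [10, 11], [9, 9]],
                               ["A"] * 5)
        m = individual_distance_matrix(table).matrix
        assert m.shape == (5, 5)
        assert np.allclose(m, m.T)
        assert np.allclose(np.diag(m), 0)
        assert m.loc["S001", "S004"] == 0.0  # identical rows

    def test_triangle_inequality_holds(self, rng):
        rows = rng.integers(10, 20, size=(6, 5)).astype(float)
        m = individual_distance_matrix(make_str_table(rows, ["A"] * 6)).matrix.to_numpy()
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-9


def test_tmrca_matrix_matches_pairwise_function(flat_rates):
    table = make_str_table([[15] * 17, [16] * 17, [15] * 17], ["A", "A", "B"])
    m = tmrca_matrix(table, flat_rates).matrix
    h = pd.Series({f"L{i + 1}": 15.0 for i in range(17)})
    assert m.loc["S001", "S002"] == pytest.approx(
        pairwise_tmrca(h, h + 1, flat_rates))
    assert m.loc["S001", "S003"] == 0.0
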