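import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twinepi.association import (
    bonferroni_adjust,
    cohens_d_ci,
    dominant_grouping,
    hwe_chi_square,
    mann_whitney,
    rank_biserial,
    rank_biserial_ci,
    run_snp_battery,
    student_t,
    welch_t,
)
from twinepi.catalog import DEFAULT_CATALOG
from twinepi.errors import InsufficientDataError, ParameterError
from twinepi.simulate import GroupShift, SimulationConfig, gen_cohort

from conftest import cohort_with_genotype_counts


class TestDominantGrouping:
    @pytest.mark.parametrize(
        "counts,n_val,n_met",
        [((129, 224, 77), 301, 129), ((23, 37, 10), 47, 23)],
    )
    def test_val_plus_pools_val_carriers(self, counts, n_val, n_met):
        groups = dominant_grouping(cohort_with_genotype_counts(*counts))
        assert groups.n_val == n_val
        assert groups.n_met == n_met
        assert not groups.val_plus & groups.met_plus

    def test_all_met_homozygotes_refuse_battery(self):
        cohort = cohort_with_genotype_counts(4, 0, 0)
        with pytest.raises(InsufficientDataError):
            run_snp_battery(cohort)


class TestHwe:
    def test_exact_proportions_give_zero(self):
        res = hwe_chi_square((25, 50, 25))
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)
        assert res.allele_freq_p == 0.5

    def test_sample_counts(self):
        res = hwe_chi_square((129, 224, 77))
        assert res.chi2 == pytest.approx(1.41, abs=0.01)
        assert res.expected == pytest.approx((135.07, 211.86, 83.07), abs=0.01)
        assert sum(res.expected) == pytest.approx(430)
        assert res.df == 1

    def test_monomorphic_convention(self):
        assert hwe_chi_square((0, 0, 50)).chi2 == 0.0

    def test_negative_count_rejected(self):
        with pytest.raises(ParameterError):
            hwe_chi_square((-1, 2, 3))

    def test_label_permutation_invariance(self):
        # swapping the homozygote labels mirrors the allele frequency only
        a = hwe_chi_square((129, 224, 77))
        b = hwe_chi_square((77, 224, 129))
        assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = mann_whitney([3, 4], [1, 2])
        assert u == 4.0
        u, _ = mann_whitney([1, 2], [3, 4])
        assert u == 0.0

    def test_tie_credit(self):
        u, _ = mann_whitney([1, 2, 3], [1, 2, 3])
        assert u == 4.5

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
    )
    def test_u_equals_pair_enumeration(self, x, y):
        u, _ = mann_whitney(x, y)
        brute = sum(
            1.0 if xi > yi else 0.5 if xi == yi else 0.0
            for xi in x
            for yi in y
        )
        assert u == pytest.approx(brute)


class TestTTests:
    def test_equal_samples(self):
        t, df, p = student_t([1, 2, 3, 4], [1, 2, 3, 4])
        assert (t, p) == (0.0, 1.0) or (t == pytest.approx(0) and p == pytest.approx(1))
        assert df == 6

    def test_large_shift_detected(self):
        rng = np.random.default_rng(0)
        t, _, p = student_t(rng.normal(1, 1, 200), rng.normal(0, 1, 200))
        assert abs(t) > 5 and p < 1e-3

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(0, 1000))
    def test_welch_df_never_exceeds_pooled(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(3, 30, 2)
        x = rng.normal(0, rng.uniform(0.5, 3), n1)
        y = rng.normal(0, rng.uniform(0.5, 3), n2)
        _, df_w, _ = welch_t(x, y)
        _, df_s, _ = student_t(x, y)
        assert df_w <= df_s + 1e-9


class TestCohensD:
    def test_identical_groups(self):
        x = [1.0, 2.0, 3.0, 4.0]
        d, lo, hi = cohens_d_ci(x, x)
        assert d == 0.0
        assert lo < 0 < hi

    def test_planted_shift_recovered(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(0.5, 1, 200), rng.normal(0, 1, 200)
        d, lo, hi = cohens_d_ci(x, y)
        assert abs(d - 0.5) < 0.15
        assert lo <= d <= hi

    def test_ci_width_shrinks_with_n(self):
        rng = np.random.default_rng(2)
        widths = []
        for n in (20, 80, 320):
            x, y = rng.normal(0.3, 1, n), rng.normal(0, 1, n)
            _, lo, hi = cohens_d_ci(x, y)
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_zero_pooled_sd_is_error(self):
        with pytest.raises(InsufficientDataError):
            cohens_d_ci([2.0, 2.0], [2.0, 2.0])


class TestRankBiserial:
    @pytest.mark.parametrize(
        "u,expected",
        [
            (22341.5, 0.151),
            (15777.5, -0.187),
            (15371.5, -0.208),
            (15564, -0.198),
            (16275.5, -0.162),
            (15971.5, -0.177),
            (16599, -0.145),
        ],
    )
    def test_known_effect_sizes(self, u, expected):
        assert round(rank_biserial(u, 129, 301), 3) == expected

    def test_no_dominance_is_zero(self):
        assert rank_biserial(129 * 301 / 2, 129, 301) == 0.0

    def test_domain(self):
        with pytest.raises(ParameterError):
            rank_biserial(129 * 301 + 1, 129, 301)

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(
        st.lists(st.integers(0, 6), min_size=1, max_size=10),
        st.lists(st.integers(0, 6), min_size=1, max_size=10),
    )
    def test_equals_dominance_statistic(self, x, y):
        """r matches (favorable - unfavorable) / (n1 n2) by enumeration."""
        u, _ = mann_whitney(x, y)
        r = rank_biserial(u, len(x), len(y))
        favorable = sum(xi > yi for xi in x for yi in y)
        unfavorable = sum(xi < yi for xi in x for yi in y)
        assert r == pytest.approx((favorable - unfavorable) / (len(x) * len(y)))

    def test_ci_symmetric_at_null(self):
        lo, hi = rank_biserial_ci(129 * 301 / 2, 129, 301)
        assert lo == pytest.approx(-hi)

    def test_ci_contains_estimate_and_matches_formula(self):
        lo, hi = rank_biserial_ci(22341.5, 129, 301)
        r = rank_biserial(22341.5, 129, 301)
        assert lo <= r <= hi
        assert (lo, hi) == (pytest.approx(0.03, abs=0.005), pytest.approx(0.27, abs=0.005))


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,m,expected", [(0.013, 2, 0.026), (0.634, 2, 1.0), (0.0, 5, 0.0)]
    )
    def test_adjustment(self, p, m, expected):
        assert bonferroni_adjust(p, m) == pytest.approx(expected)

    def test_monotone_and_capped(self):
        ps = [0.0, 0.01, 0.2, 0.49, 0.51, 1.0]
        adj = [bonferroni_adjust(p, 2) for p in ps]
        assert adj == sorted(adj)
        assert max(adj) <= 1.0
        assert bonferroni_adjust(0.3, 2) <= bonferroni_adjust(0.3, 4)

    def test_domain(self):
        with pytest.raises(ParameterError):
            bonferroni_adjust(1.2, 2)
        with pytest.raises(ParameterError):
            bonferroni_adjust(0.5, 0)


class TestBattery:
    def test_thirty_five_rows_in_catalog_order(self, null_cohort):
        results = run_snp_battery(null_cohort)
        assert [r.scale for r in results] == list(DEFAULT_CATALOG.all_scales)

    def test_determinism(self, null_cohort):
        assert run_snp_battery(null_cohort) == run_snp_battery(null_cohort)

    def test_planted_group_shift_detected(self):
        cfg = SimulationConfig(seed=17, group_shift=GroupShift("warmth", 0.6))
        cohort = gen_cohort(cfg).cohort
        row = next(
            r for r in run_snp_battery(cohort) if r.scale == "warmth"
        )
        assert row.p_bonf < 0.05
        assert row.direction == 1  # shift was applied to the Met+ group

    def test_bonferroni_consistency(self, null_cohort):
        for row in run_snp_battery(null_cohort, bonferroni_m=2):
            if not math.isnan(row.p):
                assert row.p_bonf == pytest.approx(min(1.0, 2 * row.p))
                assert row.effect_ci_low <= row.effect <= row.effect_ci_high
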