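"""Sullivan estimator, its variance, confidence intervals and contrasts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sullivan_hle import (
    AgeGrid,
    MortalitySchedule,
    PrevalenceSchedule,
    build_life_table,
    ci,
    difference_test,
    health_expectancy,
    hle_variance,
)
from sullivan_hle.grids import GridError

from conftest import naive_sullivan, random_mortality


def prev(grid, pi, **kw):
    return PrevalenceSchedule(grid=grid, condition="hypertension", pi=np.asarray(pi, float), **kw)


class TestHealthExpectancy:
    def test_disease_free_population_recovers_ex(self, total_lifetable):
        het = health_expectancy(total_lifetable, prev(total_lifetable.grid, np.zeros(18)))
        np.testing.assert_allclose(het.hle, total_lifetable.ex, rtol=1e-12)
        np.testing.assert_allclose(het.pct_with, 0.0, atol=1e-9)

    def test_constant_prevalence_scales_ex(self, total_lifetable):
        c = 0.3
        het = health_expectancy(total_lifetable, prev(total_lifetable.grid, np.full(18, c)))
        np.testing.assert_allclose(het.hle, (1 - c) * total_lifetable.ex, rtol=1e-12)
        np.testing.assert_allclose(het.pct_with, 100 * c, rtol=1e-9)

    def test_matches_naive_double_loop_on_random_schedules(self, grid):
        rng = np.random.default_rng(42)
        for _ in range(100):
            lt = build_life_table(random_mortality(rng, grid))
            pi = rng.uniform(0, 1, size=len(grid))
            het = health_expectancy(lt, prev(grid, pi))
            np.testing.assert_allclose(het.hle, naive_sullivan(lt, pi), rtol=1e-10)

    def test_healthy_plus_unhealthy_years_add_to_ex(self, total_lifetable):
        rng = np.random.default_rng(8)
        pi = rng.uniform(0, 1, size=18)
        het = health_expectancy(total_lifetable, prev(total_lifetable.grid, pi))
        with_years = het.pct_with / 100.0 * het.ex
        np.testing.assert_allclose(het.hle + with_years, het.ex, rtol=1e-10)

    def test_terminal_pct_with_equals_terminal_prevalence(self, total_lifetable):
        pi = np.linspace(0.01, 0.635, 18)
        het = health_expectancy(total_lifetable, prev(total_lifetable.grid, pi))
        assert het.pct_with[-1] == pytest.approx(100 * pi[-1], abs=1e-9)

    def test_grid_mismatch_is_loud(self, total_lifetable):
        small = AgeGrid.from_age_starts([0, 1, 5])
        with pytest.raises(GridError, match="offending"):
            health_expectancy(total_lifetable, prev(small, [0.1, 0.1, 0.1]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        bumps=st.lists(st.floats(0.0, 0.3), min_size=18, max_size=18),
    )
    def test_raising_prevalence_never_raises_hle(self, total_lifetable, bumps):
        rng = np.random.default_rng(13)
        pi = rng.uniform(0.0, 0.6, size=18)
        pi2 = np.clip(pi + np.asarray(bumps), 0.0, 1.0)
        h1 = health_expectancy(total_lifetable, prev(total_lifetable.grid, pi)).hle
        h2 = health_expectancy(total_lifetable, prev(total_lifetable.grid, pi2)).hle
        assert np.all(h2 <= h1 + 1e-12)


class TestVariance:
    def test_degenerate_prevalence_has_zero_variance(self, total_lifetable):
        pi = np.array([0.0, 1.0] * 9)
        n = np.full(18, 100.0)
        var = hle_variance(total_lifetable, prev(total_lifetable.grid, pi, n_sample=n))
        np.testing.assert_allclose(var, 0.0, atol=1e-15)

    def test_variance_shrinks_monotonically_with_sample_size(self, total_lifetable):
        pi = np.full(18, 0.3)
        prev_var = np.inf
        for n in (50, 500, 5000, 5_000_000):
            var = hle_variance(
                total_lifetable, prev(total_lifetable.grid, pi, n_sample=np.full(18, float(n)))
            )
            assert var[0] < prev_var
            prev_var = var[0]
        assert prev_var < 1e-4  # consistency: vanishes as N grows

    def test_single_term_hand_oracle(self):
        # one closed + terminal interval; evaluate the formula by hand
        grid = AgeGrid.from_age_starts([0, 5])
        lt = build_life_table(MortalitySchedule(grid=grid, mx=np.array([0.02, 0.1])))
        pi = np.array([0.2, 0.5])
        n = np.array([100.0, 400.0])
        var = hle_variance(lt, prev(grid, pi, n_sample=n))
        hand = (
            lt.Lx[0] ** 2 * 0.2 * 0.8 / 100.0 + lt.Lx[1] ** 2 * 0.5 * 0.5 / 400.0
        ) / lt.lx[0] ** 2
        assert var[0] == pytest.approx(hand, rel=1e-12)
        hand_term = (lt.Lx[1] ** 2 * 0.5 * 0.5 / 400.0) / lt.lx[1] ** 2
        assert var[1] == pytest.approx(hand_term, rel=1e-12)

    def test_missing_cell_size_marks_ci_not_estimable(self, total_lifetable):
        pi = np.full(18, 0.3)
        n = np.full(18, 200.0)
        n[5] = np.nan  # one surveyed cell without a size
        var = hle_variance(total_lifetable, prev(total_lifetable.grid, pi, n_sample=n))
        assert np.all(np.isnan(var[: 6]))  # every start at or below that cell
        assert np.all(np.isfinite(var[6:]))

    def test_assumed_intervals_suppress_their_own_ci_only(self, table1_total, total_lifetable):
        sched = table1_total["hypertension"]
        n = np.where(sched.assumed, np.nan, 300.0)
        sched2 = PrevalenceSchedule(
            grid=sched.grid, condition=sched.condition, pi=sched.pi,
            n_sample=n, assumed=sched.assumed, stratum=sched.stratum,
        )
        var = hle_variance(total_lifetable, sched2)
        i15 = sched.grid.index_of(15.0)
        assert np.all(np.isnan(var[:i15]))   # ages 0-14: prevalence assumed
        assert np.all(np.isfinite(var[i15:]))


class TestCI:
    def test_zero_variance_collapses(self):
        lo, hi = ci(np.array([40.0]), np.array([0.0]))
        assert lo[0] == hi[0] == 40.0

    def test_hand_arithmetic(self):
        lo, hi = ci(np.array([40.4]), np.array([0.28**2]))
        assert lo[0] == pytest.approx(39.85, abs=0.005)
        assert hi[0] == pytest.approx(40.95, abs=0.005)

    def test_higher_level_widens(self):
        lo95, hi95 = ci(np.array([10.0]), np.array([1.0]), level=0.95)
        lo99, hi99 = ci(np.array([10.0]), np.array([1.0]), level=0.99)
        assert lo99[0] < lo95[0] < hi95[0] < hi99[0]

    def test_bad_level_rejected(self):
        with pytest.raises(ValueError):
            ci(np.array([1.0]), np.array([0.1]), level=1.5)


def _tables_pair(grid, lt, pi_a, pi_b, n=500.0):
    ns = np.full(len(grid), n)
    a = health_expectancy(lt, prev(grid, pi_a, n_sample=ns))
    b = health_expectancy(lt, prev(grid, pi_b, n_sample=ns))
    return a, b


class TestDifferenceTest:
    def test_identical_groups_give_zero_no_stars(self, total_lifetable):
        grid = total_lifetable.grid
        pi = np.full(18, 0.25)
        a, b = _tables_pair(grid, total_lifetable, pi, pi)
        d = difference_test(a, b, 15.0)
        assert d.diff == 0.0 and d.z == 0.0 and d.stars == ""

    def test_known_gap_is_recovered_with_significance(self, total_lifetable):
        grid = total_lifetable.grid
        a, b = _tables_pair(grid, total_lifetable, np.full(18, 0.2), np.full(18, 0.3), n=5000.0)
        d = difference_test(a, b, 15.0)
        expected = 0.1 * total_lifetable.ex[grid.index_of(15.0)]
        assert d.diff == pytest.approx(expected, rel=1e-9)
        assert d.stars == "***"
        assert d.ci_low < d.diff < d.ci_high
        assert d.ci_high - d.diff == pytest.approx(1.959964 * d.se, rel=1e-5)

    def test_missing_variance_suppresses_inference(self, total_lifetable, table1_total):
        # published schedules carry no cell sizes: difference still reported
        a = health_expectancy(total_lifetable, table1_total["hypertension"])
        b = health_expectancy(total_lifetable, table1_total["hypertension"])
        d = difference_test(a, b, 15.0)
        assert d.diff == 0.0
        assert math.isnan(d.se) and d.stars == ""

    def test_zero_se_nonzero_diff_is_degenerate(self, total_lifetable):
        grid = total_lifetable.grid
        ns = np.full(18, 500.0)
        a = health_expectancy(total_lifetable, prev(grid, np.zeros(18), n_sample=ns))
        b = health_expectancy(total_lifetable, prev(grid, np.ones(18), n_sample=ns))
        d = difference_test(a, b, 0.0)
        assert d.degenerate and math.isinf(d.z) and d.z > 0

    def test_ci_coverage_of_known_gap(self, total_lifetable):
        # synthetic strata with a fixed 2-year gap at age 15: the difference CI
        # should cover the true gap in at least ~95% of survey replicates
        from sullivan_hle.synthetic import SyntheticScenario, generate_prevalence, sample_survey

        scn = SyntheticScenario()
        grid = total_lifetable.grid
        i15 = grid.index_of(15.0)
        truth = generate_prevalence(scn)
        base_pi = truth.hypertension.pi
        shift = 2.0 / total_lifetable.ex[i15]  # constant-prevalence gap of 2 years
        pi_b = np.clip(base_pi + shift, 0.0, 1.0)
        hits = 0
        reps = 500
        rng = np.random.default_rng(99)
        ns = np.full(18, 2000.0)
        for r in range(reps):
            sa = rng.binomial(2000, base_pi) / 2000.0
            sb = rng.binomial(2000, pi_b) / 2000.0
            a = health_expectancy(total_lifetable, prev(grid, sa, n_sample=ns))
            b = health_expectancy(total_lifetable, prev(grid, sb, n_sample=ns))
            d = difference_test(a, b, 15.0)
            if d.ci_low <= 2.0 <= d.ci_high:
                hits += 1
        assert hits / reps >= 0.93
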