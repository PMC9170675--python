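"""The e-value machinery: supremum, tangential set, integration, standardization."""


import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pyfbst import (
    FBSTResult,
    FLAT_REFERENCE,
    Hypothesis,
    InvalidInputError,
    NullOutsideSupportError,
    ReferenceFunction,
    asymptotic_ev0,
    asymptotic_pv0,
    build_surprise,
    e_value_montecarlo,
    estimate_posterior_density,
    gen_mixture_draws,
    gen_normal_draws,
    integrate_posterior_mass,
    run_fbst,
    standardized_e_value,
    supremum_surprise,
    tangential_region,
)
from pyfbst.core import TangentialRegion


class TestHypothesis:
    def test_null_dimension_must_be_below_parameter_dimension(self):
        with pytest.raises(InvalidInputError):
            Hypothesis(0.0, dim_theta=2, dim_null=2)
        with pytest.raises(InvalidInputError):
            Hypothesis(0.0, dim_theta=1, dim_null=-1)

    def test_degrees_of_freedom(self):
        assert Hypothesis(0.0, 9, 8).dof == 1


class TestSupremumSurprise:
    def test_null_at_mode_attains_maximum(self, std_normal_surprise):
        s_star = supremum_surprise(std_normal_surprise, Hypothesis(0.0))
        assert s_star == pytest.approx(std_normal_surprise.s_values.max(), abs=0.01)

    def test_matches_standard_normal_density(self, std_normal_surprise):
        s_star = supremum_surprise(std_normal_surprise, Hypothesis(0.0))
        assert abs(s_star - 0.3989) <= 0.02

    def test_null_outside_grid_raises(self, std_normal_surprise):
        with pytest.raises(NullOutsideSupportError):
            supremum_surprise(std_normal_surprise, Hypothesis(10.0))


class TestTangentialRegion:
    def test_level_above_maximum_gives_empty_region(self, std_normal_surprise):
        region = tangential_region(
            std_normal_surprise, std_normal_surprise.s_values.max() + 1.0
        )
        assert region.is_empty
        assert region.total_mass == 0.0

    def test_level_zero_covers_everything(
        self, std_normal_surprise, std_normal_density
    ):
        region = tangential_region(std_normal_surprise, 0.0, std_normal_density)
        assert len(region.intervals) == 1
        assert region.total_mass == pytest.approx(1.0, abs=1e-6)

    def test_bimodal_surprise_yields_two_intervals(self):
        draws = gen_mixture_draws(
            [0.5, 0.5], [-3.0, 3.0], [0.5, 0.5], 40_000, seed=21
        )
        density = estimate_posterior_density(draws)
        surprise = build_surprise(density, FLAT_REFERENCE)
        # level between the trough (~0 at theta=0) and the peaks (~0.4)
        trough = surprise.at(0.0)
        peak = surprise.s_values.max()
        level = trough + 0.3 * (peak - trough)
        region = tangential_region(surprise, level, density)
        assert len(region.intervals) == 2
        (a1, b1), (a2, b2) = region.intervals
        assert b1 < 0 < a2

    def test_endpoints_refined_across_crossing(self, std_normal_surprise):
        s_star = supremum_surprise(std_normal_surprise, Hypothesis(1.0))
        region = tangential_region(std_normal_surprise, s_star)
        (a, b) = region.intervals[0]
        # for a symmetric unimodal surprise the crossings sit at +-|theta0|
        assert a == pytest.approx(-1.0, abs=0.05)
        assert b == pytest.approx(1.0, abs=0.05)

    def test_negative_level_rejected(self, std_normal_surprise):
        with pytest.raises(InvalidInputError):
            tangential_region(std_normal_surprise, -0.1)


class TestIntegratePosteriorMass:
    def test_full_grid_mass_is_one(self, std_normal_density):
        grid = std_normal_density.grid
        region = TangentialRegion(((float(grid[0]), float(grid[-1])),), 0.0)
        assert integrate_posterior_mass(std_normal_density, region) == pytest.approx(
            1.0, abs=1e-6
        )

    def test_empty_region_mass_is_zero(self, std_normal_density):
        assert integrate_posterior_mass(std_normal_density, TangentialRegion((), 0.0)) == 0.0

    def test_central_interval_matches_normal_mass(self, std_normal_density):
        region = TangentialRegion(((-1.96, 1.96),), 0.0)
        mass = integrate_posterior_mass(std_normal_density, region)
        assert mass == pytest.approx(0.95, abs=0.02)


class TestMonteCarloEValue:
    def test_zero_level_gives_one(self, std_normal_draws, std_normal_surprise):
        assert e_value_montecarlo(std_normal_draws, std_normal_surprise, 0.0) == 1.0

    def test_level_above_max_gives_zero(self, std_normal_draws, std_normal_surprise):
        level = std_normal_surprise.s_values.max() + 1.0
        assert e_value_montecarlo(std_normal_draws, std_normal_surprise, level) == 0.0

    def test_matches_normal_oracle_at_1_96(
        self, std_normal_draws, std_normal_surprise
    ):
        s_star = supremum_surprise(std_normal_surprise, Hypothesis(1.96))
        ev = e_value_montecarlo(std_normal_draws, std_normal_surprise, s_star)
        assert ev == pytest.approx(0.95, abs=0.01)


class TestStandardizedEValue:
    def test_worked_two_dimensional_example(self):
        # ev_against = 0.8597 with k = 2, h = 1 gives sev ~ 0.047
        sev_bar, sev = standardized_e_value(0.8597, Hypothesis(0.0, 2, 1))
        assert sev == pytest.approx(0.047, abs=0.001)
        assert sev_bar + sev == 1.0

    def test_identity_when_null_has_dimension_zero(self):
        for x in (0.05, 0.3141, 0.8597, 0.99):
            sev_bar, _ = standardized_e_value(x, Hypothesis(0.0, 3, 0))
            assert sev_bar == pytest.approx(x, abs=1e-12)

    def test_boundary_inputs_map_exactly(self):
        hyp = Hypothesis(0.0, 2, 1)
        assert standardized_e_value(0.0, hyp) == (0.0, 1.0)
        assert standardized_e_value(1.0, hyp) == (1.0, 0.0)

    def test_out_of_range_input_rejected(self):
        with pytest.raises(InvalidInputError):
            standardized_e_value(1.5, Hypothesis(0.0, 2, 1))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        ev=st.floats(1e-6, 1 - 1e-6),
        step=st.floats(1e-4, 0.1),
        k=st.integers(2, 9),
        h=st.integers(1, 8),
    )
    def test_strictly_increasing_in_evidence(self, ev, step, k, h):
        if h >= k:
            h = k - 1
        hyp = Hypothesis(0.0, k, h)
        lo, _ = standardized_e_value(ev, hyp)
        hi, _ = standardized_e_value(min(ev + step, 1 - 1e-7), hyp)
        assert hi > lo


class TestAsymptoticValues:
    def test_ev0_is_one_when_modes_coincide(self):
        assert asymptotic_ev0(1.3, 1.3, 1) == 1.0

    def test_ev0_matches_two_sided_normal_tail(self):
        assert asymptotic_ev0(0.0, 1.96, 1) == pytest.approx(0.05, abs=1e-3)

    def test_ev0_decreases_with_distance(self):
        dists = [0.0, 0.5, 1.0, 2.0, 4.0]
        vals = [asymptotic_ev0(0.0, d, 2) for d in dists]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_pv0_is_one_for_zero_statistic(self):
        assert asymptotic_pv0(0.0, Hypothesis(0.0, 2, 1)) == 1.0

    @pytest.mark.parametrize("stat,dof", [(3.8416, 1), (5.9915, 2)])
    def test_pv0_at_chi_square_095_quantiles(self, stat, dof):
        hyp = Hypothesis(0.0, dof + 1, 1)
        assert asymptotic_pv0(stat, hyp) == pytest.approx(0.05, abs=1e-3)

    def test_pv0_rejects_negative_statistic(self):
        with pytest.raises(InvalidInputError):
            asymptotic_pv0(-1.0, Hypothesis(0.0, 2, 1))


class TestRunFBST:
    def test_null_in_tail_matches_closed_form(self):
        draws = gen_normal_draws(1.96, 1.0, 20_000, seed=4)
        res = run_fbst(draws, Hypothesis(0.0))
        assert res.ev_against == pytest.approx(0.95, abs=0.02)

    def test_null_at_mode_gives_small_evidence(self):
        # the tangential set of a null at the posterior mode is nearly
        # empty; its mass is floored by kernel-density noise near the flat
        # top of the posterior, not by the exact value 0
        draws = gen_normal_draws(0.0, 1.0, 20_000, seed=42)
        res = run_fbst(draws, Hypothesis(0.0))
        assert res.ev_against <= 0.1

    def test_complement_identities_and_ranges(self):
        draws = gen_normal_draws(0.7, 0.8, 10_000, seed=3)
        res = run_fbst(draws, Hypothesis(0.0, 2, 1))
        assert res.ev_against + res.ev_favor == 1.0
        assert res.sev_bar + res.sev == 1.0
        for v in (res.ev_against, res.ev_favor, res.sev, res.sev_bar, res.ev0):
            assert 0.0 <= v <= 1.0

    def test_montecarlo_method_reports_draw_fraction(self):
        draws = gen_normal_draws(1.0, 1.0, 10_000, seed=8)
        res = run_fbst(draws, Hypothesis(0.0), method="montecarlo")
        assert res.method == "montecarlo"
        assert res.ev_against == res.ev_against_montecarlo

    def test_evidence_monotone_in_null_distance(self, std_normal_draws):
        evs = [
            run_fbst(std_normal_draws, Hypothesis(theta0)).ev_against
            for theta0 in [0.25, 0.5, 1.0, 1.5, 2.0, 3.0]
        ]
        assert all(a <= b + 1e-12 for a, b in zip(evs, evs[1:]))

    def test_reference_scale_invariance(self, std_normal_draws):
        base = ReferenceFunction(
            "custom", custom_density=lambda g: stats.cauchy.pdf(g)
        )
        scaled = ReferenceFunction(
            "custom", custom_density=lambda g: 7.3 * stats.cauchy.pdf(g)
        )
        hyp = Hypothesis(1.0)
        ev1 = run_fbst(std_normal_draws, hyp, base).ev_against
        ev2 = run_fbst(std_normal_draws, hyp, scaled).ev_against
        assert abs(ev1 - ev2) <= 1e-12

    def test_pv0_only_when_statistic_supplied(self, std_normal_draws):
        hyp = Hypothesis(1.0)
        assert run_fbst(std_normal_draws, hyp).pv0 is None
        res = run_fbst(
            std_normal_draws, hyp, neg2_log_relative_likelihood=3.8416
        )
        assert res.pv0 == pytest.approx(0.05, abs=1e-3)

    def test_far_null_yields_total_evidence(self):
        draws = gen_normal_draws(1.0, 0.05, 10_000, seed=13)
        res = run_fbst(draws, Hypothesis(0.0))
        assert res.ev_against >= 0.999

    def test_result_from_ev_against_fills_complements(self):
        res = FBSTResult.from_ev_against(0.8597, Hypothesis(0.0, 2, 1))
        assert res.ev_favor == pytest.approx(0.1403, abs=1e-12)
        assert res.sev == pytest.approx(0.047, abs=0.001)
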