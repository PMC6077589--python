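"""Projection engine: trajectories, metrics, scenarios, Monte-Carlo bands."""

import numpy as np
import pandas as pd
import pytest

from ckdproj.projection import (
    ModelParameters,
    ScenarioSpec,
    monte_carlo_intervals,
    render_percent,
    run_model,
    run_projection,
    run_sensitivity,
    summarize,
)
from ckdproj.rates import ProbabilitySet
from ckdproj.states import HealthState, StateVector, TransitionMatrix

from _oracles import N, random_state, random_valid_matrix

H = HealthState


def small_params(horizon=(2007, 2012), growth=0.0, **prob_kw):
    values = dict(
        p_non_12=0.01, p_non_3=0.005, p_12_3=0.05, p_3_4=0.02, p_4_5=0.1,
        d_12=0.15, d_3=0.25, d_4=0.5,
    )
    values.update(prob_kw)
    probs = ProbabilitySet(**values)
    base = StateVector.from_dict(
        horizon[0],
        {
            H.NON_CKD: 90_000.0,
            H.S12_UNDETECTED: 4000.0,
            H.S12_DETECTED: 1000.0,
            H.S3_UNDETECTED: 2500.0,
            H.S3_DETECTED: 1500.0,
            H.S4_UNDETECTED: 400.0,
            H.S4_DETECTED: 450.0,
            H.S5: 150.0,
        },
    )
    return ModelParameters(
        base_state=base,
        probabilities={y: probs for y in range(horizon[0], horizon[1])},
        rr={"1-2": 1.5, "3": 2.5, "4": 5.0, "5": 10.0},
        background_rates={y: 0.0065 for y in range(horizon[0], horizon[1])},
        population_growth=growth,
        horizon=horizon,
    )


class TestRunProjection:
    def test_identity_matrices_freeze_the_cohort(self, rng):
        base = random_state(rng, 2007)
        matrices = {y: TransitionMatrix(y, np.eye(N)) for y in range(2007, 2035)}
        result = run_projection(base, matrices)
        assert len(result.states) == 29
        for state in result.states:
            np.testing.assert_allclose(state.counts, base.counts)

    def test_two_state_geometric_decay(self):
        # alive/dead reduction: constant death probability q gives N(1-q)^t
        q = 0.1
        P = np.eye(N)
        P[H.NON_CKD.index, H.NON_CKD.index] = 1 - q
        P[H.NON_CKD.index, H.DEATH.index] = q
        base = StateVector.from_dict(2007, {H.NON_CKD: 1000.0})
        matrices = {y: TransitionMatrix(y, P) for y in range(2007, 2017)}
        result = run_projection(base, matrices)
        for t, state in enumerate(result.states):
            assert state.alive_total == pytest.approx(1000.0 * (1 - q) ** t, rel=1e-12)

    def test_missing_year_fails(self, rng):
        base = random_state(rng, 2007)
        matrices = {2007: random_valid_matrix(rng, 2007), 2009: random_valid_matrix(rng, 2009)}
        with pytest.raises(ValueError, match="2008"):
            run_projection(base, matrices)

    def test_conservation_across_cycles_with_entrants(self, rng):
        base = random_state(rng, 2007, scale=1e4)
        matrices = {y: random_valid_matrix(rng, y) for y in range(2007, 2035)}
        entrants = {
            y: np.concatenate([rng.random(N - 1) * 50, [0.0]]) for y in range(2007, 2035)
        }
        result = run_projection(base, matrices, entrants)
        total_entrants = sum(v.sum() for v in entrants.values())
        closed = result.states[-1].counts.sum()
        assert closed == pytest.approx(base.counts.sum() + total_entrants, rel=1e-9)


class TestRunModel:
    def test_snapshot_count_and_growth_target(self):
        params = small_params(horizon=(2007, 2035), growth=0.01)
        result = run_model(params)
        assert len(result.states) == 29
        final = result.states[-1]
        assert final.alive_total == pytest.approx(
            params.base_state.alive_total * 1.01 ** 28, rel=1e-9
        )

    def test_dynamic_mortality_solve_matches_death_totals(self):
        params = small_params(horizon=(2007, 2010))
        params.background_rates = None
        params.death_totals = {y: 800.0 for y in range(2007, 2010)}
        result = run_model(params)
        # deaths booked each cycle equal the supplied national totals
        deaths = np.diff([s[H.DEATH] for s in result.states])
        np.testing.assert_allclose(deaths, 800.0, rtol=1e-9)

    def test_missing_probability_year_fails(self):
        params = small_params()
        del params.probabilities[2009]
        with pytest.raises(ValueError, match="2009"):
            run_model(params)


class TestSummarize:
    def test_all_detected_cohort_has_zero_undiagnosed(self):
        base = StateVector.from_dict(
            2007, {H.NON_CKD: 900.0, H.S3_DETECTED: 100.0}
        )
        params = small_params()
        params.base_state = base
        params.horizon = (2007, 2008)
        result = run_model(params)
        s = summarize(result, 2007)
        assert s["undiag_prevalence"] == 0.0
        assert s["prevalence_pct"] == 10.0

    def test_absent_year_fails(self):
        result = run_model(small_params())
        with pytest.raises(KeyError):
            summarize(result, 1999)

    def test_rendered_percentages_round_half_up(self):
        assert render_percent(0.12156) == 12.2
        assert render_percent(0.08765) == 8.8
        assert render_percent(0.125) == 12.5
        assert render_percent(0.0005) == 0.1


class TestSensitivity:
    def test_zero_rate_scenario_changes_nothing(self):
        deltas = run_sensitivity(small_params(), ScenarioSpec())
        assert deltas["delta_total_ckd"] == 0.0
        assert deltas["delta_undetected"] == 0.0

    def test_incidence_reduction_prevents_cases(self):
        scenario = ScenarioSpec(
            incidence_change={("non", "1-2"): -0.01}, horizon=(2007, 2012)
        )
        deltas = run_sensitivity(small_params(), scenario)
        assert deltas["delta_total_ckd"] < 0

    def test_detection_increase_moves_mass_not_totals(self):
        scenario = ScenarioSpec(
            detection_change={"1-2": 0.01}, horizon=(2007, 2012)
        )
        deltas = run_sensitivity(small_params(), scenario)
        assert deltas["delta_undetected"] < 0
        # detected and undetected compartments share stage mortality, so the
        # CKD total is unchanged up to numerical noise
        assert deltas["delta_total_ckd"] == pytest.approx(0.0, abs=1e-6)

    def test_monotone_in_perturbation_size(self):
        params = small_params()
        small = run_sensitivity(
            params, ScenarioSpec(incidence_change={("non", "1-2"): -0.01}, horizon=(2007, 2012))
        )
        large = run_sensitivity(
            params, ScenarioSpec(incidence_change={("non", "1-2"): -0.05}, horizon=(2007, 2012))
        )
        assert large["delta_total_ckd"] <= small["delta_total_ckd"]


class TestMonteCarlo:
    def test_identical_seed_gives_identical_bands(self):
        params = small_params()
        spec = {"p_non_12": 0.2, "d_12": 0.2}
        a = monte_carlo_intervals(params, spec, n_draws=25, seed=7)
        b = monte_carlo_intervals(params, spec, n_draws=25, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        params = small_params()
        spec = {"p_non_12": 0.2}
        a = monte_carlo_intervals(params, spec, n_draws=25, seed=7)
        b = monte_carlo_intervals(params, spec, n_draws=25, seed=8)
        assert not a.equals(b)

    def test_zero_spread_degenerates_to_point_projection(self):
        params = small_params()
        point = run_model(params)
        bands = monte_carlo_intervals(params, {"p_non_12": 0.0}, n_draws=10, seed=3)
        final = bands[(bands["year"] == 2012) & (bands["metric"] == "total_ckd")]
        truth = point.metrics.loc[2012, "total_ckd"]
        assert float(final["p2.5"].iloc[0]) == truth
        assert float(final["p50"].iloc[0]) == truth
        assert float(final["p97.5"].iloc[0]) == truth

    def test_band_quantiles_match_analytic_lognormal(self):
        # with a single perturbed parameter and a nearly linear metric, the
        # band endpoints approach the log-normal multiplier quantiles
        cv = 0.2
        params = small_params(
            horizon=(2007, 2009),
            p_non_3=0.0, p_12_3=0.0, p_3_4=0.0, p_4_5=0.0,
        )
        params.base_state = StateVector.from_dict(2007, {H.NON_CKD: 1e6})
        params.background_rates = {y: 0.0 for y in range(2007, 2009)}
        bands = monte_carlo_intervals(
            params, {"p_non_12": cv}, n_draws=4000, seed=11, metrics=("total_ckd",)
        )
        row = bands[(bands["year"] == 2008) & (bands["metric"] == "total_ckd")]
        sigma = np.sqrt(np.log1p(cv * cv))
        expected_lo = 0.01 * 1e6 * np.exp(-0.5 * sigma**2 + sigma * -1.959964)
        expected_hi = 0.01 * 1e6 * np.exp(-0.5 * sigma**2 + sigma * 1.959964)
        assert float(row["p2.5"].iloc[0]) == pytest.approx(expected_lo, rel=0.05)
        assert float(row["p97.5"].iloc[0]) == pytest.approx(expected_hi, rel=0.05)

    def test_too_few_draws_fails(self):
        with pytest.raises(ValueError):
            monte_carlo_intervals(small_params(), {}, n_draws=1, seed=0)
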