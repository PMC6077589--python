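"""Ageing index, base-probability averaging, detection solve, matrix assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ckdproj.rates import (
    ProbabilitySet,
    assemble_transition_matrix,
    compute_ageing_index,
    derive_base_probabilities,
    derive_detection_probabilities,
    forecast_probabilities,
)
from ckdproj.states import HealthState, validate_transition_matrix

H = HealthState

ZERO_RATES = {s: 0.0 for s in ("1-2", "3", "4", "5")}


def pset(**kw) -> ProbabilitySet:
    values = dict(
        p_non_12=0.0, p_non_3=0.0, p_12_3=0.0, p_3_4=0.0, p_4_5=0.0,
        d_12=0.0, d_3=0.0, d_4=0.0,
    )
    values.update(kw)
    return ProbabilitySet(**values)


class TestAgeingIndex:
    def test_reference_year_has_unit_multiplier(self):
        series = {y: 0.10 for y in range(2010, 2016)}
        ageing = compute_ageing_index(series)
        assert ageing.index[2015] == 0.0
        assert ageing.multiplier[2015] == 1.0

    def test_formula_evaluation(self):
        series = {**{y: 0.10 for y in range(2010, 2015)}, 2020: 0.20}
        ageing = compute_ageing_index(series)
        assert ageing.reference == pytest.approx(0.10)
        assert ageing.index[2020] == pytest.approx(0.20 * (0.20 - 0.10) / 0.10)
        assert ageing.multiplier[2020] == pytest.approx(1.20)

    def test_absolute_form(self):
        series = {**{y: 0.10 for y in range(2010, 2015)}, 2020: 0.20}
        ageing = compute_ageing_index(series, form="absolute")
        assert ageing.index[2020] == pytest.approx(0.20 * 0.10)

    def test_monotone_in_elderly_share(self):
        series = {**{y: 0.10 for y in range(2010, 2015)}}
        series.update({2020 + i: 0.10 + 0.01 * (i + 1) for i in range(10)})
        ageing = compute_ageing_index(series)
        mults = [ageing.multiplier[2020 + i] for i in range(10)]
        assert all(b > a for a, b in zip(mults, mults[1:]))

    def test_unknown_form_fails(self):
        with pytest.raises(ValueError, match="form"):
            compute_ageing_index({2010: 0.1}, (2010, 2010), form="quadratic")


class TestBaseProbabilities:
    def test_constant_series(self):
        annual = {y: pset(p_3_4=0.02) for y in range(2010, 2015)}
        assert derive_base_probabilities(annual).p_3_4 == pytest.approx(0.02)

    def test_arithmetic_mean(self):
        annual = {
            2010 + i: pset(p_12_3=0.01 * (i + 1)) for i in range(5)
        }
        assert derive_base_probabilities(annual).p_12_3 == pytest.approx(0.03)

    def test_missing_year_fails(self):
        with pytest.raises(ValueError, match="missing"):
            derive_base_probabilities({2010: pset()})


class TestDetectionSolve:
    def test_single_stage(self):
        d = derive_detection_probabilities(10.0, {"1-2": 100.0}, {"1-2": 0.01})
        assert d["1-2"] == pytest.approx(0.10)

    def test_hand_solved_linear_system(self):
        d = derive_detection_probabilities(
            35.0,
            {"1-2": 100.0, "3": 100.0, "4": 100.0},
            {"1-2": 0.01, "3": 0.02, "4": 0.04},
        )
        assert d["1-2"] == pytest.approx(0.05)
        assert d["3"] == pytest.approx(0.10)
        assert d["4"] == pytest.approx(0.20)

    def test_ratio_identity_holds_exactly(self, rng):
        for _ in range(20):
            pools = {s: float(10 + 990 * rng.random()) for s in ("1-2", "3", "4")}
            mr = {s: float(0.001 + 0.05 * rng.random()) for s in ("1-2", "3", "4")}
            d = derive_detection_probabilities(float(5 + 20 * rng.random()), pools, mr)
            assert d["3"] / d["1-2"] == pytest.approx(mr["3"] / mr["1-2"], rel=1e-12)
            assert d["4"] / d["1-2"] == pytest.approx(mr["4"] / mr["1-2"], rel=1e-12)

    def test_clipping_warns(self, caplog):
        with caplog.at_level("WARNING"):
            d = derive_detection_probabilities(
                500.0, {"1-2": 100.0, "3": 100.0, "4": 100.0},
                {"1-2": 0.01, "3": 0.02, "4": 0.04},
            )
        assert max(d.values()) == 1.0
        assert "clipped" in caplog.text

    def test_zero_pool_fails(self):
        with pytest.raises(ValueError):
            derive_detection_probabilities(10.0, {"1-2": 0.0}, {"1-2": 0.01})


class TestForecastProbabilities:
    def _ageing(self, multipliers):
        from ckdproj.rates import AgeingIndexSeries

        return AgeingIndexSeries(
            elderly={y: 0.1 for y in multipliers},
            reference=0.1,
            index={y: m - 1 for y, m in multipliers.items()},
            multiplier=dict(multipliers),
        )

    def test_unit_multiplier_reproduces_base(self):
        base = pset(p_3_4=0.02, p_4_5=0.05, d_12=0.1)
        out = forecast_probabilities(base, self._ageing({2020: 1.0}), (2020, 2020))
        assert out[2020] == base

    def test_elevation_and_stage45_exemption(self):
        base = pset(p_3_4=0.02, p_4_5=0.05, d_12=0.1)
        out = forecast_probabilities(base, self._ageing({2020: 1.2}), (2020, 2020))
        assert out[2020].p_3_4 == pytest.approx(0.024)
        assert out[2020].d_12 == pytest.approx(0.12)
        assert out[2020].p_4_5 == 0.05  # never elevated
        assert out[2020].d_5 == 1.0

    def test_order_preserving(self):
        base = pset(p_3_4=0.02, d_3=0.3)
        small = forecast_probabilities(base, self._ageing({2020: 1.1}), (2020, 2020))
        large = forecast_probabilities(base, self._ageing({2020: 1.5}), (2020, 2020))
        assert large[2020].p_3_4 >= small[2020].p_3_4
        assert large[2020].d_3 >= small[2020].d_3

    def test_missing_horizon_year_fails(self):
        with pytest.raises(ValueError, match="missing"):
            forecast_probabilities(pset(), self._ageing({2020: 1.0}), (2020, 2021))


class TestAssembleMatrix:
    def test_degenerate_inputs_give_identity(self):
        matrix = assemble_transition_matrix(pset(), ZERO_RATES, 0.0, 2007)
        np.testing.assert_allclose(matrix.probs, np.eye(9))

    def test_onset_split_by_detection(self):
        probs = pset(p_non_12=0.1, d_12=0.3)
        matrix = assemble_transition_matrix(probs, ZERO_RATES, 0.0, 2007)
        assert matrix[(H.NON_CKD, H.S12_DETECTED)] == pytest.approx(0.03)
        assert matrix[(H.NON_CKD, H.S12_UNDETECTED)] == pytest.approx(0.07)
        assert matrix[(H.NON_CKD, H.NON_CKD)] == pytest.approx(0.90)

    def test_stage4_routes_to_stage5_fully_detected(self):
        probs = pset(p_4_5=0.08)
        matrix = assemble_transition_matrix(probs, ZERO_RATES, 0.0, 2007)
        assert matrix[(H.S4_UNDETECTED, H.S5)] == pytest.approx(0.08)
        assert matrix[(H.S4_DETECTED, H.S5)] == pytest.approx(0.08)

    def test_death_competes_proportionally(self):
        probs = pset(p_non_12=0.1, d_12=0.3)
        rates = {s: 0.05 for s in ("1-2", "3", "4", "5")}
        matrix = assemble_transition_matrix(probs, rates, 0.02, 2007)
        assert matrix[(H.NON_CKD, H.DEATH)] == pytest.approx(0.02)
        assert matrix[(H.NON_CKD, H.S12_DETECTED)] == pytest.approx(0.03 * 0.98)
        assert matrix[(H.S5, H.DEATH)] == pytest.approx(0.05)

    def test_within_stage_detection_flag(self):
        probs = pset(p_12_3=0.1, d_12=0.2, d_3=0.4)
        off = assemble_transition_matrix(probs, ZERO_RATES, 0.0, 2007)
        assert off[(H.S12_UNDETECTED, H.S12_DETECTED)] == 0.0
        on = assemble_transition_matrix(
            probs, ZERO_RATES, 0.0, 2007, within_stage_detection=True
        )
        assert on[(H.S12_UNDETECTED, H.S12_DETECTED)] == pytest.approx(0.9 * 0.2)

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(0.0, 1.0, allow_nan=False), min_size=8, max_size=8
        ),
        mr=st.floats(0.0, 0.5),
        bg=st.floats(0.0, 0.5),
        within=st.booleans(),
    )
    def test_rows_stochastic_for_admissible_inputs(self, values, mr, bg, within):
        # the two onset flows out of the disease-free state share one budget
        values = list(values)
        values[1] = min(values[1], 1.0 - values[0])
        probs = ProbabilitySet(*values)
        rates = {s: mr for s in ("1-2", "3", "4", "5")}
        matrix = assemble_transition_matrix(probs, rates, bg, 2007, within)
        report = validate_transition_matrix(matrix)
        assert report.ok, str(report)

    def test_round_trip_extraction(self, rng):
        for _ in range(10):
            values = rng.random(8) * np.array([0.3, 0.3, 0.3, 0.3, 0.3, 0.9, 0.9, 0.9])
            probs = ProbabilitySet(*values)
            rates = {s: float(0.05 * rng.random()) for s in ("1-2", "3", "4", "5")}
            bg = float(0.02 * rng.random())
            matrix = assemble_transition_matrix(probs, rates, bg, 2007)
            surv = 1.0 - bg
            p12 = (
                matrix[(H.NON_CKD, H.S12_DETECTED)]
                + matrix[(H.NON_CKD, H.S12_UNDETECTED)]
            ) / surv
            assert p12 == pytest.approx(probs.p_non_12, rel=1e-9)
            if p12 > 0:
                d12 = matrix[(H.NON_CKD, H.S12_DETECTED)] / (p12 * surv)
                assert d12 == pytest.approx(probs.d_12, rel=1e-9)
            surv12 = 1.0 - rates["1-2"]
            p123 = (
                matrix[(H.S12_DETECTED, H.S3_DETECTED)]
                + matrix[(H.S12_DETECTED, H.S3_UNDETECTED)]
            ) / surv12
            assert p123 == pytest.approx(probs.p_12_3, rel=1e-9)
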