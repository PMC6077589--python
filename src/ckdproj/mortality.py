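"""Mortality decomposition: stage rates, background-rate solve, forecasts.

The model assumes the mortality rate of stage-i CKD patients is a relative
risk times the background (non-CKD) rate, ``MR_it = RR_i * MR_t``.  Given a
national death total MV_t and the current state occupancy, the background
rate is identified by dividing MV_t by the RR-weighted alive population:

    MR_t = MV_t / (sum_i RR_i * CKD_it + NCKD_t)

so that re-expanding per-stage deaths reproduces MV_t exactly.  Rates are
annual probabilities throughout (one-year cycles; no hazard conversion).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .states import STAGES, HealthState, StateVector

__all__ = [
    "MortalitySchedule",
    "RelativeRisk",
    "stage_mortality",
    "expected_deaths",
    "solve_background_mortality",
    "historical_relative_risks",
    "forecast_death_totals",
]

#: default averaging window for the reference relative risks
DEFAULT_RR_WINDOW = (2010, 2014)


@dataclass
class RelativeRisk:
    """Per-year per-stage relative risks of death and their window averages."""

    annual: dict[int, dict[str, float]]
    average: dict[str, float]

    def __post_init__(self) -> None:
        for year, rrs in self.annual.items():
            for stage, rr in rrs.items():
                if rr <= 0:
                    raise ValueError(f"RR[{year}][{stage}] = {rr} must be positive")
        for stage, rr in self.average.items():
            if rr <= 0:
                raise ValueError(f"average RR[{stage}] = {rr} must be positive")


@dataclass
class MortalitySchedule:
    """Background rate, per-stage rates, and national death totals by year."""

    background: dict[int, float] = field(default_factory=dict)
    by_stage: dict[int, dict[str, float]] = field(default_factory=dict)
    death_totals: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for year, rate in self.background.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"background rate {rate} for {year} outside [0, 1]")
        for year, rates in self.by_stage.items():
            for stage, rate in rates.items():
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(
                        f"stage {stage} rate {rate} for {year} outside [0, 1]"
                    )


def stage_mortality(rr: float, background_rate: float) -> float:
    """Stage mortality rate as relative risk times background rate, capped at 1."""
    if rr < 0 or background_rate < 0:
        raise ValueError("rr and background_rate must be non-negative")
    if background_rate > 1:
        raise ValueError("background_rate must be at most 1")
    return min(rr * background_rate, 1.0)


def _rr_map(rr) -> dict[str, float]:
    if isinstance(rr, RelativeRisk):
        return rr.average
    return dict(rr)


def expected_deaths(state: StateVector, rr, background_rate: float) -> float:
    """Total deaths implied by the state occupancy and the rate decomposition.

    MV_t = sum_i MR_it * CKD_it + MR_t * NCKD_t with MR_it = RR_i * MR_t.
    """
    rrs = _rr_map(rr)
    total = background_rate * state.non_ckd
    for stage in STAGES:
        total += stage_mortality(rrs[stage], background_rate) * state.stage_total(stage)
    return total


def solve_background_mortality(total_deaths: float, state: StateVector, rr) -> float:
    """Identify the background (non-CKD) mortality rate from a national death total.

    Divides the death total by the RR-weighted alive population; substituting
    the result back into the death decomposition reproduces the input total.
    """
    if total_deaths < 0:
        raise ValueError("total_deaths must be non-negative")
    rrs = _rr_map(rr)
    denom = state.non_ckd + sum(
        rrs[stage] * state.stage_total(stage) for stage in STAGES
    )
    if denom <= 0:
        raise ValueError("RR-weighted alive population must be positive")
    return total_deaths / denom


def historical_relative_risks(
    stage_rates: dict[int, dict[str, float]],
    background_rates: dict[int, float],
    window: tuple[int, int] = DEFAULT_RR_WINDOW,
) -> RelativeRisk:
    """Annual relative risks MR_it / MR_t and their window arithmetic means."""
    annual: dict[int, dict[str, float]] = {}
    for year, rates in stage_rates.items():
        mr_t = background_rates[year]
        if mr_t <= 0:
            raise ValueError(f"background rate for {year} must be positive")
        annual[year] = {stage: mr_it / mr_t for stage, mr_it in rates.items()}
    lo, hi = window
    years = [y for y in range(lo, hi + 1)]
    missing = [y for y in years if y not in annual]
    if missing:
        raise ValueError(f"window years missing from inputs: {missing}")
    stages = sorted(annual[years[0]])
    average = {
        stage: float(np.mean([annual[y][stage] for y in years])) for stage in stages
    }
    return RelativeRisk(annual, average)


def forecast_death_totals(
    population_series: dict[int, float],
    life_expectancy: dict[int, float],
    under21_deaths: dict[int, float],
    years: tuple[int, int] = (2015, 2035),
) -> dict[int, float]:
    """Forecast national adult (21+) death totals per year.

    Uses a stationary-population approximation — all-age deaths of roughly
    population over period life expectancy — minus deaths under age 21.
    Each component can be overridden by supplying its series directly.
    """
    lo, hi = years
    totals: dict[int, float] = {}
    for year in range(lo, hi + 1):
        missing = [
            name
            for name, series in (
                ("population", population_series),
                ("life_expectancy", life_expectancy),
                ("under21_deaths", under21_deaths),
            )
            if year not in series
        ]
        if missing:
            raise ValueError(f"series {missing} missing year {year}")
        le = life_expectancy[year]
        if le <= 0:
            raise ValueError(f"life expectancy for {year} must be positive")
        totals[year] = population_series[year] / le - under21_deaths[year]
        if totals[year] < 0:
            raise ValueError(f"negative adult death total for {year}")
    return totals
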