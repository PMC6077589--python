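"""28-cycle cohort projection, burden metrics, sensitivity and uncertainty.

Runs the annual cohort update from the 2007 base year out to 2035,
collecting per-year burden metrics (total CKD, prevalence, undiagnosed
burden by stage, stage shares).  Supports scenario analysis (compounded
annual changes to incidence or detection probabilities) and Monte-Carlo
parameter uncertainty via independent log-normal multiplicative
perturbations of the transition and detection probabilities.
"""

from __future__ import annotations

import decimal
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mortality import solve_background_mortality, stage_mortality
from .rates import ProbabilitySet, assemble_transition_matrix
from .states import (
    STAGES,
    HealthState,
    StateVector,
    TransitionMatrix,
    entrants_vector,
    step_cohort,
)

__all__ = [
    "ProjectionResult",
    "ScenarioSpec",
    "ModelParameters",
    "build_transition_matrices",
    "run_projection",
    "run_model",
    "summarize",
    "run_sensitivity",
    "monte_carlo_intervals",
    "render_percent",
]

logger = logging.getLogger(__name__)

BASE_YEAR = 2007
END_YEAR = 2035


def render_percent(fraction: float) -> float:
    """Render a fraction as a percentage rounded half-up to one decimal."""
    return float(
        decimal.Decimal(fraction * 100).quantize(
            decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
        )
    )


@dataclass
class ProjectionResult:
    """Annual state trajectory plus derived burden metrics.

    ``metrics`` holds one row per year; ``bands`` (optional) holds the
    2.5/50/97.5 percentile of each metric per year from a Monte-Carlo run.
    """

    states: list[StateVector]
    metrics: pd.DataFrame
    bands: pd.DataFrame | None = None

    @property
    def years(self) -> list[int]:
        return [s.year for s in self.states]

    def state_at(self, year: int) -> StateVector:
        for s in self.states:
            if s.year == year:
                return s
        raise KeyError(f"year {year} not in projection")


@dataclass
class ScenarioSpec:
    """Compounded annual multiplicative changes for sensitivity analysis.

    ``incidence_change`` maps a progression edge (source stage, destination
    stage) to an annual rate r; the year-t probability is multiplied by
    (1 + r)^(t - base year).  ``detection_change`` does the same per stage
    for detection probabilities.
    """

    incidence_change: dict[tuple[str, str], float] = field(default_factory=dict)
    detection_change: dict[str, float] = field(default_factory=dict)
    horizon: tuple[int, int] = (BASE_YEAR, END_YEAR)

    def apply(self, probabilities: ProbabilitySet, year: int) -> ProbabilitySet:
        t = year - self.horizon[0]
        if t < 0 or year >= self.horizon[1]:
            return probabilities
        prog = {
            edge: (1.0 + rate) ** t for edge, rate in self.incidence_change.items()
        }
        det = {stage: (1.0 + rate) ** t for stage, rate in self.detection_change.items()}
        for factor in list(prog.values()) + list(det.values()):
            if factor <= 0:
                raise ValueError("compounded scenario multiplier must stay positive")
        return probabilities.scaled(prog, det)


@dataclass
class ModelParameters:
    """Everything needed to run the projection end to end.

    Mortality is specified either as a per-year background-rate series, or
    as per-year national death totals plus reference relative risks, in
    which case the background rate is solved each cycle from the current
    state occupancy (the forecast-mortality route).  Entrants either follow
    a target population path with annual growth ``population_growth`` (the
    entrant count closes the demographic balance each cycle) or are supplied
    explicitly per year.
    """

    base_state: StateVector
    probabilities: dict[int, ProbabilitySet]
    rr: dict[str, float]
    background_rates: dict[int, float] | None = None
    death_totals: dict[int, float] | None = None
    population_growth: float = 0.0
    entrants: dict[int, np.ndarray] | None = None
    within_stage_detection: bool = False
    horizon: tuple[int, int] = (BASE_YEAR, END_YEAR)

    def background_rate_for(self, state: StateVector) -> float:
        year = state.year
        if self.background_rates is not None and year in self.background_rates:
            return self.background_rates[year]
        if self.death_totals is None or year not in self.death_totals:
            raise ValueError(f"no mortality input for year {year}")
        return solve_background_mortality(self.death_totals[year], state, self.rr)

    def stage_rates(self, background: float) -> dict[str, float]:
        return {s: stage_mortality(self.rr[s], background) for s in STAGES}

    def replace_probabilities(
        self, probabilities: dict[int, ProbabilitySet]
    ) -> "ModelParameters":
        return ModelParameters(
            base_state=self.base_state,
            probabilities=probabilities,
            rr=self.rr,
            background_rates=self.background_rates,
            death_totals=self.death_totals,
            population_growth=self.population_growth,
            entrants=self.entrants,
            within_stage_detection=self.within_stage_detection,
            horizon=self.horizon,
        )


def build_transition_matrices(
    probabilities: dict[int, ProbabilitySet],
    background_rates: dict[int, float],
    rr: dict[str, float],
    within_stage_detection: bool = False,
) -> dict[int, TransitionMatrix]:
    """Assemble one matrix per year from probabilities and the mortality model."""
    matrices: dict[int, TransitionMatrix] = {}
    for year, probs in probabilities.items():
        background = background_rates[year]
        stage_rates = {s: stage_mortality(rr[s], background) for s in STAGES}
        matrices[year] = assemble_transition_matrix(
            probs, stage_rates, background, year, within_stage_detection
        )
    return matrices


def _metrics_row(state: StateVector) -> dict[str, float]:
    alive = state.alive_total
    total_ckd = state.total_ckd
    row: dict[str, float] = {
        "year": state.year,
        "alive": alive,
        "non_ckd": state.non_ckd,
        "total_ckd": total_ckd,
        "prevalence": total_ckd / alive if alive > 0 else np.nan,
        "cumulative_deaths": state[HealthState.DEATH],
    }
    undiag_total = 0.0
    for stage in STAGES:
        total = state.stage_total(stage)
        undet = state.stage_undetected(stage)
        undiag_total += undet
        key = stage.replace("-", "")
        row[f"stage{key}_count"] = total
        row[f"stage{key}_undiagnosed"] = undet
        row[f"stage{key}_undiag_prevalence"] = undet / alive if alive > 0 else np.nan
        row[f"stage{key}_share"] = total / total_ckd if total_ckd > 0 else np.nan
    row["undiagnosed_count"] = undiag_total
    row["undiag_prevalence"] = undiag_total / alive if alive > 0 else np.nan
    row["proportion_undiagnosed"] = (
        undiag_total / total_ckd if total_ckd > 0 else np.nan
    )
    row["detection_rate"] = (
        1.0 - row["proportion_undiagnosed"] if total_ckd > 0 else np.nan
    )
    return row


def _result_from_states(states: list[StateVector]) -> ProjectionResult:
    metrics = pd.DataFrame([_metrics_row(s) for s in states]).set_index("year")
    return ProjectionResult(states, metrics)


def run_projection(
    base_state: StateVector,
    matrices: dict[int, TransitionMatrix],
    entrants: dict[int, np.ndarray] | None = None,
) -> ProjectionResult:
    """Apply the annual update through the horizon with precomputed matrices.

    Matrices must cover every cycle year (base year through the year before
    the final snapshot).  Conservation — alive plus cumulative deaths minus
    cumulative entrants constant — is checked every cycle.
    """
    states = [base_state.copy()]
    state = states[0]
    years = sorted(matrices)
    expected = list(range(base_state.year, max(years) + 1))
    missing = [y for y in expected if y not in matrices]
    if missing:
        raise ValueError(f"transition matrices missing for years {missing}")
    cumulative_entrants = 0.0
    baseline_total = float(state.counts.sum())
    for year in expected:
        vec = entrants.get(year) if entrants else None
        state = step_cohort(state, matrices[year], vec)
        cumulative_entrants += float(vec.sum()) if vec is not None else 0.0
        closed = state.counts.sum() - cumulative_entrants
        if abs(closed - baseline_total) > 1e-6 * max(baseline_total, 1.0):
            raise ArithmeticError(f"conservation violated after cycle {year}")
        states.append(state)
    return _result_from_states(states)


def run_model(
    params: ModelParameters,
    scenario: ScenarioSpec | None = None,
) -> ProjectionResult:
    """Run the full projection, solving mortality and entrants cycle by cycle.

    Each cycle: the background mortality rate is taken from the series or
    solved from the national death total and the current occupancy; stage
    rates follow from the relative risks; the year's probabilities (after
    any scenario adjustment) are assembled into a matrix; the cohort is
    stepped; entrants close the demographic balance to the target
    population path when ``population_growth`` is set.
    """
    lo, hi = params.horizon
    state = params.base_state.copy()
    if state.year != lo:
        raise ValueError(f"base state year {state.year} != horizon start {lo}")
    states = [state]
    base_alive = state.alive_total
    for year in range(lo, hi):
        probs = params.probabilities.get(year)
        if probs is None:
            raise ValueError(f"no probability set for year {year}")
        if scenario is not None:
            probs = scenario.apply(probs, year)
        background = params.background_rate_for(state)
        matrix = assemble_transition_matrix(
            probs,
            params.stage_rates(background),
            background,
            year,
            params.within_stage_detection,
        )
        stepped = step_cohort(state, matrix)
        if params.entrants is not None and year in params.entrants:
            entrant_vec = params.entrants[year]
        else:
            target = base_alive * (1.0 + params.population_growth) ** (year + 1 - lo)
            total = max(target - stepped.alive_total, 0.0)
            entrant_vec = entrants_vector(total)
        state = StateVector(stepped.year, stepped.counts + entrant_vec)
        states.append(state)
    return _result_from_states(states)


def summarize(result: ProjectionResult, year: int) -> dict[str, float]:
    """One year's burden metrics, with rendered (one-decimal) percentages.

    Full-precision fractions stay in ``result.metrics``; the ``*_pct``
    entries here round half-up to one decimal, the reporting convention.
    """
    if year not in result.metrics.index:
        raise KeyError(f"year {year} not in projection")
    row = result.metrics.loc[year]
    out = {k: float(v) for k, v in row.items()}
    for key in list(out):
        if "prevalence" in key or "share" in key or key in (
            "proportion_undiagnosed",
            "detection_rate",
        ):
            out[f"{key}_pct"] = render_percent(out[key])
    return out


def run_sensitivity(
    params: ModelParameters,
    scenario: ScenarioSpec,
) -> dict[str, float]:
    """Final-year differences of a scenario run against the baseline run.

    Negative ``delta_total_ckd`` means the scenario prevents cases; negative
    ``delta_undetected`` means it reduces the undiagnosed pool.
    """
    baseline = run_model(params)
    varied = run_model(params, scenario=scenario)
    final = params.horizon[1]
    return {
        "final_year": float(final),
        "baseline_total_ckd": float(baseline.metrics.loc[final, "total_ckd"]),
        "scenario_total_ckd": float(varied.metrics.loc[final, "total_ckd"]),
        "delta_total_ckd": float(
            varied.metrics.loc[final, "total_ckd"]
            - baseline.metrics.loc[final, "total_ckd"]
        ),
        "baseline_undetected": float(baseline.metrics.loc[final, "undiagnosed_count"]),
        "scenario_undetected": float(varied.metrics.loc[final, "undiagnosed_count"]),
        "delta_undetected": float(
            varied.metrics.loc[final, "undiagnosed_count"]
            - baseline.metrics.loc[final, "undiagnosed_count"]
        ),
    }


def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    # mean-one log-normal multiplier; cv = 0 degenerates to exactly 1
    if cv == 0:
        return 1.0
    sigma = np.sqrt(np.log1p(cv * cv))
    return float(np.exp(rng.normal(-0.5 * sigma * sigma, sigma)))


def monte_carlo_intervals(
    params: ModelParameters,
    perturbation_spec: dict[str, float],
    n_draws: int,
    seed: int,
    metrics: tuple[str, ...] = (
        "total_ckd",
        "prevalence",
        "undiagnosed_count",
        "proportion_undiagnosed",
    ),
) -> pd.DataFrame:
    """Percentile bands from log-normal parameter perturbations.

    ``perturbation_spec`` maps a probability field name (``p_non_12`` ...
    ``d_4``) to a coefficient of variation; each draw multiplies that field
    by an independent mean-one log-normal factor in every year, re-runs the
    projection, and the 2.5/50/97.5 percentiles per metric per year are
    returned.  Identical seed and spec give bit-identical bands.  Draws that
    fail matrix validation are rejected and redrawn (logged).
    """
    if n_draws < 2:
        raise ValueError("n_draws must be at least 2")
    for name, cv in perturbation_spec.items():
        if cv < 0:
            raise ValueError(f"spread for {name} must be non-negative")
    rng = np.random.default_rng(seed)
    samples: list[pd.DataFrame] = []
    rejections = 0
    while len(samples) < n_draws:
        factors = {
            name: _lognormal_factor(rng, cv) for name, cv in perturbation_spec.items()
        }
        perturbed: dict[int, ProbabilitySet] = {}
        try:
            for year, probs in params.probabilities.items():
                values = probs.as_dict()
                for name, f in factors.items():
                    values[name] = min(values[name] * f, 1.0)
                perturbed[year] = ProbabilitySet(**values)
            result = run_model(params.replace_probabilities(perturbed))
        except (ValueError, ArithmeticError) as exc:
            rejections += 1
            logger.warning("rejected Monte-Carlo draw: %s", exc)
            if rejections > 100 * n_draws:
                raise RuntimeError("Monte-Carlo rejection rate too high") from exc
            continue
        samples.append(result.metrics[list(metrics)])
    if rejections:
        logger.info("Monte-Carlo run rejected %d draws", rejections)
    stacked = np.stack([s.to_numpy() for s in samples])  # draw x year x metric
    percentiles = np.percentile(stacked, [2.5, 50.0, 97.5], axis=0)
    years = samples[0].index
    rows = []
    for yi, year in enumerate(years):
        for mi, metric in enumerate(metrics):
            rows.append(
                {
                    "year": year,
                    "metric": metric,
                    "p2.5": percentiles[0, yi, mi],
                    "p50": percentiles[1, yi, mi],
                    "p97.5": percentiles[2, yi, mi],
                }
            )
    return pd.DataFrame(rows)
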