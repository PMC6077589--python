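"""Synthetic disease-registry generator and parameter-recovery pipeline.

Real registry extracts behind the model are access-restricted, so every
estimator in the package is validated against synthetic observations drawn
from known ground truth.  The generator runs the cohort model forward from
a configurable base year, records the exact per-edge flows, and emits

* a deterministic national series (population, death totals satisfying the
  mortality decomposition exactly, elderly share, per-stage case counts,
  stage-5 incidence), and
* registry-like observations: per-stage prevalent counts thinned by stage
  coverage (binomial), per-edge incident transition counts thinned by the
  destination-stage coverage (Poisson), a detected-incident total thinned
  by the detected-CKD coverage (Poisson), and per-stage death counts
  (Poisson event noise only — death ascertainment is via national
  death-registry linkage, so no coverage thinning applies).

With noise disabled the observations equal their expected values and the
full pipeline (generate -> estimate coverage -> recover rates) inverts the
ground truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from .calibration import CoverageEstimate, estimate_coverage
from .mortality import historical_relative_risks
from .rates import ProbabilitySet, assemble_transition_matrix, derive_detection_probabilities
from .states import (
    STAGES,
    STAGE_STATES,
    HealthState,
    StateVector,
    entrants_vector,
    step_cohort,
)

__all__ = [
    "GroundTruth",
    "TruthTrajectory",
    "RecoveredParameters",
    "simulate_truth",
    "generate_national_series",
    "generate_registry_observations",
    "recover_parameters",
    "parameter_recovery_report",
]

#: progression edges as (source, destination) stage labels; "non" = no CKD.
EDGE_LABELS = (("non", "1-2"), ("non", "3"), ("1-2", "3"), ("3", "4"), ("4", "5"))

_SOURCE_STATES = {
    "non": (HealthState.NON_CKD,),
    "1-2": (HealthState.S12_UNDETECTED, HealthState.S12_DETECTED),
    "3": (HealthState.S3_UNDETECTED, HealthState.S3_DETECTED),
    "4": (HealthState.S4_UNDETECTED, HealthState.S4_DETECTED),
    "5": (HealthState.S5,),
}


def _default_probabilities() -> ProbabilitySet:
    # detection probabilities satisfy the mortality-rate-ratio identity for
    # the default relative risks (d_3 = d_12 * 2.5/1.5, d_4 = d_12 * 5/1.5)
    return ProbabilitySet(
        p_non_12=0.008,
        p_non_3=0.004,
        p_12_3=0.05,
        p_3_4=0.02,
        p_4_5=0.10,
        d_12=0.15,
        d_3=0.25,
        d_4=0.50,
    )


@dataclass
class GroundTruth:
    """Known parameters behind a synthetic registry.

    Defaults emulate the study setting: base prevalences matching the
    calibrated 2007 burden, relative risks of death rising with stage
    within the reported hazard-ratio range (stage 5 higher, as dialysis
    mortality is), registry coverage rising with severity, and a 70%
    registry coverage of detected CKD.
    """

    probabilities: ProbabilitySet = field(default_factory=_default_probabilities)
    rr: dict[str, float] = field(
        default_factory=lambda: {"1-2": 1.5, "3": 2.5, "4": 5.0, "5": 10.0}
    )
    coverage: dict[str, float] = field(
        default_factory=lambda: {"1-2": 0.45, "3": 0.60, "5": 0.85}
    )
    detected_coverage: float = 0.70
    population: float = 1_000_000.0
    base_prevalence: dict[str, float] = field(
        default_factory=lambda: {"1-2": 0.056, "3": 0.053, "4": 0.00933, "5": 0.00324}
    )
    base_undiagnosed: dict[str, float] = field(
        default_factory=lambda: {"1-2": 0.853, "3": 0.669, "4": 0.473}
    )
    background_mortality: float = 0.0065
    population_growth: float = 0.01
    elderly_2007: float = 0.085
    elderly_annual_increase: float = 0.004
    years: tuple[int, int] = (2007, 2014)
    seed: int = 0

    def __post_init__(self) -> None:
        for stage, cov in self.coverage.items():
            if not (0.0 < cov <= 1.0):
                raise ValueError(f"coverage[{stage}] = {cov} outside (0, 1]")
        if "4" not in self.coverage:
            self.coverage = dict(self.coverage)
            self.coverage["4"] = 0.5 * (self.coverage["3"] + self.coverage["5"])

    def with_ratio_consistent_detection(self) -> "GroundTruth":
        """Force d_3 and d_4 onto the mortality-rate-ratio identity.

        The detection-probability estimator assumes d_i / d_{1-2} equals the
        stage mortality-rate ratio; a truth satisfying it is exactly
        recoverable, so validation uses this variant.
        """
        r3 = self.rr["3"] / self.rr["1-2"]
        r4 = self.rr["4"] / self.rr["1-2"]
        probs = dc_replace(
            self.probabilities,
            d_3=min(self.probabilities.d_12 * r3, 1.0),
            d_4=min(self.probabilities.d_12 * r4, 1.0),
        )
        return dc_replace(self, probabilities=probs)

    def base_state(self) -> StateVector:
        pop = self.population
        counts: dict[HealthState, float] = {}
        total_ckd = 0.0
        for stage in STAGES:
            total = self.base_prevalence[stage] * pop
            total_ckd += total
            undet_state, det_state = STAGE_STATES[stage]
            undiag = self.base_undiagnosed.get(stage, 0.0)
            if undet_state is not None:
                counts[undet_state] = total * undiag
                counts[det_state] = total * (1.0 - undiag)
            else:
                counts[det_state] = total
        counts[HealthState.NON_CKD] = pop - total_ckd
        counts[HealthState.DEATH] = 0.0
        return StateVector.from_dict(self.years[0], counts)

    def elderly_series(self) -> dict[int, float]:
        lo, hi = self.years
        return {
            y: self.elderly_2007 + self.elderly_annual_increase * (y - lo)
            for y in range(lo, hi + 1)
        }


@dataclass
class TruthTrajectory:
    """Exact expected-value trajectory and flow decomposition of a truth run."""

    states: list[StateVector]
    flows: pd.DataFrame  # year, from_stage, to_stage, count (progression edges)
    incident: dict[int, dict[str, float]]  # new entrants into each stage per cycle
    detected_incident: dict[int, dict[str, float]]
    deaths: pd.DataFrame  # year, stage ('non', '1-2', ... '5'), count
    death_totals: dict[int, float]

    def state_at(self, year: int) -> StateVector:
        for s in self.states:
            if s.year == year:
                return s
        raise KeyError(year)


def simulate_truth(truth: GroundTruth) -> TruthTrajectory:
    """Run the cohort model at the truth parameters, recording per-edge flows.

    Flows for cycle year t are the exact expected transitions between the
    start-of-year t and start-of-year t+1 snapshots; death totals equal the
    mortality decomposition applied to the year-t occupancy, exactly.
    """
    lo, hi = truth.years
    state = truth.base_state()
    stage_rates = {
        s: min(truth.rr[s] * truth.background_mortality, 1.0) for s in STAGES
    }
    states = [state]
    flow_rows: list[dict] = []
    death_rows: list[dict] = []
    incident: dict[int, dict[str, float]] = {}
    detected_incident: dict[int, dict[str, float]] = {}
    death_totals: dict[int, float] = {}
    for year in range(lo, hi):
        matrix = assemble_transition_matrix(
            truth.probabilities, stage_rates, truth.background_mortality, year
        )
        F = state.counts[:, None] * matrix.probs  # exact pairwise flows
        for src, dst in EDGE_LABELS:
            count = sum(
                F[s.index, d.index]
                for s in _SOURCE_STATES[src]
                for d in _SOURCE_STATES[dst]
            )
            flow_rows.append(
                {"year": year, "from_stage": src, "to_stage": dst, "count": count}
            )
        incident[year] = {}
        detected_incident[year] = {}
        for stage in STAGES:
            dests = _SOURCE_STATES[stage]
            sources = [
                s for s in HealthState if s not in dests and s is not HealthState.DEATH
            ]
            total_in = sum(F[s.index, d.index] for s in sources for d in dests)
            det_state = STAGE_STATES[stage][1]
            det_in = sum(F[s.index, det_state.index] for s in sources)
            incident[year][stage] = total_in
            detected_incident[year][stage] = det_in
        for label, group in _SOURCE_STATES.items():
            death_rows.append(
                {
                    "year": year,
                    "stage": label,
                    "count": sum(F[s.index, HealthState.DEATH.index] for s in group),
                }
            )
        # new deaths this cycle: flows from alive sources only (the
        # DEATH -> DEATH self-flow carries the cumulative count)
        death_totals[year] = float(
            F[: HealthState.DEATH.index, HealthState.DEATH.index].sum()
        )
        stepped = step_cohort(state, matrix)
        target = truth.population * (1.0 + truth.population_growth) ** (year + 1 - lo)
        entrants = max(target - stepped.alive_total, 0.0)
        state = StateVector(stepped.year, stepped.counts + entrants_vector(entrants))
        states.append(state)
    return TruthTrajectory(
        states,
        pd.DataFrame(flow_rows),
        incident,
        detected_incident,
        pd.DataFrame(death_rows),
        death_totals,
    )


def generate_national_series(
    truth: GroundTruth, trajectory: TruthTrajectory | None = None
) -> pd.DataFrame:
    """Deterministic national series implied by the truth parameters.

    One row per year: alive population, national death total for the cycle
    starting that year, elderly share, per-stage national case counts, and
    national stage-5 incidence (new renal-failure cases during the cycle).
    """
    if trajectory is None:
        trajectory = simulate_truth(truth)
    elderly = truth.elderly_series()
    rows = []
    for state in trajectory.states:
        year = state.year
        row = {
            "year": year,
            "population": state.alive_total,
            "elderly_share": elderly[year],
            "deaths": trajectory.death_totals.get(year, np.nan),
            "stage5_incidence": np.nan,
        }
        if year in trajectory.incident:
            row["stage5_incidence"] = trajectory.incident[year]["5"]
        for stage in STAGES:
            row[f"stage{stage.replace('-', '')}_count"] = state.stage_total(stage)
        rows.append(row)
    return pd.DataFrame(rows)


def generate_registry_observations(
    truth: GroundTruth,
    trajectory: TruthTrajectory | None = None,
    noise: bool = True,
) -> dict[str, pd.DataFrame]:
    """Registry-like observations with coverage thinning and sampling noise.

    Returns four tables: ``prevalent`` (year, stage, count), ``transitions``
    (year, from_stage, to_stage, count), ``detected_incident`` (year, count
    over stages 1-4), and ``deaths`` (year, stage, count, including the
    ``non`` background row).  Identical truth and seed give identical
    output; ``noise=False`` returns exact expected values.
    """
    if trajectory is None:
        trajectory = simulate_truth(truth)
    rng = np.random.default_rng(truth.seed)

    def binomial(n_expected: float, p: float) -> float:
        if not noise:
            return n_expected * p
        return float(rng.binomial(int(round(n_expected)), p))

    def poisson(mean: float) -> float:
        if not noise:
            return mean
        return float(rng.poisson(mean))

    prevalent_rows = []
    for state in trajectory.states:
        for stage in STAGES:
            prevalent_rows.append(
                {
                    "year": state.year,
                    "stage": stage,
                    "count": binomial(state.stage_total(stage), truth.coverage[stage]),
                }
            )
    transition_rows = []
    for _, row in trajectory.flows.iterrows():
        cov = truth.coverage[row["to_stage"]]
        transition_rows.append(
            {
                "year": int(row["year"]),
                "from_stage": row["from_stage"],
                "to_stage": row["to_stage"],
                "count": poisson(row["count"] * cov),
            }
        )
    detected_rows = []
    for year, det in trajectory.detected_incident.items():
        total = sum(det[s] for s in ("1-2", "3", "4"))
        detected_rows.append(
            {"year": year, "count": poisson(total * truth.detected_coverage)}
        )
    death_rows = []
    for _, row in trajectory.deaths.iterrows():
        death_rows.append(
            {
                "year": int(row["year"]),
                "stage": row["stage"],
                "count": poisson(row["count"]),
            }
        )
    return {
        "prevalent": pd.DataFrame(prevalent_rows),
        "transitions": pd.DataFrame(transition_rows),
        "detected_incident": pd.DataFrame(detected_rows),
        "deaths": pd.DataFrame(death_rows),
    }


@dataclass
class RecoveredParameters:
    """Estimates produced by the calibration pipeline from observations."""

    coverage: CoverageEstimate
    probabilities: ProbabilitySet
    rr: dict[str, float]
    background_mortality: float


def recover_parameters(
    national: pd.DataFrame,
    observations: dict[str, pd.DataFrame],
    coverage_years: tuple[int, int] = (2007, 2010),
    detected_coverage: float = 0.70,
) -> RecoveredParameters:
    """Full estimation pipeline: coverage, mortality, transition, detection.

    Coverage comes from registry-vs-national prevalent counts (stages 1-2
    and 3) and registry-vs-national stage-5 incidence, averaged over the
    two reference years, with stage 4 imputed as the stage-3/5 mean.  Stage
    mortality rates pool deaths over all observed cycles against national
    at-risk pools; transition probabilities pool coverage-corrected incident
    transitions against survival-adjusted source pools; detection
    probabilities are solved per year from the detected-incident total via
    the mortality-rate-ratio identity and averaged.
    """
    prevalent = observations["prevalent"].set_index(["year", "stage"])["count"]
    transitions = observations["transitions"].set_index(
        ["year", "from_stage", "to_stage"]
    )["count"]
    deaths = observations["deaths"].set_index(["year", "stage"])["count"]
    detected = observations["detected_incident"].set_index("year")["count"]
    nat = national.set_index("year")
    cycle_years = sorted(observations["deaths"]["year"].unique())

    # --- registry coverage -------------------------------------------------
    y1, y2 = coverage_years
    registry_prev = {
        y: {s: float(prevalent[y, s]) for s in ("1-2", "3")} for y in (y1, y2)
    }
    national_counts = {
        y: {
            "1-2": float(nat.loc[y, "stage12_count"]),
            "3": float(nat.loc[y, "stage3_count"]),
        }
        for y in (y1, y2)
    }
    registry_s5_incident = {
        y: float(
            transitions.loc[y].xs("5", level="to_stage").sum()
        )
        for y in (y1, y2)
    }
    national_s5_incidence = {y: float(nat.loc[y, "stage5_incidence"]) for y in (y1, y2)}
    coverage = estimate_coverage(
        registry_prev, national_counts, registry_s5_incident, national_s5_incidence
    )
    cov = coverage.average

    # --- national at-risk pools -------------------------------------------
    def stage_pool(year: int, stage: str) -> float:
        if stage in ("1-2", "3"):
            return float(nat.loc[year, f"stage{stage.replace('-', '')}_count"])
        return float(prevalent[year, stage]) / cov[stage]

    def non_pool(year: int) -> float:
        return float(nat.loc[year, "population"]) - sum(
            stage_pool(year, s) for s in STAGES
        )

    # --- mortality: pooled deaths over pooled exposure ---------------------
    stage_mr: dict[str, float] = {}
    for stage in STAGES:
        d = sum(float(deaths[y, stage]) for y in cycle_years)
        pool = sum(stage_pool(y, stage) for y in cycle_years)
        stage_mr[stage] = d / pool
    bg_deaths = sum(float(deaths[y, "non"]) for y in cycle_years)
    bg_pool = sum(non_pool(y) for y in cycle_years)
    background = bg_deaths / bg_pool
    annual_stage_rates = {
        y: {s: float(deaths[y, s]) / stage_pool(y, s) for s in STAGES}
        for y in cycle_years
    }
    annual_background = {
        y: float(deaths[y, "non"]) / non_pool(y) for y in cycle_years
    }
    try:
        rr = historical_relative_risks(
            annual_stage_rates,
            annual_background,
            window=(cycle_years[0], cycle_years[-1]),
        ).average
    except ValueError:
        # zero death counts in some year (small populations): fall back to
        # the pooled-exposure ratio, which is defined whenever any deaths
        # occurred over the window
        rr = {s: stage_mr[s] / background for s in STAGES}

    # --- transition probabilities: pooled exact-cohort estimator -----------
    source_mr = {"non": background, **stage_mr}

    def edge_probability(src: str, dst: str) -> float:
        num = 0.0
        den = 0.0
        for y in cycle_years:
            num += float(transitions[y, src, dst]) / cov[dst]
            pool = non_pool(y) if src == "non" else stage_pool(y, src)
            den += pool * (1.0 - source_mr[src])
        return num / den

    progression = {edge: edge_probability(*edge) for edge in EDGE_LABELS}

    # --- detection probabilities via the mortality-rate-ratio identity -----
    d_annual: list[dict[str, float]] = []
    for y in cycle_years:
        pools = {
            "1-2": float(transitions[y, "non", "1-2"]) / cov["1-2"],
            "3": (
                float(transitions[y, "non", "3"]) + float(transitions[y, "1-2", "3"])
            )
            / cov["3"],
            "4": float(transitions[y, "3", "4"]) / cov["4"],
        }
        total = float(detected[y]) / detected_coverage
        d_annual.append(
            derive_detection_probabilities(
                total, pools, {s: stage_mr[s] for s in ("1-2", "3", "4")}
            )
        )
    d_mean = {s: float(np.mean([d[s] for d in d_annual])) for s in ("1-2", "3", "4")}

    probabilities = ProbabilitySet(
        p_non_12=progression[("non", "1-2")],
        p_non_3=progression[("non", "3")],
        p_12_3=progression[("1-2", "3")],
        p_3_4=progression[("3", "4")],
        p_4_5=progression[("4", "5")],
        d_12=min(d_mean["1-2"], 1.0),
        d_3=min(d_mean["3"], 1.0),
        d_4=min(d_mean["4"], 1.0),
    )
    return RecoveredParameters(coverage, probabilities, rr, background)


def parameter_recovery_report(
    truth: GroundTruth,
    estimates: RecoveredParameters,
    tolerance: float = 0.05,
) -> pd.DataFrame:
    """Relative error of each recovered parameter against the ground truth."""
    rows = []

    def add(name: str, true_value: float, estimate: float) -> None:
        rel = abs(estimate - true_value) / abs(true_value)
        rows.append(
            {
                "parameter": name,
                "truth": true_value,
                "estimate": estimate,
                "relative_error": rel,
                "within_tolerance": rel <= tolerance,
            }
        )

    true_probs = truth.probabilities.as_dict()
    est_probs = estimates.probabilities.as_dict()
    for name in true_probs:
        add(name, true_probs[name], est_probs[name])
    for stage in ("1-2", "3", "4", "5"):
        add(f"coverage_{stage}", truth.coverage[stage], estimates.coverage.average[stage])
        add(f"rr_{stage}", truth.rr[stage], estimates.rr[stage])
    add("background_mortality", truth.background_mortality, estimates.background_mortality)
    return pd.DataFrame(rows)
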