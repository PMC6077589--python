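"""Base-year (2007) calibration from printed inputs and registry coverage.

Builds the starting state vector from survey prevalences, the albuminuria
persistence adjustment for stages 1-2, registry-coverage-derived national
counts for stages 4-5, and per-stage detected fractions obtained under the
assumption that the registry captures 70% of all *detected* CKD.

Coverage here means the fraction of the true national case count that the
disease registry captures; dividing registry counts by coverage inflates
them to national counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .states import STAGES, STAGE_STATES, HealthState, StateVector

__all__ = [
    "CoverageEstimate",
    "DetectionFractions",
    "BaseYearInputs",
    "adjust_stage12_prevalence",
    "estimate_coverage",
    "national_count_from_coverage",
    "derive_detection_fractions",
    "build_base_year",
]

logger = logging.getLogger(__name__)

DEFAULT_DETECTED_COVERAGE = 0.70


def _check_fraction(name: str, value: float, lo: float = 0.0, hi: float = 1.0) -> None:
    if not (lo <= value <= hi):
        raise ValueError(f"{name} = {value} outside [{lo}, {hi}]")


@dataclass
class CoverageEstimate:
    """Per-stage registry coverage for two reference years and their mean.

    The stage-4 coverage is never observed directly (no national stage-4
    incidence series exists); it is imputed as the mean of the stage-3 and
    stage-5 coverages within each year, on the assumption that coverage
    rises with disease severity.
    """

    by_year: dict[int, dict[str, float]]
    average: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        for year, cov in self.by_year.items():
            for stage, value in cov.items():
                if not (0.0 < value <= 1.0):
                    raise ValueError(
                        f"coverage[{year}][{stage}] = {value} outside (0, 1]"
                    )
        years = sorted(self.by_year)
        self.average = {
            stage: float(np.mean([self.by_year[y][stage] for y in years]))
            for stage in self.by_year[years[0]]
        }


@dataclass
class DetectionFractions:
    """Detected fraction of prevalent cases per CKD stage.

    Stage 5 is fixed at 1 (renal failure is nationally registered); the
    undiagnosed fraction is the exact complement per stage.
    """

    detected: dict[str, float]

    def __post_init__(self) -> None:
        self.detected = dict(self.detected)
        self.detected["5"] = 1.0
        for stage, value in self.detected.items():
            _check_fraction(f"detected[{stage}]", value)

    @property
    def undiagnosed(self) -> dict[str, float]:
        return {stage: 1.0 - d for stage, d in self.detected.items()}

    @classmethod
    def from_undiagnosed(cls, undiagnosed: dict[str, float]) -> "DetectionFractions":
        return cls({stage: 1.0 - u for stage, u in undiagnosed.items() if stage != "5"})


@dataclass
class BaseYearInputs:
    """Printed base-year inputs: prevalences, persistence, population, mortality.

    ``raw_prevalence`` holds the unadjusted survey prevalences per stage;
    ``undiagnosed`` the (adjusted) undiagnosed fractions for stages 1-2/3/4;
    ``crude_mortality`` is deaths per person-year in the whole population.
    """

    raw_prevalence: dict[str, float]
    persistence_fraction: float
    population: float
    crude_mortality: float
    undiagnosed: dict[str, float]

    def __post_init__(self) -> None:
        for stage, p in self.raw_prevalence.items():
            _check_fraction(f"raw_prevalence[{stage}]", p)
        _check_fraction("persistence_fraction", self.persistence_fraction)
        for stage, u in self.undiagnosed.items():
            _check_fraction(f"undiagnosed[{stage}]", u)
        _check_fraction("crude_mortality", self.crude_mortality)
        if self.population <= 0:
            raise ValueError("population must be positive")

    @property
    def detection_fractions(self) -> DetectionFractions:
        return DetectionFractions.from_undiagnosed(self.undiagnosed)


def adjust_stage12_prevalence(raw_prevalence: float, persistence_fraction: float) -> float:
    """Deflate single-measurement stages 1-2 prevalence by albuminuria persistence.

    Kidney damage requires a *persistent* (>= 3 months) albuminuria
    abnormality; a survey based on one urine measurement overestimates the
    stages 1-2 prevalence by the non-persistent fraction.
    """
    _check_fraction("raw_prevalence", raw_prevalence)
    _check_fraction("persistence_fraction", persistence_fraction)
    return raw_prevalence * persistence_fraction


def estimate_coverage(
    registry_prevalent: dict[int, dict[str, float]],
    national_counts: dict[int, dict[str, float]],
    registry_stage5_incident: dict[int, float],
    national_stage5_incidence: dict[int, float],
) -> CoverageEstimate:
    """Estimate per-stage registry coverage, averaged over two reference years.

    Stages 1-2 and 3: registry prevalent count over the national count.
    Stage 5: registry incident count over national renal-failure incidence.
    Stage 4: mean of the stage-3 and stage-5 coverages within each year.
    The final estimate averages the per-year values (typically the launch
    year and a year three years later, once registry capture stabilised).
    """
    by_year: dict[int, dict[str, float]] = {}
    for year in sorted(registry_prevalent):
        cov: dict[str, float] = {}
        for stage in ("1-2", "3"):
            national = national_counts[year][stage]
            if national <= 0:
                raise ValueError(f"national count for stage {stage}, {year} is not positive")
            cov[stage] = registry_prevalent[year][stage] / national
        incidence = national_stage5_incidence[year]
        if incidence <= 0:
            raise ValueError(f"national stage-5 incidence for {year} is not positive")
        cov["5"] = registry_stage5_incident[year] / incidence
        # sampling noise in small registries can push a ratio past 1
        for stage in list(cov):
            if cov[stage] > 1.0:
                logger.warning(
                    "coverage[%s][%s] clipped from %.4f to 1", year, stage, cov[stage]
                )
                cov[stage] = 1.0
        cov["4"] = 0.5 * (cov["3"] + cov["5"])
        by_year[year] = cov
    return CoverageEstimate(by_year)


def national_count_from_coverage(registry_count: float, coverage: float) -> float:
    """Inflate a registry count to the national count via the coverage fraction."""
    if not (0.0 < coverage <= 1.0):
        raise ValueError(f"coverage = {coverage} outside (0, 1]")
    if registry_count < 0:
        raise ValueError("registry count must be non-negative")
    return registry_count / coverage


def derive_detection_fractions(
    registry_detected: dict[str, float],
    national_counts: dict[str, float],
    detected_coverage: float = DEFAULT_DETECTED_COVERAGE,
) -> DetectionFractions:
    """Per-stage detected fractions under a fixed detected-CKD registry coverage.

    National detected count = registry detected / detected_coverage; the
    detected fraction is that count over the national (detected plus
    undetected) case count, clipped to [0, 1] with a warning — sampling
    noise in a registry extract can push the ratio past 1.
    """
    if not (0.0 < detected_coverage <= 1.0):
        raise ValueError(f"detected_coverage = {detected_coverage} outside (0, 1]")
    detected: dict[str, float] = {}
    for stage, registry_count in registry_detected.items():
        national = national_counts[stage]
        if national <= 0:
            raise ValueError(f"national count for stage {stage} is not positive")
        fraction = (registry_count / detected_coverage) / national
        if fraction > 1.0:
            logger.warning(
                "detected fraction for stage %s clipped from %.4f to 1", stage, fraction
            )
            fraction = 1.0
        detected[stage] = fraction
    return DetectionFractions(detected)


def build_base_year(
    inputs: BaseYearInputs,
    stage4_count: float = 24293.0,
    stage5_count: float = 8434.0,
    year: int = 2007,
    detection: DetectionFractions | None = None,
) -> StateVector:
    """Assemble the base-year state vector.

    Stages 1-2 use the persistence-adjusted prevalence times the population;
    stage 3 the raw prevalence; stages 4 and 5 the coverage-derived national
    counts (survey prevalence under-represents severe CKD).  Each of stages
    1-2/3/4 is split into detected and undetected compartments; stage 5 is
    wholly detected; the remainder of the population is non-CKD; cumulative
    deaths start at zero.
    """
    if stage4_count < 0 or stage5_count < 0:
        raise ValueError("stage counts must be non-negative")
    if detection is None:
        detection = inputs.detection_fractions
    pop = inputs.population
    adjusted12 = adjust_stage12_prevalence(
        inputs.raw_prevalence["1-2"], inputs.persistence_fraction
    )
    stage_totals = {
        "1-2": adjusted12 * pop,
        "3": inputs.raw_prevalence["3"] * pop,
        "4": float(stage4_count),
        "5": float(stage5_count),
    }
    total_ckd = sum(stage_totals.values())
    if total_ckd > pop:
        raise ValueError(f"total CKD {total_ckd} exceeds population {pop}")
    counts: dict[HealthState, float] = {HealthState.NON_CKD: pop - total_ckd}
    for stage in STAGES:
        undet_state, det_state = STAGE_STATES[stage]
        d = detection.detected[stage]
        counts[det_state] = stage_totals[stage] * d
        if undet_state is not None:
            counts[undet_state] = stage_totals[stage] * (1.0 - d)
    counts[HealthState.DEATH] = 0.0
    return StateVector.from_dict(year, counts)
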