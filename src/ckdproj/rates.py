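"""Transition/detection probability derivation, ageing index, matrix assembly.

Historical annual progression and detection probabilities are averaged over
a reference window (2010-2014 by default) into base probabilities, then
elevated for forecast years by an ageing index built from the elderly (65+)
population share.  The elevated probabilities, together with per-stage
mortality rates, are assembled into row-stochastic transition matrices.

Two structural rules from the model design:

* the stage 4 -> 5 progression probability is never elevated by the ageing
  index (competing risks of death dominate among the elderly at stage 4);
* detection at stage 5 is always 100%, because renal-failure incidence is
  registered nationally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .states import HealthState, TransitionMatrix, validate_transition_matrix

__all__ = [
    "AgeingIndexSeries",
    "ProbabilitySet",
    "PROGRESSION_EDGES",
    "compute_ageing_index",
    "derive_base_probabilities",
    "derive_detection_probabilities",
    "forecast_probabilities",
    "assemble_transition_matrix",
]

logger = logging.getLogger(__name__)

DEFAULT_BASE_WINDOW = (2010, 2014)

#: progression parameters, keyed by (source stage, destination stage);
#: "non" is the disease-free state.
PROGRESSION_EDGES = (("non", "1-2"), ("non", "3"), ("1-2", "3"), ("3", "4"), ("4", "5"))


@dataclass(frozen=True)
class ProbabilitySet:
    """One year's annual progression and detection probabilities.

    ``p_non_12``/``p_non_3`` are onset probabilities out of the disease-free
    state (onset with proteinuria lands in stages 1-2, onset without lands
    directly in stage 3); the remaining progressions are to the adjacent
    stage.  ``d_12``/``d_3``/``d_4`` are the detection probabilities applied
    to incident entrants of each stage; stage-5 detection is identically 1.
    """

    p_non_12: float
    p_non_3: float
    p_12_3: float
    p_3_4: float
    p_4_5: float
    d_12: float
    d_3: float
    d_4: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} = {value} outside [0, 1]")

    @property
    def d_5(self) -> float:
        return 1.0

    def as_dict(self) -> dict[str, float]:
        return {
            "p_non_12": self.p_non_12,
            "p_non_3": self.p_non_3,
            "p_12_3": self.p_12_3,
            "p_3_4": self.p_3_4,
            "p_4_5": self.p_4_5,
            "d_12": self.d_12,
            "d_3": self.d_3,
            "d_4": self.d_4,
        }

    def progression(self, edge: tuple[str, str]) -> float:
        return {
            ("non", "1-2"): self.p_non_12,
            ("non", "3"): self.p_non_3,
            ("1-2", "3"): self.p_12_3,
            ("3", "4"): self.p_3_4,
            ("4", "5"): self.p_4_5,
        }[edge]

    def detection(self, stage: str) -> float:
        return {"1-2": self.d_12, "3": self.d_3, "4": self.d_4, "5": 1.0}[stage]

    def elevated(self, multiplier: float) -> "ProbabilitySet":
        """Scale every stage 1-4 probability by the ageing multiplier.

        The 4->5 progression is left unchanged; everything clips at 1.
        """

        def scale(x: float) -> float:
            return min(x * multiplier, 1.0)

        return replace(
            self,
            p_non_12=scale(self.p_non_12),
            p_non_3=scale(self.p_non_3),
            p_12_3=scale(self.p_12_3),
            p_3_4=scale(self.p_3_4),
            d_12=scale(self.d_12),
            d_3=scale(self.d_3),
            d_4=scale(self.d_4),
        )

    def scaled(self, progression_factor: dict[tuple[str, str], float] | None = None,
               detection_factor: dict[str, float] | None = None) -> "ProbabilitySet":
        """Multiply selected probabilities by per-edge / per-stage factors (clipped)."""
        values = self.as_dict()
        key_of = {
            ("non", "1-2"): "p_non_12",
            ("non", "3"): "p_non_3",
            ("1-2", "3"): "p_12_3",
            ("3", "4"): "p_3_4",
            ("4", "5"): "p_4_5",
        }
        for edge, factor in (progression_factor or {}).items():
            values[key_of[edge]] = min(max(values[key_of[edge]] * factor, 0.0), 1.0)
        for stage, factor in (detection_factor or {}).items():
            key = {"1-2": "d_12", "3": "d_3", "4": "d_4"}[stage]
            values[key] = min(max(values[key] * factor, 0.0), 1.0)
        return ProbabilitySet(**values)


@dataclass
class AgeingIndexSeries:
    """Elderly share, reference rate, ageing index and multiplier per year."""

    elderly: dict[int, float]
    reference: float
    index: dict[int, float]
    multiplier: dict[int, float]


def compute_ageing_index(
    elderly_series: dict[int, float],
    reference_window: tuple[int, int] = DEFAULT_BASE_WINDOW,
    form: str = "relative",
) -> AgeingIndexSeries:
    """Ageing index per year from the elderly (65+) population share.

    The index is the product of the year's elderly share and its increase
    from the reference rate (the window-average share).  The default
    ``relative`` form measures the increase relative to the reference,
    AI_t = e_t * (e_t - e_ref) / e_ref, which is dimensionless; the
    ``absolute`` alternative uses AI_t = e_t * (e_t - e_ref).  The
    probability multiplier is 1 + AI_t, floored at 0.
    """
    if form not in ("relative", "absolute"):
        raise ValueError(f"unknown ageing-index form {form!r}")
    for year, e in elderly_series.items():
        if not (0.0 < e < 1.0):
            raise ValueError(f"elderly share {e} for {year} outside (0, 1)")
    lo, hi = reference_window
    window_years = [y for y in range(lo, hi + 1) if y in elderly_series]
    if not window_years:
        raise ValueError("reference window not covered by the elderly series")
    reference = float(np.mean([elderly_series[y] for y in window_years]))
    if reference <= 0:
        raise ValueError("reference elderly share must be positive")
    index: dict[int, float] = {}
    multiplier: dict[int, float] = {}
    for year, e in elderly_series.items():
        increase = (e - reference) / reference if form == "relative" else (e - reference)
        index[year] = e * increase
        multiplier[year] = max(1.0 + index[year], 0.0)
    return AgeingIndexSeries(dict(elderly_series), reference, index, multiplier)


def derive_base_probabilities(
    annual: dict[int, ProbabilitySet],
    window: tuple[int, int] = DEFAULT_BASE_WINDOW,
) -> ProbabilitySet:
    """Arithmetic mean of each probability over the reference window."""
    lo, hi = window
    years = list(range(lo, hi + 1))
    missing = [y for y in years if y not in annual]
    if missing:
        raise ValueError(f"window years missing from annual probabilities: {missing}")
    fields = annual[years[0]].as_dict().keys()
    means = {
        name: float(np.mean([annual[y].as_dict()[name] for y in years]))
        for name in fields
    }
    return ProbabilitySet(**means)


def derive_detection_probabilities(
    detected_incident_total: float,
    incident_pools: dict[str, float],
    stage_mortality_rates: dict[str, float],
) -> dict[str, float]:
    """Solve per-stage detection probabilities from one detected-incident total.

    The system is closed by the identity that the ratio of detection
    probabilities between a higher and a lower stage equals their mortality
    rate ratio (sicker patients use more healthcare, hence are found at the
    same relative rate they die at).  With r_i = MR_i / MR_{1-2}:

        detected_total = sum_i d_i * pool_i,   d_i = d_{1-2} * r_i

    leaves the single unknown d_{1-2}.  Solutions outside [0, 1] are clipped
    with a warning.
    """
    stages = tuple(incident_pools)
    if "1-2" not in stages:
        raise ValueError("incident pools must include the reference stage 1-2")
    for stage in stages:
        if incident_pools[stage] <= 0:
            raise ValueError(f"incident pool for stage {stage} must be positive")
        if stage_mortality_rates[stage] <= 0:
            raise ValueError(f"mortality rate for stage {stage} must be positive")
    if detected_incident_total < 0:
        raise ValueError("detected incident total must be non-negative")
    mr12 = stage_mortality_rates["1-2"]
    ratios = {stage: stage_mortality_rates[stage] / mr12 for stage in stages}
    weighted_pool = sum(ratios[s] * incident_pools[s] for s in stages)
    d12 = detected_incident_total / weighted_pool
    solution = {stage: d12 * ratios[stage] for stage in stages}
    clipped = {s: v for s, v in solution.items() if v > 1.0}
    if clipped:
        logger.warning("detection probabilities clipped to 1: %s", clipped)
        solution = {s: min(v, 1.0) for s, v in solution.items()}
    return solution


def forecast_probabilities(
    base: ProbabilitySet,
    ageing: AgeingIndexSeries,
    horizon: tuple[int, int],
) -> dict[int, ProbabilitySet]:
    """Elevate base probabilities by the per-year ageing multiplier.

    Stage 1-4 progression and detection probabilities scale with m_t; the
    4->5 progression stays at its base value; stage-5 detection stays 1.
    Warns if more than 10% of scaled cells hit the [0, 1] clip.
    """
    lo, hi = horizon
    missing = [y for y in range(lo, hi + 1) if y not in ageing.multiplier]
    if missing:
        raise ValueError(f"ageing series missing horizon years: {missing}")
    forecast: dict[int, ProbabilitySet] = {}
    n_cells = 0
    n_clipped = 0
    scaled_fields = ("p_non_12", "p_non_3", "p_12_3", "p_3_4", "d_12", "d_3", "d_4")
    for year in range(lo, hi + 1):
        m = ageing.multiplier[year]
        for name in scaled_fields:
            n_cells += 1
            if base.as_dict()[name] * m > 1.0:
                n_clipped += 1
        forecast[year] = base.elevated(m)
    if n_cells and n_clipped / n_cells > 0.10:
        logger.warning(
            "ageing elevation clipped %d of %d probability cells", n_clipped, n_cells
        )
    return forecast


def assemble_transition_matrix(
    probabilities: ProbabilitySet,
    stage_mortality_rates: dict[str, float],
    background_rate: float,
    year: int,
    within_stage_detection: bool = False,
) -> TransitionMatrix:
    """Build the year's row-stochastic transition matrix.

    For each alive source state the progression flow to the next stage is
    split between the destination's detected and undetected compartments by
    the destination detection probability (stage 5 is wholly detected).
    Death competes simultaneously with progression within the cycle: each
    row's death entry equals the source's stage mortality and the remaining
    flows are scaled by one minus it, preserving row-stochasticity.

    With ``within_stage_detection`` enabled, undetected non-progressors are
    additionally detected at their stage's detection probability; disabled
    by default, which reproduces the strictly progression-linked screening
    narrative of the model.
    """
    H = HealthState
    n = len(H)
    P = np.zeros((n, n))

    def mr(stage: str | None) -> float:
        if stage is None:
            return background_rate
        return stage_mortality_rates[stage]

    def fill_row(
        source: HealthState,
        stage: str | None,
        flows: dict[HealthState, float],
    ) -> None:
        total_flow = sum(flows.values())
        self_loop = 1.0 - total_flow
        if self_loop < -1e-12:
            raise ValueError(
                f"over-specified flows for {source.name}: total {total_flow:.6g} > 1"
            )
        self_loop = max(self_loop, 0.0)
        death = mr(stage)
        if not (0.0 <= death <= 1.0):
            raise ValueError(f"mortality for {source.name} outside [0, 1]")
        survive = 1.0 - death
        for dest, p in flows.items():
            P[source.index, dest.index] = p * survive
        P[source.index, source.index] = self_loop * survive
        P[source.index, H.DEATH.index] = death

    p = probabilities
    # disease-free: onset with proteinuria -> stages 1-2, without -> stage 3
    fill_row(
        H.NON_CKD,
        None,
        {
            H.S12_DETECTED: p.p_non_12 * p.d_12,
            H.S12_UNDETECTED: p.p_non_12 * (1.0 - p.d_12),
            H.S3_DETECTED: p.p_non_3 * p.d_3,
            H.S3_UNDETECTED: p.p_non_3 * (1.0 - p.d_3),
        },
    )
    w12 = p.d_12 if within_stage_detection else 0.0
    fill_row(
        H.S12_UNDETECTED,
        "1-2",
        {
            H.S3_DETECTED: p.p_12_3 * p.d_3,
            H.S3_UNDETECTED: p.p_12_3 * (1.0 - p.d_3),
            H.S12_DETECTED: (1.0 - p.p_12_3) * w12,
        },
    )
    fill_row(
        H.S12_DETECTED,
        "1-2",
        {
            H.S3_DETECTED: p.p_12_3 * p.d_3,
            H.S3_UNDETECTED: p.p_12_3 * (1.0 - p.d_3),
        },
    )
    w3 = p.d_3 if within_stage_detection else 0.0
    fill_row(
        H.S3_UNDETECTED,
        "3",
        {
            H.S4_DETECTED: p.p_3_4 * p.d_4,
            H.S4_UNDETECTED: p.p_3_4 * (1.0 - p.d_4),
            H.S3_DETECTED: (1.0 - p.p_3_4) * w3,
        },
    )
    fill_row(
        H.S3_DETECTED,
        "3",
        {
            H.S4_DETECTED: p.p_3_4 * p.d_4,
            H.S4_UNDETECTED: p.p_3_4 * (1.0 - p.d_4),
        },
    )
    w4 = p.d_4 if within_stage_detection else 0.0
    fill_row(
        H.S4_UNDETECTED,
        "4",
        {
            H.S5: p.p_4_5,  # stage-5 detection is 100%
            H.S4_DETECTED: (1.0 - p.p_4_5) * w4,
        },
    )
    fill_row(H.S4_DETECTED, "4", {H.S5: p.p_4_5})
    fill_row(H.S5, "5", {})
    P[H.DEATH.index, H.DEATH.index] = 1.0

    matrix = TransitionMatrix(year, P)
    report = validate_transition_matrix(matrix)
    if not report.ok:
        raise ValueError(f"assembled matrix invalid: {report}")
    return matrix
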