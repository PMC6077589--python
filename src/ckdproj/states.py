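"""Nine-state Markov state space for chronic kidney disease progression.

The model partitions the adult population into mutually exclusive health
states: no CKD, stages 1-2 / 3 / 4 each split into undetected and detected
compartments, stage 5 (end-stage renal disease, always detected because
renal-failure incidence is captured by a national registry), and death.
Progression is one-way — no regression to an earlier stage — and death is
absorbing.  Cohort counts are continuous (expected-value simulation), moved
once per one-year cycle by a row-stochastic transition matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "HealthState",
    "StateVector",
    "TransitionMatrix",
    "ValidationReport",
    "STAGES",
    "STAGE_STATES",
    "legal_edges",
    "validate_transition_matrix",
    "step_cohort",
]

ROW_SUM_TOL = 1e-9


class HealthState(Enum):
    """The nine mutually exclusive health states."""

    NON_CKD = 0
    S12_UNDETECTED = 1
    S12_DETECTED = 2
    S3_UNDETECTED = 3
    S3_DETECTED = 4
    S4_UNDETECTED = 5
    S4_DETECTED = 6
    S5 = 7
    DEATH = 8

    @property
    def index(self) -> int:
        return self.value


N_STATES = len(HealthState)

#: CKD stage labels used throughout the package.
STAGES = ("1-2", "3", "4", "5")

#: stage label -> (undetected state, detected state).  Stage 5 has no
#: undetected compartment: detection is 100% at end-stage renal disease.
STAGE_STATES: dict[str, tuple[HealthState | None, HealthState]] = {
    "1-2": (HealthState.S12_UNDETECTED, HealthState.S12_DETECTED),
    "3": (HealthState.S3_UNDETECTED, HealthState.S3_DETECTED),
    "4": (HealthState.S4_UNDETECTED, HealthState.S4_DETECTED),
    "5": (None, HealthState.S5),
}

ALIVE_STATES = tuple(s for s in HealthState if s is not HealthState.DEATH)


def _edge_set() -> frozenset[tuple[HealthState, HealthState]]:
    H = HealthState
    edges: set[tuple[HealthState, HealthState]] = set()
    # self-loops on every non-death state; death is absorbing
    for s in ALIVE_STATES:
        edges.add((s, s))
        edges.add((s, H.DEATH))
    edges.add((H.DEATH, H.DEATH))
    # onset: stages 1-2 (with proteinuria) or directly stage 3 (without)
    edges |= {
        (H.NON_CKD, H.S12_UNDETECTED),
        (H.NON_CKD, H.S12_DETECTED),
        (H.NON_CKD, H.S3_UNDETECTED),
        (H.NON_CKD, H.S3_DETECTED),
    }
    # one-way progression to the adjacent stage, destination split by
    # screening; plus within-stage detection for the undetected compartments
    edges |= {
        (H.S12_UNDETECTED, H.S12_DETECTED),
        (H.S12_UNDETECTED, H.S3_UNDETECTED),
        (H.S12_UNDETECTED, H.S3_DETECTED),
        (H.S12_DETECTED, H.S3_UNDETECTED),
        (H.S12_DETECTED, H.S3_DETECTED),
        (H.S3_UNDETECTED, H.S3_DETECTED),
        (H.S3_UNDETECTED, H.S4_UNDETECTED),
        (H.S3_UNDETECTED, H.S4_DETECTED),
        (H.S3_DETECTED, H.S4_UNDETECTED),
        (H.S3_DETECTED, H.S4_DETECTED),
        (H.S4_UNDETECTED, H.S4_DETECTED),
        (H.S4_UNDETECTED, H.S5),
        (H.S4_DETECTED, H.S5),
    }
    return frozenset(edges)


_LEGAL_EDGES = _edge_set()

_LEGAL_MASK = np.zeros((N_STATES, N_STATES), dtype=bool)
for _i, _j in _LEGAL_EDGES:
    _LEGAL_MASK[_i.index, _j.index] = True


def legal_edges() -> frozenset[tuple[HealthState, HealthState]]:
    """The fixed set of ordered state pairs a transition may use.

    Encodes one-way staging (no regression), the direct non-CKD -> stage 3
    onset route, within-stage detection for undetected compartments, the
    absorbing death state, and self-loops for everyone alive.
    """
    return _LEGAL_EDGES


@dataclass
class StateVector:
    """Occupancy counts per health state at a given calendar year.

    Counts are continuous expected values.  The DEATH entry accumulates all
    deaths since the base year.
    """

    year: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (N_STATES,):
            raise ValueError(f"counts must have shape ({N_STATES},)")
        if not np.all(np.isfinite(self.counts)) or np.any(self.counts < 0):
            raise ValueError("counts must be finite and non-negative")

    def __getitem__(self, state: HealthState) -> float:
        return float(self.counts[state.index])

    @property
    def alive_total(self) -> float:
        return float(self.counts.sum() - self.counts[HealthState.DEATH.index])

    def stage_total(self, stage: str) -> float:
        undet, det = STAGE_STATES[stage]
        total = self[det]
        if undet is not None:
            total += self[undet]
        return total

    def stage_undetected(self, stage: str) -> float:
        undet, _ = STAGE_STATES[stage]
        return 0.0 if undet is None else self[undet]

    @property
    def total_ckd(self) -> float:
        return sum(self.stage_total(s) for s in STAGES)

    @property
    def non_ckd(self) -> float:
        return self[HealthState.NON_CKD]

    def copy(self) -> "StateVector":
        return StateVector(self.year, self.counts.copy())

    @classmethod
    def from_dict(cls, year: int, counts: dict[HealthState, float]) -> "StateVector":
        arr = np.zeros(N_STATES)
        for state, value in counts.items():
            arr[state.index] = value
        return cls(year, arr)


@dataclass
class TransitionMatrix:
    """Row-stochastic one-year transition probabilities for a given year."""

    year: int
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (N_STATES, N_STATES):
            raise ValueError(f"probs must have shape ({N_STATES}, {N_STATES})")

    def __getitem__(self, edge: tuple[HealthState, HealthState]) -> float:
        i, j = edge
        return float(self.probs[i.index, j.index])


@dataclass
class ValidationReport:
    """Diagnostic list of transition-matrix invariant violations."""

    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        return "valid" if self.ok else "; ".join(self.violations)


def validate_transition_matrix(matrix: TransitionMatrix) -> ValidationReport:
    """Check row sums, entry bounds and the legal-edge structure.

    Purely diagnostic: returns the full list of violations, never raises.
    """
    report = ValidationReport()
    P = matrix.probs
    row_sums = P.sum(axis=1)
    for state in HealthState:
        dev = abs(row_sums[state.index] - 1.0)
        if not np.isfinite(dev) or dev > ROW_SUM_TOL:
            report.violations.append(
                f"row {state.name} sums to {row_sums[state.index]:.12g}"
            )
    neg = np.argwhere((P < 0) | (P > 1) | ~np.isfinite(P))
    for i, j in neg:
        report.violations.append(
            f"entry {HealthState(i).name}->{HealthState(j).name} = {P[i, j]:.12g} "
            "outside [0, 1]"
        )
    illegal = np.argwhere((P != 0) & ~_LEGAL_MASK)
    for i, j in illegal:
        report.violations.append(
            f"illegal edge {HealthState(i).name}->{HealthState(j).name} = {P[i, j]:.12g}"
        )
    return report


def step_cohort(
    state: StateVector,
    matrix: TransitionMatrix,
    entrants: np.ndarray | None = None,
) -> StateVector:
    """Advance the cohort one annual cycle.

    New occupancy is the matrix-propagated flow plus entrants (net migrants
    and live births), which are added after the transition flows.  Raises
    ``ValueError`` with the validation report if the matrix is invalid, or on
    a year mismatch between state and matrix.
    """
    report = validate_transition_matrix(matrix)
    if not report.ok:
        raise ValueError(f"invalid transition matrix for {matrix.year}: {report}")
    if state.year != matrix.year:
        raise ValueError(
            f"year mismatch: state is {state.year}, matrix is {matrix.year}"
        )
    if entrants is None:
        entrants = np.zeros(N_STATES)
    entrants = np.asarray(entrants, dtype=float)
    if entrants.shape != (N_STATES,):
        raise ValueError(f"entrants must have shape ({N_STATES},)")
    if np.any(entrants < 0) or entrants[HealthState.DEATH.index] != 0:
        raise ValueError("entrants must be non-negative and alive")
    new_counts = state.counts @ matrix.probs + entrants
    return StateVector(state.year + 1, new_counts)


def entrants_vector(total: float, distribution: np.ndarray | None = None) -> np.ndarray:
    """Entrant counts per state; by default all entrants are non-CKD."""
    vec = np.zeros(N_STATES)
    if distribution is None:
        vec[HealthState.NON_CKD.index] = total
        return vec
    distribution = np.asarray(distribution, dtype=float)
    if distribution.shape != (N_STATES,) or abs(distribution.sum() - 1.0) > 1e-9:
        raise ValueError("distribution must be a length-9 simplex vector")
    if distribution[HealthState.DEATH.index] != 0:
        raise ValueError("entrants cannot enter the death state")
    return total * distribution
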