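"""Independent oracles shared across the test suite.

``brute_force_step`` re-implements the annual cohort update as an explicit
loop over all 81 ordered state pairs, never touching the vectorised path it
checks.  ``random_valid_matrix`` draws a row-stochastic matrix supported on
the legal edge set.
"""

from __future__ import annotations

import numpy as np

from ckdproj.states import HealthState, TransitionMatrix, legal_edges

N = len(HealthState)


def brute_force_step(counts: np.ndarray, matrix: TransitionMatrix) -> np.ndarray:
    """Accumulate every pairwise flow explicitly: the matrix-free oracle."""
    out = np.zeros(N)
    for i in HealthState:
        for j in HealthState:
            out[j.index] += counts[i.index] * matrix.probs[i.index, j.index]
    return out


def random_valid_matrix(rng: np.random.Generator, year: int) -> TransitionMatrix:
    """Row-stochastic matrix with random mass on the legal edges only."""
    P = np.zeros((N, N))
    edges = legal_edges()
    for i in HealthState:
        dests = [j for j in HealthState if (i, j) in edges]
        weights = rng.random(len(dests))
        weights /= weights.sum()
        for j, w in zip(dests, weights):
            P[i.index, j.index] = w
    return TransitionMatrix(year, P)


def random_state(rng: np.random.Generator, year: int, scale: float = 1000.0):
    from ckdproj.states import StateVector

    counts = rng.random(N) * scale
    return StateVector(year, counts)
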