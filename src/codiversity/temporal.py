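"""Kitagawa decomposition of the change in overall diversity over time.

Overall diversity at time t is S_t = f(pi_t, M_t) = pi_t' M_t pi_t, a
function of the group weights and the diversity matrix. The change
between two periods splits symmetrically into a composition effect (the
weights changing, diversity levels held fixed) and a diversity effect
(the matrix changing, weights held fixed), each averaged over the two
counterfactual orderings:

    delta_pi = [ (f(pi2, M2) - f(pi1, M2)) + (f(pi2, M1) - f(pi1, M1)) ] / 2
    delta_S  = [ (f(pi2, M2) - f(pi2, M1)) + (f(pi1, M2) - f(pi1, M1)) ] / 2

and delta_pi + delta_S = S_2 - S_1 exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import GroupedMortality, ValidationError
from .diversity import (
    DiversityMatrix,
    InternalConsistencyError,
    IDENTITY_RTOL,
    diversity_matrix,
    quadratic_form,
)

__all__ = ["DiversityState", "TemporalChange", "evaluate_state", "kitagawa", "state_of"]


@dataclass(frozen=True)
class DiversityState:
    """Group weights and diversity matrix of one period."""

    weights: np.ndarray
    matrix: DiversityMatrix

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if w.shape != (self.matrix.G,):
            raise ValidationError("weights length does not match the matrix")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError("weights must be non-negative and sum to 1")


@dataclass(frozen=True)
class TemporalChange:
    """delta = S_2 - S_1 split into composition and diversity effects."""

    delta: float
    delta_pi: float
    delta_S: float

    def __post_init__(self):
        resid = abs(self.delta - (self.delta_pi + self.delta_S))
        if resid > IDENTITY_RTOL * max(1.0, abs(self.delta)):
            raise InternalConsistencyError(
                f"delta != delta_pi + delta_S (residual {resid:.3e})"
            )


def state_of(gm: GroupedMortality) -> DiversityState:
    """The (weights, diversity matrix) state of a grouped-mortality period."""
    return DiversityState(gm.weights, diversity_matrix(gm))


def evaluate_state(state: DiversityState) -> float:
    """Overall diversity f(pi, M) = pi' M pi of one period."""
    return quadratic_form(state.weights, state.matrix)


def kitagawa(state1: DiversityState, state2: DiversityState) -> TemporalChange:
    """Symmetric two-factor decomposition of S_2 - S_1.

    The two states must describe the same groups in the same order;
    unbalanced panels are rejected rather than zero-padded, because
    padding would silently renormalize the weights.
    """
    if state1.matrix.group_labels != state2.matrix.group_labels:
        raise ValidationError("states describe different group sets or orderings")

    def f(w: np.ndarray, M: DiversityMatrix) -> float:
        return float(w @ M.values @ w)

    w1, w2 = state1.weights, state2.weights
    M1, M2 = state1.matrix, state2.matrix
    f11, f12 = f(w1, M1), f(w1, M2)
    f21, f22 = f(w2, M1), f(w2, M2)
    delta_pi = ((f22 - f12) + (f21 - f11)) / 2.0
    delta_S = ((f22 - f21) + (f12 - f11)) / 2.0
    return TemporalChange(delta=f22 - f11, delta_pi=delta_pi, delta_S=delta_S)
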