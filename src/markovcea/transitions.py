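"""Annual BCVA-change outcome distributions and transition matrices.

Treatment effect after one cycle is expressed as the probability of a
letter-change category: {+15, 0, -15} for AMD and DME, {+30, +15, 0, -15,
-30} for PM.  A +/-15-letter change maps to a one-band shift on the state
ladder and +/-30 letters to a two-band shift, uniformly across bands.
Shifts that would leave the ladder fold into the nearest feasible state
(improvement from the best state and worsening from blindness become
"stay"), which conserves probability mass.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ParameterError
from .state_space import StateSpace

logger = logging.getLogger(__name__)

#: Letter-change categories allowed per shipped disease.
ALLOWED_CATEGORIES = {
    "AMD": frozenset({15, 0, -15}),
    "DME": frozenset({15, 0, -15}),
    "PM": frozenset({30, 15, 0, -15, -30}),
}
_ALL_CATEGORIES = frozenset({30, 15, 0, -15, -30})

#: Letters per band shift on the state ladder.
LETTERS_PER_BAND = 15


@dataclass(frozen=True)
class OutcomeDistribution:
    """Probabilities of annual BCVA letter-change categories for one arm."""

    drug: str
    disease: str
    probs: Mapping[int, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", dict(self.probs))
        bad = set(self.probs) - _ALL_CATEGORIES
        if bad:
            raise ParameterError(f"{self.drug}/{self.disease}: unknown letter-change categories {sorted(bad)}")
        allowed = ALLOWED_CATEGORIES.get(self.disease)
        if allowed is not None and not set(self.probs) <= allowed:
            raise ParameterError(
                f"{self.drug}/{self.disease}: categories {sorted(self.probs)} not allowed for "
                f"{self.disease} (allowed: {sorted(allowed)})"
            )
        for cat, p in self.probs.items():
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"{self.drug}/{self.disease}: P[{cat:+d}] = {p} outside [0, 1]")

    @property
    def total(self) -> float:
        return float(sum(self.probs.values()))


def normalize_outcomes(raw: OutcomeDistribution) -> OutcomeDistribution:
    """Renormalize an outcome distribution to sum to exactly 1.

    Raw sums outside [0.99, 1.01] signal a typo-level inconsistency and
    raise; deviations above 1e-6 (table rounding, e.g. a printed column
    summing to 0.9998) are renormalized with a logged warning.
    """
    total = raw.total
    if not 0.99 <= total <= 1.01:
        raise ParameterError(
            f"{raw.drug}/{raw.disease}: outcome probabilities sum to {total:.6f}, outside [0.99, 1.01]"
        )
    if abs(total - 1.0) <= 1e-12:
        return raw
    if abs(total - 1.0) > 1e-6:
        logger.warning("%s/%s: outcome probabilities sum to %.6f; renormalizing", raw.drug, raw.disease, total)
    return replace(raw, probs={c: p / total for c, p in raw.probs.items()})


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic annual state-to-state transition probabilities.

    Rows are origin states, columns destinations, both ordered best vision
    first.
    """

    disease: str
    matrix: np.ndarray
    state_names: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ParameterError(f"transition matrix must be square, got shape {m.shape}")
        if len(self.state_names) != m.shape[0]:
            raise ParameterError("state_names length does not match matrix size")
        if (m < -1e-15).any() or (m > 1 + 1e-12).any():
            raise ParameterError("transition probabilities must lie in [0, 1]")
        rows = m.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12, rtol=0):
            raise ParameterError(f"rows must sum to 1, got sums {rows}")

    @property
    def n_states(self) -> int:
        return self.matrix.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame, origin states as index, destinations as columns."""
        return pd.DataFrame(self.matrix, index=list(self.state_names), columns=list(self.state_names))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="from_state")


def build_transition_matrix(
    outcomes: OutcomeDistribution,
    space: StateSpace,
    blindness_absorbing: bool = False,
) -> TransitionMatrix:
    """Map letter-change outcome probabilities onto the state ladder.

    +15 letters moves one band toward better vision (lower index), -15 one
    band toward worse, +/-30 letters (PM) two bands; 0 stays.  Destinations
    outside the ladder are clipped to the nearest end state, so the best
    state's improvement mass and the worst state's worsening mass fold into
    "stay" and each row still sums to the full outcome mass.

    Parameters
    ----------
    blindness_absorbing : bool
        When True, the worst state keeps all its mass (no recovery from
        blindness).  Default False: improvement probabilities apply from
        every state alike.
    """
    if outcomes.disease != space.disease:
        raise ParameterError(
            f"outcome distribution is for {outcomes.disease!r} but state space is for {space.disease!r}"
        )
    outcomes = normalize_outcomes(outcomes)
    k = space.n_states
    m = np.zeros((k, k))
    for i in range(k):
        if blindness_absorbing and i == k - 1:
            m[i, i] = 1.0
            continue
        for delta_letters, p in outcomes.probs.items():
            shift = -delta_letters // LETTERS_PER_BAND  # +letters => toward index 0
            j = min(max(i + shift, 0), k - 1)
            m[i, j] += p
    return TransitionMatrix(space.disease, m, space.names)
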