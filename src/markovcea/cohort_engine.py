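"""Cohort propagation: discounted QALY and cost accumulation per arm.

The baseline occupancy vector is pushed through the annual transition
matrix for each cycle.  Cycle QALYs use start-of-cycle occupancy (no
half-cycle correction by default) and annual drug cost is unit price times
injections per year plus any other annual cost.  Discounting follows the
annuity-due convention: the first cycle is undiscounted, cycle t
contributes value / (1 + r)^t.  Both conventions are switchable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, ParameterError
from .state_space import StateSpace
from .transitions import TransitionMatrix


@dataclass(frozen=True)
class ArmParameters:
    """Economic parameters of one treatment arm."""

    drug: str
    unit_price: float
    injections_per_year: float
    other_annual_cost: float = 0.0
    discount_rate: float = 0.035
    horizon: int = 10

    def __post_init__(self) -> None:
        if self.unit_price < 0:
            raise DomainError(f"unit_price must be >= 0, got {self.unit_price}")
        if self.injections_per_year < 0:
            raise DomainError(f"injections_per_year must be >= 0, got {self.injections_per_year}")
        if self.other_annual_cost < 0:
            raise DomainError(f"other_annual_cost must be >= 0, got {self.other_annual_cost}")
        if not 0.0 <= self.discount_rate < 1.0:
            raise DomainError(f"discount_rate must be in [0, 1), got {self.discount_rate}")
        if int(self.horizon) != self.horizon or self.horizon < 1:
            raise DomainError(f"horizon must be an integer >= 1, got {self.horizon}")

    @property
    def annual_cost(self) -> float:
        return self.unit_price * self.injections_per_year + self.other_annual_cost


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle record of one simulation.

    ``occupancy`` has ``horizon + 1`` rows (cycle starts 0..horizon);
    ``per_cycle_qaly`` and ``per_cycle_cost`` have ``horizon`` entries,
    undiscounted.
    """

    occupancy: np.ndarray
    per_cycle_qaly: np.ndarray
    per_cycle_cost: np.ndarray
    state_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        object.__setattr__(self, "occupancy", occ)
        object.__setattr__(self, "per_cycle_qaly", np.asarray(self.per_cycle_qaly, dtype=float))
        object.__setattr__(self, "per_cycle_cost", np.asarray(self.per_cycle_cost, dtype=float))
        if not np.allclose(occ.sum(axis=1), 1.0, atol=1e-10, rtol=0):
            raise ParameterError("every occupancy vector must sum to 1")
        if (self.per_cycle_cost < 0).any():
            raise ParameterError("per-cycle costs must be >= 0")

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self, rate: float = 0.0, first_cycle_discounted: bool = False) -> pd.DataFrame:
        """Trace as a tidy table: shares, cycle QALY/cost, discounted cumulatives."""
        t = self.horizon
        names = self.state_names or tuple(f"state_{i}" for i in range(self.occupancy.shape[1]))
        df = pd.DataFrame(self.occupancy[:t], columns=list(names))
        df.insert(0, "cycle", np.arange(t))
        df["cycle_qaly"] = self.per_cycle_qaly
        df["cycle_cost"] = self.per_cycle_cost
        w = discount_weights(t, rate, first_cycle_discounted)
        df["cum_discounted_qaly"] = np.cumsum(self.per_cycle_qaly * w)
        df["cum_discounted_cost"] = np.cumsum(self.per_cycle_cost * w)
        return df


@dataclass(frozen=True)
class ArmResult:
    """Discounted totals plus the full trace for one arm."""

    drug: str
    total_cost: float
    total_qaly: float
    trace: CohortTrace


def discount_weights(horizon: int, rate: float, first_cycle_discounted: bool = False) -> np.ndarray:
    """Per-cycle discount factors for cycles 0..horizon-1."""
    if rate < 0:
        raise DomainError(f"discount rate must be >= 0, got {rate}")
    t = np.arange(horizon, dtype=float)
    if first_cycle_discounted:
        t = t + 1.0
    return (1.0 + rate) ** -t


def discounted_sum(per_cycle, rate: float, first_cycle_discounted: bool = False) -> float:
    """Sum of per-cycle values discounted at ``rate``.

    By default cycle 0 is undiscounted (annuity-due):
    ``sum_t value_t / (1 + rate)^t``.
    """
    values = np.asarray(per_cycle, dtype=float)
    return float(values @ discount_weights(len(values), rate, first_cycle_discounted))


def annuity_factor(rate: float, horizon: int, first_cycle_discounted: bool = False) -> float:
    """Discounted sum of a unit annual value over ``horizon`` cycles."""
    return discounted_sum(np.ones(horizon), rate, first_cycle_discounted)


def simulate_cohort(
    space: StateSpace,
    matrix: TransitionMatrix,
    horizon: int = 10,
    annual_cost: float = 0.0,
    half_cycle_correction: bool = False,
) -> CohortTrace:
    """Propagate the baseline cohort through ``horizon`` annual cycles.

    Cycle QALY is occupancy-weighted utility at cycle start, or the average
    of start and end occupancy when ``half_cycle_correction`` is on.
    """
    if int(horizon) != horizon or horizon < 1:
        raise DomainError(f"horizon must be an integer >= 1, got {horizon}")
    if matrix.n_states != space.n_states:
        raise ParameterError(
            f"matrix has {matrix.n_states} states but state space has {space.n_states}"
        )
    horizon = int(horizon)
    occ = np.empty((horizon + 1, space.n_states))
    occ[0] = space.baseline
    for t in range(horizon):
        occ[t + 1] = occ[t] @ matrix.matrix
    u = space.utilities
    if half_cycle_correction:
        qaly = 0.5 * (occ[:-1] + occ[1:]) @ u
    else:
        qaly = occ[:-1] @ u
    cost = np.full(horizon, float(annual_cost))
    return CohortTrace(occ, qaly, cost, state_names=space.names)


def run_arm(
    space: StateSpace,
    matrix: TransitionMatrix,
    arm: ArmParameters,
    half_cycle_correction: bool = False,
    first_cycle_discounted: bool = False,
) -> ArmResult:
    """Simulate one arm and accumulate discounted cost and QALY totals."""
    trace = simulate_cohort(
        space, matrix, arm.horizon, annual_cost=arm.annual_cost, half_cycle_correction=half_cycle_correction
    )
    total_cost = discounted_sum(trace.per_cycle_cost, arm.discount_rate, first_cycle_discounted)
    total_qaly = discounted_sum(trace.per_cycle_qaly, arm.discount_rate, first_cycle_discounted)
    return ArmResult(arm.drug, total_cost, total_qaly, trace)
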