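"""Random but structurally valid scenario generation for testing.

Baseline shares and outcome probabilities are drawn from flat Dirichlet
(simplex) distributions, utilities are sampled uniformly then sorted
decreasing, and prices/injection counts are uniform within their ranges.
Generation is deterministic under the seed.  Also provides a closed-form
QALY oracle for identity-transition scenarios, computed independently of
the cohort engine.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cea import WTPThreshold
from .cohort_engine import ArmParameters
from .errors import ParameterError
from .scenarios_io import ModelOptions, Scenario
from .state_space import HealthState, StateSpace

#: Letter-change categories by category count.
CATEGORY_SETS = {3: (15, 0, -15), 5: (30, 15, 0, -15, -30)}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the scenario generator."""

    n_states: int = 5
    outcome_categories: int = 3
    utility_range: tuple[float, float] = (0.3, 0.9)
    price_range: tuple[float, float] = (1_000.0, 10_000.0)
    injection_range: tuple[float, float] = (1.0, 12.0)
    seed: int = 0
    horizon: int = 10
    discount_rate: float = 0.035

    def __post_init__(self) -> None:
        if not 2 <= self.n_states <= 8:
            raise ParameterError(f"n_states must be in [2, 8], got {self.n_states}")
        if self.outcome_categories not in CATEGORY_SETS:
            raise ParameterError(f"outcome_categories must be 3 or 5, got {self.outcome_categories}")
        lo, hi = self.utility_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ParameterError(f"utility_range must satisfy 0 <= lo < hi <= 1, got {self.utility_range}")
        for name in ("price_range", "injection_range"):
            lo, hi = getattr(self, name)
            if not 0.0 <= lo <= hi:
                raise ParameterError(f"{name} must satisfy 0 <= lo <= hi, got {(lo, hi)}")


def _sorted_distinct_utilities(rng: np.random.Generator, spec: SyntheticSpec) -> np.ndarray:
    lo, hi = spec.utility_range
    for _ in range(100):
        u = np.sort(rng.uniform(lo, hi, size=spec.n_states))[::-1]
        if (np.diff(u) < 0).all():
            return u
    raise ParameterError("could not draw strictly decreasing utilities")  # pragma: no cover


def generate_scenario(spec: SyntheticSpec) -> Scenario:
    """Draw one structurally valid random scenario (disease label "custom")."""
    from .transitions import OutcomeDistribution  # local to avoid cycle at import time

    rng = np.random.default_rng(spec.seed)
    k = spec.n_states
    baseline = rng.dirichlet(np.ones(k))
    utilities = _sorted_distinct_utilities(rng, spec)
    # 15-letter bands walking down from 85; geometry is cosmetic for synthetic ladders.
    bounds = [85.0 - 15.0 * i for i in range(k + 1)]
    states = tuple(
        HealthState(
            name=f"state_{i}",
            letters_low=None if i == k - 1 else bounds[i + 1],
            letters_high=None if i == 0 else bounds[i],
            utility=float(utilities[i]),
            baseline_share=float(baseline[i]),
        )
        for i in range(k)
    )
    space = StateSpace("custom", states)

    cats = CATEGORY_SETS[spec.outcome_categories]
    outcomes = {}
    for arm in ("arm_a", "arm_b"):
        probs = rng.dirichlet(np.ones(len(cats)))
        outcomes[arm] = OutcomeDistribution(arm, "custom", dict(zip(cats, map(float, probs))))

    def draw_arm(drug: str) -> ArmParameters:
        return ArmParameters(
            drug=drug,
            unit_price=float(rng.uniform(*spec.price_range)),
            injections_per_year=float(rng.uniform(*spec.injection_range)),
            discount_rate=spec.discount_rate,
            horizon=spec.horizon,
        )

    return Scenario(
        disease="custom",
        mode="synthetic",
        space=space,
        outcomes_a=outcomes["arm_a"],
        outcomes_b=outcomes["arm_b"],
        arm_a=draw_arm("arm_a"),
        arm_b=draw_arm("arm_b"),
        wtp=WTPThreshold(float(rng.uniform(10_000, 300_000)), 1.0),
        options=ModelOptions(),
    )


def with_identity_transitions(scenario: Scenario) -> Scenario:
    """Force both arms to stay-probability 1 (identity transition matrix)."""
    from .transitions import OutcomeDistribution

    stay_a = OutcomeDistribution(scenario.outcomes_a.drug, scenario.disease, {0: 1.0})
    stay_b = OutcomeDistribution(scenario.outcomes_b.drug, scenario.disease, {0: 1.0})
    return replace(scenario, outcomes_a=stay_a, outcomes_b=stay_b)


def closed_form_qaly_oracle(scenario: Scenario, first_cycle_discounted: bool = False) -> float:
    """Discounted QALY total under identity transitions, without the engine.

    ``(baseline . utilities) * sum_t (1+r)^-t`` over the horizon; arms share
    the state space so the value applies to either arm.
    """
    r = scenario.arm_a.discount_rate
    t = np.arange(scenario.arm_a.horizon, dtype=float)
    if first_cycle_discounted:
        t = t + 1.0
    annuity = float(np.sum((1.0 + r) ** -t))
    return float(scenario.space.baseline @ scenario.space.utilities) * annuity
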