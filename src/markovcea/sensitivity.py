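"""Deterministic sensitivity sweeps and gamma-cost probabilistic sensitivity.

One-way and two-way sweeps rerun the full comparison over grids of unit
prices or injection counts (including relative price fluctuations such as
+/-5% and +/-10%, and the 2020 negotiated-price preset).  The PSA draws
each arm's total cost from a gamma distribution whose mean equals the
deterministic total (shape = 1/cv^2, scale = mean * cv^2) while utilities
and transitions stay fixed, and summarizes decisions as cost-effectiveness
acceptability curves (CEACs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cea import CEAComparison
from .errors import ParameterError
from .scenarios_io import NEGOTIATED_PRICES, RunResult, Scenario, apply_overrides, run_base_case

SWEEP_PARAMETERS = ("unit_price_a", "unit_price_b", "injections_a", "injections_b")

#: Default relative price fluctuations.
DEFAULT_FLUCTUATIONS = (-0.10, -0.05, 0.0, 0.05, 0.10)

_MAX_GRID_CELLS = 10_000


@dataclass(frozen=True)
class SweepSpec:
    """One swept parameter: explicit values or relative fluctuations."""

    parameter: str
    values: Sequence[float] | None = None
    fluctuations: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.parameter not in SWEEP_PARAMETERS:
            raise ParameterError(f"unknown sweep parameter {self.parameter!r}; valid: {SWEEP_PARAMETERS}")
        if (self.values is None) == (self.fluctuations is None):
            raise ParameterError("exactly one of values/fluctuations must be given")
        if self.values is not None and len(self.values) == 0:
            raise ParameterError("values list must be nonempty")
        if self.fluctuations is not None and len(self.fluctuations) == 0:
            raise ParameterError("fluctuations list must be nonempty")

    def resolve(self, base_value: float) -> list[float]:
        vals = list(self.values) if self.values is not None else [base_value * (1 + f) for f in self.fluctuations]
        if any(v < 0 for v in vals):
            raise ParameterError(f"{self.parameter}: swept values must be >= 0, got {vals}")
        return vals


def _base_value(scenario: Scenario, parameter: str) -> float:
    return {
        "unit_price_a": scenario.arm_a.unit_price,
        "unit_price_b": scenario.arm_b.unit_price,
        "injections_a": scenario.arm_a.injections_per_year,
        "injections_b": scenario.arm_b.injections_per_year,
    }[parameter]


def _comparison_record(comp: CEAComparison) -> dict:
    return {
        "cost_a": comp.cost_a,
        "cost_b": comp.cost_b,
        "qaly_a": comp.qaly_a,
        "qaly_b": comp.qaly_b,
        "delta_cost": comp.delta_cost,
        "delta_qaly": comp.delta_qaly,
        "icer": comp.icer,
        "dominance": comp.dominance,
        "cost_effective": comp.cost_effective,
    }


def one_way_sweep(scenario: Scenario, spec: SweepSpec) -> pd.DataFrame:
    """Rerun the comparison for each swept value; one row per value."""
    rows = []
    for value in spec.resolve(_base_value(scenario, spec.parameter)):
        comp = run_base_case(apply_overrides(scenario, **{spec.parameter: value})).comparison
        rows.append({"parameter": spec.parameter, "value": value, **_comparison_record(comp)})
    return pd.DataFrame(rows)


def two_way_sweep(
    scenario: Scenario,
    spec_a: SweepSpec,
    spec_b: SweepSpec,
    max_cells: int = _MAX_GRID_CELLS,
) -> pd.DataFrame:
    """Cartesian grid over two swept parameters; one row per cell."""
    vals_a = spec_a.resolve(_base_value(scenario, spec_a.parameter))
    vals_b = spec_b.resolve(_base_value(scenario, spec_b.parameter))
    if len(vals_a) * len(vals_b) > max_cells:
        raise ParameterError(
            f"grid of {len(vals_a)}x{len(vals_b)} exceeds the {max_cells}-cell cap; "
            "thin the value lists or raise max_cells"
        )
    rows = []
    for va in vals_a:
        for vb in vals_b:
            comp = run_base_case(
                apply_overrides(scenario, **{spec_a.parameter: va, spec_b.parameter: vb})
            ).comparison
            rows.append({spec_a.parameter: va, spec_b.parameter: vb, **_comparison_record(comp)})
    return pd.DataFrame(rows)


def negotiated_price_scenario(scenario: Scenario) -> Scenario:
    """The named preset with both arms at the 2020 negotiated unit prices."""
    return apply_overrides(
        scenario,
        unit_price_a=NEGOTIATED_PRICES[scenario.arm_a.drug],
        unit_price_b=NEGOTIATED_PRICES[scenario.arm_b.drug],
    )


# ---------------------------------------------------------------------------
# probabilistic sensitivity analysis


def _default_wtp_grid(threshold: float) -> tuple[float, ...]:
    return tuple(np.linspace(0.0, 2.0 * threshold, 41))


@dataclass(frozen=True)
class PSAConfig:
    """Monte-Carlo configuration for the gamma-cost PSA."""

    iterations: int = 10_000
    seed: int = 0
    cost_cv: float = 0.2
    wtp_grid: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ParameterError(f"iterations must be >= 1, got {self.iterations}")
        if self.cost_cv <= 0:
            raise ParameterError(f"cost_cv must be > 0, got {self.cost_cv}")


@dataclass(frozen=True)
class CEACPoint:
    wtp: float
    prob_cost_effective: float


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration sample plus the acceptability curves."""

    base: RunResult
    samples: pd.DataFrame
    ceac: pd.DataFrame
    config: PSAConfig = field(repr=False, default_factory=PSAConfig)


def gamma_parameters(mean: float, cv: float) -> tuple[float, float]:
    """(shape, scale) of a gamma with the given mean and coefficient of variation."""
    if mean <= 0:
        raise ParameterError(f"gamma mean must be > 0, got {mean}")
    if cv <= 0:
        raise ParameterError(f"gamma cv must be > 0, got {cv}")
    shape = 1.0 / cv**2
    return shape, mean * cv**2


def run_psa(scenario: Scenario, config: PSAConfig) -> PSAResult:
    """Gamma-cost Monte-Carlo PSA.

    Each arm's total cost is drawn from an independent gamma stream whose
    mean is that arm's deterministic discounted total; QALYs stay at their
    deterministic values.  The run is fully reproducible from the seed.
    """
    base = run_base_case(scenario)
    n = config.iterations
    # Independent substreams keep the two arms' cost draws uncorrelated.
    ss_a, ss_b = np.random.SeedSequence(config.seed).spawn(2)
    rng_a, rng_b = np.random.default_rng(ss_a), np.random.default_rng(ss_b)

    def draw(rng: np.random.Generator, mean: float) -> np.ndarray:
        if mean == 0.0:
            return np.zeros(n)
        shape, scale = gamma_parameters(mean, config.cost_cv)
        return rng.gamma(shape, scale, size=n)

    cost_a = draw(rng_a, base.result_a.total_cost)
    cost_b = draw(rng_b, base.result_b.total_cost)
    qaly_a = np.full(n, base.result_a.total_qaly)
    qaly_b = np.full(n, base.result_b.total_qaly)
    samples = pd.DataFrame(
        {
            "iteration": np.arange(n),
            "cost_a": cost_a,
            "cost_b": cost_b,
            "qaly_a": qaly_a,
            "qaly_b": qaly_b,
            "delta_cost": cost_a - cost_b,
            "delta_qaly": qaly_a - qaly_b,
        }
    )
    grid = config.wtp_grid if config.wtp_grid is not None else _default_wtp_grid(scenario.wtp.threshold)
    ceac = ceac_frame(samples, grid)
    return PSAResult(base, samples, ceac, config)


def ceac_curve(samples: pd.DataFrame, wtp_grid: Sequence[float]) -> list[CEACPoint]:
    """Acceptability of arm a: fraction of iterations with strictly greater NMB.

    Ties (equal NMB) count as not cost-effective for arm a.
    """
    if len(samples) == 0:
        raise ParameterError("PSA sample is empty")
    if len(wtp_grid) == 0:
        raise ParameterError("wtp grid is empty")
    dc = samples["delta_cost"].to_numpy()
    de = samples["delta_qaly"].to_numpy()
    return [
        CEACPoint(float(w), float(np.mean(w * de - dc > 0.0)))
        for w in wtp_grid
    ]


def ceac_frame(samples: pd.DataFrame, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """CEAC for both arms as a table; the two probabilities sum to 1."""
    points = ceac_curve(samples, wtp_grid)
    return pd.DataFrame(
        {
            "wtp": [p.wtp for p in points],
            "prob_a": [p.prob_cost_effective for p in points],
            "prob_b": [1.0 - p.prob_cost_effective for p in points],
        }
    )


def plot_psa(result: PSAResult, scatter_path=None, ceac_path=None) -> None:
    """Optional plots: incremental cost-effectiveness plane and CEAC."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if scatter_path is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.scatter(result.samples["delta_qaly"], result.samples["delta_cost"], s=4, alpha=0.3)
        ax.axhline(0, color="grey", lw=0.8)
        ax.axvline(0, color="grey", lw=0.8)
        ax.set_xlabel("Incremental effectiveness (QALYs)")
        ax.set_ylabel("Incremental cost (RMB)")
        fig.tight_layout()
        fig.savefig(scatter_path, dpi=150)
        plt.close(fig)
    if ceac_path is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(result.ceac["wtp"], result.ceac["prob_a"], label=result.base.result_a.drug)
        ax.plot(result.ceac["wtp"], result.ceac["prob_b"], label=result.base.result_b.drug)
        ax.set_xlabel("Willingness to pay (RMB/QALY)")
        ax.set_ylabel("Probability cost-effective")
        ax.set_ylim(-0.02, 1.02)
        ax.legend()
        fig.tight_layout()
        fig.savefig(ceac_path, dpi=150)
        plt.close(fig)
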