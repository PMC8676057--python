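"""Built-in scenario library, config I/O and report writing.

Ships the six base scenarios (AMD/DME/PM crossed with real-world and RCT
injection counts) with all published parameters: baseline acuity
distributions, annual letter-change probabilities, utilities, unit prices
(list prices 5,550/5,700 RMB; 2020 negotiated prices 4,160/3,950 RMB),
a 3.5% discount rate, a 10-year horizon, and a WTP threshold of three
times 2019 Chinese per-capita GDP (70,892 RMB).

User configs are YAML; a config naming a ``disease`` (and optionally
``mode``) starts from the matching built-in scenario and overrides only
the keys present.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .cea import CEAComparison, WTPThreshold, compare_arms
from .cohort_engine import ArmParameters, ArmResult, run_arm
from .errors import ConfigurationError, MarkovCEAError, ValidationError
from .state_space import DISEASES, HealthState, StateSpace, build_state_space
from .transitions import OutcomeDistribution, TransitionMatrix, build_transition_matrix

MODES = ("real_world", "rct")

CONBERCEPT = "conbercept"
RANIBIZUMAB = "ranibizumab"

#: National reimbursement list prices (RMB per injection, 2019).
LIST_PRICES = {CONBERCEPT: 5550.0, RANIBIZUMAB: 5700.0}
#: Negotiated prices effective 2020-01-01 (RMB per injection).
NEGOTIATED_PRICES = {CONBERCEPT: 4160.0, RANIBIZUMAB: 3950.0}

GDP_PER_CAPITA_2019 = 70892.0
DEFAULT_WTP = WTPThreshold(GDP_PER_CAPITA_2019, 3.0)

DISCOUNT_RATE = 0.035
HORIZON_YEARS = 10

#: Annual injection counts (conbercept, ranibizumab) by disease and mode.
INJECTIONS = {
    "real_world": {"AMD": (4.8, 5.4), "DME": (5.5, 6.2), "PM": (1.8, 1.92)},
    "rct": {"AMD": (5.8, 11.5), "DME": (9.48, 7.9), "PM": (3.76, 3.9)},
}

#: Annual BCVA letter-change probabilities by disease and drug.
OUTCOME_PROBS = {
    "AMD": {
        CONBERCEPT: {15: 0.3210, 0: 0.5062, -15: 0.1728},
        RANIBIZUMAB: {15: 0.4300, 0: 0.4820, -15: 0.0880},
    },
    "DME": {
        CONBERCEPT: {15: 0.2500, 0: 0.7232, -15: 0.0268},
        RANIBIZUMAB: {15: 0.1850, 0: 0.7850, -15: 0.0300},
    },
    "PM": {
        CONBERCEPT: {30: 0.1832, 15: 0.5344, 0: 0.2519, -15: 0.0305, -30: 0.0000},
        RANIBIZUMAB: {30: 0.2003, 15: 0.4913, 0: 0.2755, -15: 0.0320, -30: 0.0007},
    },
}


@dataclass(frozen=True)
class ModelOptions:
    """Structural toggles; defaults reflect the documented base conventions."""

    blindness_absorbing: bool = False
    half_cycle_correction: bool = False
    first_cycle_discounted: bool = False


@dataclass(frozen=True)
class Scenario:
    """One fully parameterized two-arm comparison."""

    disease: str
    mode: str
    space: StateSpace
    outcomes_a: OutcomeDistribution
    outcomes_b: OutcomeDistribution
    arm_a: ArmParameters
    arm_b: ArmParameters
    wtp: WTPThreshold = DEFAULT_WTP
    options: ModelOptions = field(default_factory=ModelOptions)

    def matrix(self, arm: str) -> TransitionMatrix:
        outcomes = self.outcomes_a if arm == "a" else self.outcomes_b
        return build_transition_matrix(outcomes, self.space, self.options.blindness_absorbing)


@dataclass(frozen=True)
class RunResult:
    """Base-case outputs for a scenario."""

    scenario: Scenario
    result_a: ArmResult
    result_b: ArmResult
    comparison: CEAComparison


def load_builtin(disease: str, mode: str = "real_world", negotiated_prices: bool = False) -> Scenario:
    """Load one of the six shipped scenarios.

    Parameters
    ----------
    disease : {"AMD", "DME", "PM"}
    mode : {"real_world", "rct"}
        Source of the annual injection counts.
    negotiated_prices : bool
        Use the 2020 negotiated unit prices instead of the 2019 list prices.
    """
    if disease not in DISEASES:
        raise ConfigurationError(f"unknown disease {disease!r}; valid: {', '.join(DISEASES)}")
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; valid: {', '.join(MODES)}")
    prices = NEGOTIATED_PRICES if negotiated_prices else LIST_PRICES
    inj_a, inj_b = INJECTIONS[mode][disease]
    space = build_state_space(disease)
    return Scenario(
        disease=disease,
        mode=mode,
        space=space,
        outcomes_a=OutcomeDistribution(CONBERCEPT, disease, OUTCOME_PROBS[disease][CONBERCEPT]),
        outcomes_b=OutcomeDistribution(RANIBIZUMAB, disease, OUTCOME_PROBS[disease][RANIBIZUMAB]),
        arm_a=ArmParameters(CONBERCEPT, prices[CONBERCEPT], inj_a, discount_rate=DISCOUNT_RATE, horizon=HORIZON_YEARS),
        arm_b=ArmParameters(RANIBIZUMAB, prices[RANIBIZUMAB], inj_b, discount_rate=DISCOUNT_RATE, horizon=HORIZON_YEARS),
    )


def builtin_keys() -> list[tuple[str, str]]:
    """All (disease, mode) pairs in the shipped library."""
    return [(d, m) for d in DISEASES for m in MODES]


def run_base_case(scenario: Scenario) -> RunResult:
    """Simulate both arms and compare them at the scenario's WTP threshold."""
    opts = scenario.options
    res_a = run_arm(scenario.space, scenario.matrix("a"), scenario.arm_a,
                    opts.half_cycle_correction, opts.first_cycle_discounted)
    res_b = run_arm(scenario.space, scenario.matrix("b"), scenario.arm_b,
                    opts.half_cycle_correction, opts.first_cycle_discounted)
    return RunResult(scenario, res_a, res_b, compare_arms(res_a, res_b, scenario.wtp))


# ---------------------------------------------------------------------------
# serialization

def scenario_to_dict(scenario: Scenario) -> dict:
    return {
        "disease": scenario.disease,
        "mode": scenario.mode,
        "states": [asdict(s) for s in scenario.space.states],
        "outcomes": {
            scenario.arm_a.drug: {int(k): float(v) for k, v in scenario.outcomes_a.probs.items()},
            scenario.arm_b.drug: {int(k): float(v) for k, v in scenario.outcomes_b.probs.items()},
        },
        "arms": {"a": asdict(scenario.arm_a), "b": asdict(scenario.arm_b)},
        "wtp": {"gdp_per_capita": scenario.wtp.gdp_per_capita, "multiplier": scenario.wtp.multiplier},
        "options": asdict(scenario.options),
    }


def write_scenario(scenario: Scenario, path) -> None:
    """Serialize a scenario as a YAML config readable by :func:`read_config`."""
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False))


def _scenario_from_dict(cfg: dict) -> Scenario:
    """Build a Scenario from a fully populated dict, collecting all violations."""
    errors: list[str] = []
    disease = cfg.get("disease", "custom")
    mode = cfg.get("mode", "custom")

    space = None
    try:
        states = tuple(
            HealthState(
                name=str(s["name"]),
                letters_low=s.get("letters_low"),
                letters_high=s.get("letters_high"),
                utility=float(s["utility"]),
                baseline_share=float(s["baseline_share"]),
            )
            for s in cfg["states"]
        )
        space = StateSpace(disease, states)
    except ValidationError as exc:
        errors.extend(f"states: {e}" for e in exc.errors)
    except (MarkovCEAError, KeyError, TypeError) as exc:
        errors.append(f"states: {exc}")

    arms, outcomes = {}, {}
    for key in ("a", "b"):
        try:
            arms[key] = ArmParameters(**cfg["arms"][key])
        except (MarkovCEAError, KeyError, TypeError) as exc:
            errors.append(f"arms.{key}: {exc}")
    for key in ("a", "b"):
        # resolve the drug label from the raw config so outcome errors are
        # still reported when the arm itself failed to validate
        drug = cfg.get("arms", {}).get(key, {}).get("drug") or (arms[key].drug if key in arms else key)
        try:
            probs = {int(k): float(v) for k, v in cfg["outcomes"][drug].items()}
            dist = OutcomeDistribution(drug, disease, probs)
            if not 1 - 5e-4 <= dist.total <= 1 + 5e-4:
                errors.append(f"outcomes.{drug}: probabilities sum to {dist.total:.6f}, not 1")
            outcomes[key] = dist
        except (MarkovCEAError, KeyError, TypeError) as exc:
            errors.append(f"outcomes.{drug}: {exc}")

    try:
        wtp = WTPThreshold(**cfg.get("wtp", {"gdp_per_capita": GDP_PER_CAPITA_2019}))
    except (MarkovCEAError, TypeError) as exc:
        errors.append(f"wtp: {exc}")
        wtp = DEFAULT_WTP
    try:
        options = ModelOptions(**cfg.get("options", {}))
    except TypeError as exc:
        errors.append(f"options: {exc}")
        options = ModelOptions()

    if errors:
        raise ValidationError(errors)
    return Scenario(disease, mode, space, outcomes["a"], outcomes["b"], arms["a"], arms["b"], wtp, options)


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def read_config(path) -> Scenario:
    """Read a YAML scenario config.

    A config whose ``disease`` is one of the shipped diseases is layered
    over the matching built-in scenario (``mode`` defaults to real_world),
    so a file may override a single parameter such as one arm's unit price.
    Fully custom scenarios must supply every section.
    """
    path = Path(path)
    try:
        cfg = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise OSError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ValidationError([f"{path}: config must be a mapping, got {type(cfg).__name__}"])
    disease = cfg.get("disease")
    if disease in DISEASES:
        base = scenario_to_dict(load_builtin(disease, cfg.get("mode", "real_world")))
        cfg = _deep_merge(base, cfg)
    return _scenario_from_dict(cfg)


def validate_scenario(scenario: Scenario) -> list[str]:
    """Re-validate a scenario dict round-trip; returns all violations (empty if valid)."""
    try:
        _scenario_from_dict(scenario_to_dict(scenario))
    except ValidationError as exc:
        return exc.errors
    return []


# ---------------------------------------------------------------------------
# reports

REPORT_COLUMNS = [
    "Strategy",
    "Cost (RMB)",
    "Incremental costs",
    "Effectiveness (QALYs)",
    "Incremental effectiveness",
    "CER",
    "ICER",
]


def comparison_table(results: dict[str, CEAComparison] | list[CEAComparison] | CEAComparison) -> pd.DataFrame:
    """Stack comparisons into a result table (two rows per comparison)."""
    if isinstance(results, CEAComparison):
        results = [results]
    rows = []
    if isinstance(results, dict):
        for name, comp in results.items():
            for row in comp.to_rows():
                rows.append({"Scenario": name, **row})
        columns = ["Scenario"] + REPORT_COLUMNS
    else:
        for comp in results:
            rows.extend(comp.to_rows())
        columns = REPORT_COLUMNS
    return pd.DataFrame(rows, columns=columns)


def write_report(results, path, format: str = "csv") -> None:
    """Write comparisons to ``path`` as CSV (3-decimal) or JSON (full precision)."""
    table = comparison_table(results)
    path = Path(path)
    try:
        if format == "csv":
            table.round(3).to_csv(path, index=False)
        elif format == "json":
            records = table.to_dict(orient="records")
            path.write_text(json.dumps(records, indent=2))
        else:
            raise ConfigurationError(f"unknown report format {format!r}; valid: csv, json")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc


def apply_overrides(
    scenario: Scenario,
    unit_price_a: float | None = None,
    unit_price_b: float | None = None,
    injections_a: float | None = None,
    injections_b: float | None = None,
    discount_rate: float | None = None,
    horizon: int | None = None,
    wtp: float | None = None,
) -> Scenario:
    """Return a copy of ``scenario`` with selected parameters replaced."""
    arm_a, arm_b = scenario.arm_a, scenario.arm_b
    if unit_price_a is not None:
        arm_a = replace(arm_a, unit_price=unit_price_a)
    if unit_price_b is not None:
        arm_b = replace(arm_b, unit_price=unit_price_b)
    if injections_a is not None:
        arm_a = replace(arm_a, injections_per_year=injections_a)
    if injections_b is not None:
        arm_b = replace(arm_b, injections_per_year=injections_b)
    if discount_rate is not None:
        arm_a = replace(arm_a, discount_rate=discount_rate)
        arm_b = replace(arm_b, discount_rate=discount_rate)
    if horizon is not None:
        arm_a = replace(arm_a, horizon=horizon)
        arm_b = replace(arm_b, horizon=horizon)
    new_wtp = scenario.wtp if wtp is None else WTPThreshold(wtp, 1.0)
    return replace(scenario, arm_a=arm_a, arm_b=arm_b, wtp=new_wtp)
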