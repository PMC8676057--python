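import numpy as np
import pytest

from markovcea import build_state_space, load_builtin


@pytest.fixture(scope="session")
def amd_space():
    return build_state_space("AMD")


@pytest.fixture(scope="session")
def dme_space():
    return build_state_space("DME")


@pytest.fixture(scope="session")
def pm_space():
    return build_state_space("PM")


@pytest.fixture(scope="session")
def amd_scenario():
    return load_builtin("AMD", "real_world")


@pytest.fixture(scope="session")
def all_builtin_scenarios():
    return [load_builtin(d, m) for d in ("AMD", "DME", "PM") for m in ("real_world", "rct")]


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def annuity_oracle(rate: float, horizon: int) -> float:
    """Independent discount-factor sum: explicit per-cycle division."""
    total = 0.0
    for t in range(horizon):
        total += 1.0 / (1.0 + rate) ** t
    return total
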