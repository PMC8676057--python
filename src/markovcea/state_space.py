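"""Visual-acuity health-state ladders, unit conversions and utility valuation.

Health states are bands of best-corrected visual acuity (BCVA) measured in
ETDRS letters, ordered best vision first.  Each state carries a utility
weight in [0, 1] and a baseline cohort share.  AMD uses literature utility
values directly; DME and PM value each band with a linear utility-on-logMAR
model evaluated at band anchor acuities spaced 15 letters (0.3 logMAR)
apart.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError, ValidationError

logger = logging.getLogger(__name__)

DISEASES = ("AMD", "DME", "PM")

#: Linear utility model: utility = UTILITY_INTERCEPT - UTILITY_SLOPE * logMAR.
UTILITY_INTERCEPT = 0.828
UTILITY_SLOPE = 0.359

#: Tolerance on the raw baseline-share sum before it is considered a typo
#: rather than table rounding.
SHARE_SUM_TOL = 5e-4


def letters_to_logmar(letters: float) -> float:
    """Convert an ETDRS letter score to logMAR.

    Uses the standard chart relationship of 5 letters per 0.1 logMAR with
    85 letters at logMAR 0.0, i.e. ``(85 - letters) / 50``.

    Parameters
    ----------
    letters : float
        ETDRS letter count, in [0, 100].

    Returns
    -------
    float
        logMAR value (higher = worse vision).
    """
    if not 0 <= letters <= 100:
        raise DomainError(f"letters must be in [0, 100], got {letters}")
    return (85.0 - letters) / 50.0


def utility_from_logmar(logmar: float) -> float:
    """Health utility from visual acuity via the linear model.

    ``utility = 0.828 - 0.359 * logMAR``, clamped to [0, 1].  The clamp is
    never active over the acuity range used by the shipped scenarios
    (logMAR 0.2 to 1.4) but protects extreme user inputs.

    Parameters
    ----------
    logmar : float
        Non-negative logMAR value.
    """
    if logmar < 0:
        raise DomainError(f"logmar must be >= 0, got {logmar}")
    u = UTILITY_INTERCEPT - UTILITY_SLOPE * logmar
    return min(1.0, max(0.0, u))


@dataclass(frozen=True)
class HealthState:
    """One BCVA band.

    ``letters_low`` is the exclusive lower bound and ``letters_high`` the
    inclusive upper bound of the band; either may be ``None`` for an
    open-ended band (best and worst states).
    """

    name: str
    letters_low: float | None
    letters_high: float | None
    utility: float
    baseline_share: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.utility <= 1.0:
            raise DomainError(f"{self.name}: utility must be in [0, 1], got {self.utility}")
        if not 0.0 <= self.baseline_share <= 1.0:
            raise DomainError(f"{self.name}: baseline_share must be in [0, 1], got {self.baseline_share}")
        if (
            self.letters_low is not None
            and self.letters_high is not None
            and not self.letters_low < self.letters_high
        ):
            raise DomainError(
                f"{self.name}: letters_low ({self.letters_low}) must be < letters_high ({self.letters_high})"
            )


@dataclass(frozen=True)
class StateSpace:
    """Ordered ladder of health states, best vision first.

    Baseline shares are renormalized to sum to exactly 1 at construction;
    a warning is logged when the raw sum deviates from 1 by more than 1e-6
    (the AMD table sums to 0.9999).
    """

    disease: str
    states: tuple[HealthState, ...] = field()

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValidationError([f"{self.disease}: a state space needs at least 2 states"])
        errors = []
        utils = [s.utility for s in self.states]
        if any(b >= a for a, b in zip(utils, utils[1:])):
            errors.append(f"{self.disease}: utilities must be strictly decreasing best to worst, got {utils}")
        raw = sum(s.baseline_share for s in self.states)
        if abs(raw - 1.0) > SHARE_SUM_TOL:
            errors.append(f"{self.disease}: baseline shares sum to {raw:.6f}, outside 1 +/- {SHARE_SUM_TOL}")
        if errors:
            raise ValidationError(errors)
        if abs(raw - 1.0) > 1e-6:
            logger.warning("%s: baseline shares sum to %.6f; renormalizing", self.disease, raw)

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.states)

    @property
    def utilities(self) -> np.ndarray:
        return np.array([s.utility for s in self.states], dtype=float)

    @property
    def baseline(self) -> np.ndarray:
        """Baseline occupancy vector, renormalized to sum to exactly 1."""
        raw = np.array([s.baseline_share for s in self.states], dtype=float)
        return raw / raw.sum()


# Band tables: (name, letters_low, letters_high, baseline_share[, utility]).
# AMD carries literature utilities; DME/PM utilities come from the linear
# model at anchor acuities 75, 60, 45, 30, 15 letters.
_AMD_BANDS = (
    ("no visual impairment", 78.0, None, 0.0, 0.90),
    ("slight visual impairment", 68.0, 78.0, 0.1111, 0.85),
    ("mild visual impairment", 53.0, 68.0, 0.3827, 0.81),
    ("moderate visual impairment", 33.0, 53.0, 0.3210, 0.57),
    ("severe visual impairment", 18.0, 33.0, 0.1728, 0.52),
    ("blindness", None, 18.0, 0.0123, 0.40),
)

_DME_BANDS = (
    ("no visual impairment", 75.0, None, 0.0),
    ("mild visual impairment", 60.0, 75.0, 0.436),
    ("moderate visual impairment", 45.0, 60.0, 0.419),
    ("severe visual impairment", 30.0, 45.0, 0.117),
    ("blindness", None, 30.0, 0.028),
)

_PM_BANDS = (
    ("no visual impairment", 75.0, None, 0.0),
    ("mild visual impairment", 60.0, 75.0, 0.2938),
    ("moderate visual impairment", 45.0, 60.0, 0.4463),
    ("severe visual impairment", 30.0, 45.0, 0.2034),
    ("blindness", None, 30.0, 0.0565),
)

#: Letter anchor of the best state for formula-valued ladders; subsequent
#: anchors step down 15 letters per band (0.3 logMAR), with the open-ended
#: blindness band anchored 15 letters below the previous band.
_FORMULA_BEST_ANCHOR = 75.0
_FORMULA_ANCHOR_STEP = 15.0

_DEFAULT_UTILITY_SOURCE = {"AMD": "lookup", "DME": "formula", "PM": "formula"}


def band_anchor_letters(n_states: int, best_anchor: float = _FORMULA_BEST_ANCHOR) -> list[float]:
    """Anchor acuities for a formula-valued ladder: 15-letter spacing."""
    return [best_anchor - _FORMULA_ANCHOR_STEP * i for i in range(n_states)]


def build_state_space(disease: str, utility_source: str | None = None) -> StateSpace:
    """Build the shipped state space for one disease.

    Parameters
    ----------
    disease : {"AMD", "DME", "PM"}
    utility_source : {"lookup", "formula"}, optional
        Defaults to ``"lookup"`` for AMD (literature values) and
        ``"formula"`` for DME/PM (linear utility-on-logMAR model at the
        band anchors).  AMD has no formula anchors (its bands are unequal
        widths) so requesting ``"formula"`` for AMD is an error.
    """
    if disease not in DISEASES:
        raise ConfigurationError(f"unknown disease {disease!r}; valid: {', '.join(DISEASES)}")
    source = utility_source or _DEFAULT_UTILITY_SOURCE[disease]
    if source not in ("lookup", "formula"):
        raise ConfigurationError(f"unknown utility_source {source!r}; valid: lookup, formula")

    if disease == "AMD":
        if source == "formula":
            raise ConfigurationError("AMD utilities are literature lookup values; no formula anchors defined")
        states = tuple(
            HealthState(name, lo, hi, utility=u, baseline_share=share)
            for name, lo, hi, share, u in _AMD_BANDS
        )
        return StateSpace("AMD", states)

    bands = _DME_BANDS if disease == "DME" else _PM_BANDS
    if source == "lookup":
        # The shipped lookup IS the formula output; keep one code path.
        source = "formula"
    anchors = band_anchor_letters(len(bands))
    states = tuple(
        HealthState(name, lo, hi, utility=utility_from_logmar(letters_to_logmar(anchor)), baseline_share=share)
        for (name, lo, hi, share), anchor in zip(bands, anchors)
    )
    return StateSpace(disease, states)
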