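"""Exception hierarchy.

All package errors derive from :class:`MarkovCEAError` so callers can catch
everything with one clause; the subclasses distinguish bad numeric domains,
bad parameter combinations, unknown configuration keys, and config-file
validation failures (which carry the full list of violations, not just the
first).
"""

from __future__ import annotations


class MarkovCEAError(Exception):
    """Base class for all package errors."""


class DomainError(MarkovCEAError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ParameterError(MarkovCEAError, ValueError):
    """A parameter combination is inconsistent (e.g. category/disease mismatch)."""


class ConfigurationError(MarkovCEAError, KeyError):
    """An unknown scenario / disease / mode key was requested."""


class ValidationError(MarkovCEAError, ValueError):
    """A scenario failed validation.

    Attributes
    ----------
    errors : list of str
        Every violation found, each prefixed with the offending field path.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("scenario validation failed:\n" + "\n".join(f"  - {e}" for e in self.errors))
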