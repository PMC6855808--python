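"""Exception hierarchy.

All package errors derive from :class:`LipidModError` so callers can catch
one base class; the subclasses distinguish bad data from failed fits from
bad configuration.
"""


class LipidModError(Exception):
    """Base class for all package errors."""


class DegenerateDataError(LipidModError, ValueError):
    """Input is structurally valid but carries no usable signal
    (all-zero intensities, coplanar lipids, empty filter result...)."""


class DomainError(LipidModError, ValueError):
    """Argument outside the mathematical domain of the operation."""


class FitFailureError(LipidModError, RuntimeError):
    """A least-squares fit did not converge or the data are unidentifiable.

    Carries a ``diagnostics`` dict with the initial guesses / objective
    trace when available.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ComparabilityError(LipidModError, ValueError):
    """Two results cannot be compared (e.g. affinity ratio across fits
    with different site counts)."""


class SchemaError(LipidModError, ValueError):
    """A tabular input file violates the expected schema."""


class ConfigError(LipidModError, ValueError):
    """Invalid pipeline / CLI configuration."""
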