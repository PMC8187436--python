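"""Exception hierarchy.

All argument/contract violations raise :class:`ValueError` subclasses so callers
can distinguish bad inputs (their bug) from degenerate data (a property of the
recording) without broad excepts.
"""


class GammaresError(Exception):
    """Base class for package-specific errors."""


class ConfigError(GammaresError, ValueError):
    """A configuration object violates its invariants."""


class DegenerateDataError(GammaresError, ValueError):
    """Data are structurally valid but make the requested quantity undefined
    (e.g. non-positive baseline power, all-zero paired differences)."""


class NoResponseError(DegenerateDataError):
    """No positive spectral peak in the analysis band; the condition cannot
    yield weighted gamma-response metrics."""
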