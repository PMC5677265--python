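"""Exception hierarchy for gaitproxy.

All errors derive from :class:`GaitProxyError` so callers can catch the
package's failures with a single except clause; each subclass also derives
from the closest built-in so generic handling (``ValueError``) keeps working.
"""


class GaitProxyError(Exception):
    """Base class for all gaitproxy errors."""


class ParameterError(GaitProxyError, ValueError):
    """An argument value is outside its documented domain."""


class DomainError(GaitProxyError, ValueError):
    """Input data violates a mathematical precondition (e.g. negative force)."""


class StructuralError(GaitProxyError, ValueError):
    """Inputs are structurally inconsistent (length mismatch, missing channel)."""


class InsufficientDataError(GaitProxyError, ValueError):
    """Not enough samples to perform the requested operation."""


class UnsupportedGaitError(GaitProxyError, ValueError):
    """Gait pattern outside the supported regime (e.g. flight phases)."""


class DegenerateShapeError(GaitProxyError, ValueError):
    """A gait cycle lacks the expected M-shaped stance profile.

    Carries the single extremum that was found, if any, as ``extremum``
    (value, index) so callers can degrade gracefully.
    """

    def __init__(self, message, extremum=None):
        super().__init__(message)
        self.extremum = extremum


class ParseError(GaitProxyError, ValueError):
    """A file could not be parsed; carries the 1-based line number if known."""

    def __init__(self, message, line=None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line
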