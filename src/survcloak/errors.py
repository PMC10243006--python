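"""Exception hierarchy.

All library errors derive from :class:`SurvcloakError` so callers (and the
CLI) can map them onto exit codes: validation/configuration problems are
user errors, disclosure-control refusals are policy decisions, numerical
degeneracies are fit failures.
"""


class SurvcloakError(Exception):
    """Base class for all survcloak errors."""


class ValidationError(SurvcloakError):
    """Input violates a documented precondition or invariant."""


class ConfigurationError(SurvcloakError):
    """A requested column, option or mapping does not exist."""


class ParseError(SurvcloakError):
    """A cell could not be parsed; message carries the 1-based row number."""


class DisclosureControlError(SurvcloakError):
    """The disclosure guard refused the analysis.

    The message names the rule that fired and the threshold; it never
    contains subject-level data values.
    """


class DegenerateFitError(SurvcloakError):
    """A local regression window is numerically rank-deficient, or the
    AICc denominator is non-positive (span too small for n)."""


class SpanSelectionError(SurvcloakError):
    """No span in the search interval yields a valid smoother fit."""
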