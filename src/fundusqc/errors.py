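"""Exception hierarchy for fundusqc.

All package errors derive from :class:`FundusQCError` so callers can catch
everything with one clause; the subclasses distinguish bad parameters
(:class:`ValidationError`), failed structure detection
(:class:`DetectionError`), per-cell measurement failures
(:class:`MeasurementError`) and out-of-range queries (:class:`RangeError`).
"""


class FundusQCError(Exception):
    """Base class for all fundusqc errors."""


class ValidationError(FundusQCError, ValueError):
    """Invalid parameter or configuration value."""


class DetectionError(FundusQCError, RuntimeError):
    """No tape-like structure could be located in an image."""


class MeasurementError(FundusQCError, RuntimeError):
    """A requested cell or stripe could not be measured."""


class RangeError(FundusQCError, ValueError):
    """A queried position lies outside the rendered or readable range."""
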