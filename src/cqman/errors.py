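"""Exception hierarchy.

All package-specific failures derive from :class:`QpcrError` so callers can
catch one base class; the leaves also derive from the matching builtin
(ValueError / RuntimeError) for idiomatic handling.
"""


class QpcrError(Exception):
    """Base class for all errors raised by cqman."""


class FormatError(QpcrError, ValueError):
    """A file does not conform to the expected CSV schema."""


class CurveValidationError(QpcrError, ValueError):
    """An amplification curve violates its structural invariants."""


class ParameterError(QpcrError, ValueError):
    """A function argument is outside its admissible range."""


class DomainError(QpcrError, ValueError):
    """A mathematically required precondition does not hold."""


class StateError(QpcrError, RuntimeError):
    """An operation was applied to an object in the wrong state."""


class NoAmplificationError(QpcrError):
    """A curve shows no usable amplification (flat/noise-only or fit failure)."""


class EfficiencyError(QpcrError):
    """Per-reaction efficiency could not be estimated for a curve."""
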