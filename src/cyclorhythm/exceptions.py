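"""Exception hierarchy shared across the package.

Validation failures (bad annotations, bad parameters, domain violations)
derive from :class:`ValidationError`; file-format problems derive from
:class:`FormatError`.  The CLI maps these onto exit codes 2 and 3.
"""


class CyclorhythmError(Exception):
    """Base class for all package errors."""


class ValidationError(CyclorhythmError, ValueError):
    """Input violates a structural invariant or a parameter precondition."""


class AnnotationError(ValidationError):
    """Cycle/zone boundary annotation is malformed."""


class InsufficientCyclesError(ValidationError):
    """The operation needs more cycles than the annotation provides."""


class RhythmDomainError(ValidationError):
    """Rhythm-function evaluation requested outside its domain."""


class ParameterError(ValidationError):
    """A numeric parameter is out of its admissible range."""


class AlignmentError(ValidationError):
    """A cycle-aligned sample time falls outside the recording."""


class FormatError(CyclorhythmError, ValueError):
    """A file could not be parsed in the expected dialect."""
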