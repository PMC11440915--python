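"""Exception hierarchy.

Validation-type errors (bad input data, bad parameters) map to CLI exit
code 1; anything else maps to exit code 2.
"""


class SigattribError(Exception):
    """Base class for all package errors."""


class ValidationError(SigattribError, ValueError):
    """Input data violates a documented invariant."""


class SchemeMismatchError(ValidationError):
    """A matrix/catalog does not match the requested channel scheme."""


class MafFormatError(ValidationError):
    """A MAF file is missing mandatory columns or is malformed."""


class ContextUnavailableError(SigattribError):
    """Sequence context cannot be extracted (contig edge or N base)."""


class ParameterError(ValidationError):
    """A function parameter is outside its documented range."""


class GenerationError(SigattribError):
    """The simulator cannot satisfy a request (e.g. missing context)."""
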