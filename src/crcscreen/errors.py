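"""Exception hierarchy shared across the pipeline."""


class CrcScreenError(Exception):
    """Base class for all package errors."""


class FormatError(CrcScreenError):
    """A file does not conform to its declared format."""


class ParseError(CrcScreenError):
    """A single record or token could not be parsed."""


class DomainError(CrcScreenError, ValueError):
    """An argument is outside its mathematically valid domain."""


class DegenerateDataError(CrcScreenError):
    """Input is formally valid but carries no usable signal
    (zero variance, empty CDS, all-identical expression, ...)."""


class PairingError(CrcScreenError):
    """Tumor/normal or tumor/matched-sample metadata do not line up."""


class InsufficientDataError(CrcScreenError):
    """Fewer usable observations than the procedure requires."""
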