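"""Exception hierarchy shared across the package."""


class MitocharError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MitocharError):
    """A file could not be parsed; the message names the offending line."""


class CoordinateError(MitocharError):
    """A feature's coordinates are invalid for the genome it refers to."""


class ValidationError(MitocharError):
    """An annotation table violates a structural invariant."""


class CodonUsageError(MitocharError):
    """A coding sequence violates a reading-frame or stop-codon constraint."""
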