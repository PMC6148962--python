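"""Exception hierarchy shared across the pipeline."""


class SaavPipeError(Exception):
    """Base class for all pipeline errors."""


class ParseError(SaavPipeError, ValueError):
    """An input file violates its schema; the message names the offending
    record or line where possible."""


class ValidationError(SaavPipeError, ValueError):
    """A value breaks a domain invariant (coordinates, alphabets, ranges)."""


class ReferenceMismatchError(SaavPipeError, ValueError):
    """A variant's reference residue disagrees with the protein sequence,
    usually a sign of stale annotation.  ``mismatches`` holds every
    offending event when raised in aggregate."""

    def __init__(self, message, mismatches=None):
        super().__init__(message)
        self.mismatches = list(mismatches or [])
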