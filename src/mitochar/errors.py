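"""Exception hierarchy shared across the package.

Each error class maps to a distinct CLI exit code (see :mod:`mitochar.cli`).
"""


class MitocharError(Exception):
    """Base class for all package errors."""


class FormatError(MitocharError):
    """Malformed input file (FASTA, feature table, alignment)."""


class ValidationError(MitocharError):
    """Input violates a domain invariant (coordinates, alphabet, frame)."""


class InternalStopError(ValidationError):
    """A CDS contains an in-frame stop codon before its terminal codon."""

    def __init__(self, message: str, codon_indices=()):
        super().__init__(message)
        #: 1-based indices of the offending codons
        self.codon_indices = tuple(codon_indices)


class SpecError(MitocharError):
    """A synthetic-genome specification is unsatisfiable."""
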