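"""Domain types for circular annotated mitogenomes and sequence utilities.

Coordinate convention: 1-based inclusive throughout, matching published
mitogenome organization tables. A feature whose ``start`` exceeds its ``end``
wraps across the circle origin. Light-strand (L) features are stored with
canonical ``start <= end`` plus a strand flag; reverse-complement orientation
is applied only at extraction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError

#: IUPAC nucleotide codes and the unambiguous bases they expand to.
IUPAC_EXPANSION: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN",
    "TGCAYRSWMKVHDBN",
)

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "CR", "OL")


def reverse_complement(seq: str) -> str:
    """Reverse complement, IUPAC-aware; an involution on valid input."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named DNA sequence, optionally circular.

    Residues are stored uppercase; any character outside the IUPAC alphabet
    raises :class:`ValidationError` naming the first offending position.
    """

    id: str
    residues: str
    circular: bool = False
    description: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.residues:
            raise ValidationError(f"record {self.id!r}: empty sequence")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in IUPAC_EXPANSION:
                raise ValidationError(
                    f"record {self.id!r}: invalid character {ch!r} at position {i}"
                )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Feature:
    """An annotated feature on the circle.

    ``start > end`` marks an origin-wrapping feature. Duplicated gene names
    are conventional only for the two Leu/Ser tRNAs, which callers should
    disambiguate with a numeric suffix (tRNA-Leu1, tRNA-Ser2, ...).
    """

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "H"
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValidationError(
                f"feature {self.name!r}: unknown type {self.ftype!r} "
                f"(expected one of {FEATURE_TYPES})"
            )
        if self.strand not in ("H", "L"):
            raise ValidationError(f"feature {self.name!r}: strand must be H or L")
        if self.start < 1 or self.end < 1:
            raise ValidationError(
                f"feature {self.name!r}: coordinates must be >= 1 "
                f"(got {self.start}..{self.end})"
            )

    @property
    def wraps(self) -> bool:
        return self.start > self.end

    def length(self, genome_length: int) -> int:
        """Span length on a circle of the given size (1-based inclusive)."""
        if not self.wraps:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end


@dataclass
class AnnotatedMitogenome:
    """A circular mitogenome sequence plus its ordered feature annotation."""

    record: SequenceRecord
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.record.circular:
            raise ValidationError("annotated mitogenome requires a circular sequence record")
        n = len(self.record)
        for f in self.features:
            if f.start > n or f.end > n:
                raise ValidationError(
                    f"feature {f.name!r} at {f.start}..{f.end} exceeds genome length {n}"
                )
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))

    def __len__(self) -> int:
        return len(self.record)

    def feature(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of_type(self, ftype: str) -> list[Feature]:
        return [f for f in self.features if f.ftype == ftype]


def extract_feature_sequence(
    genome: AnnotatedMitogenome | SequenceRecord, feature: Feature
) -> str:
    """Coding-strand sequence of a feature.

    H-strand features return the genomic substring; L-strand features return
    its reverse complement. Origin-wrapping features concatenate the tail and
    head of the circle before orientation is applied.
    """
    record = genome.record if isinstance(genome, AnnotatedMitogenome) else genome
    residues = record.residues
    n = len(residues)
    if feature.start > n or feature.end > n:
        raise ValidationError(
            f"feature {feature.name!r} at {feature.start}..{feature.end} "
            f"exceeds sequence length {n}"
        )
    if feature.wraps:
        if not record.circular:
            raise ValidationError(
                f"feature {feature.name!r} wraps the origin of a non-circular record"
            )
        sub = residues[feature.start - 1 :] + residues[: feature.end]
    else:
        sub = residues[feature.start - 1 : feature.end]
    return reverse_complement(sub) if feature.strand == "L" else sub
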