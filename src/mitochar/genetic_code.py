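"""Vertebrate mitochondrial genetic code and CDS translation.

The vertebrate mitochondrial code (NCBI translation table 2) differs from the
standard code in ways that matter throughout this package: TGA encodes Trp,
ATA encodes Met, and AGA/AGG are stop codons, giving four stops in total
(TAA, TAG, AGA, AGG). Mitochondrial mRNAs may additionally terminate on an
*incomplete* stop codon -- a bare terminal T or TA that is completed to TAA
by post-transcriptional polyadenylation -- conventionally written "T(AA)" or
"TA(A)" in annotation tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

from .errors import InternalStopError, ValidationError

_UNAMBIGUOUS = frozenset("ACGT")


@lru_cache(maxsize=None)
def _ncbi_table(table_id: int) -> CodonTable.CodonTable:
    return CodonTable.unambiguous_dna_by_id[table_id]


@dataclass(frozen=True)
class GeneticCodeSpec:
    """A genetic code plus the start codons a pipeline run accepts.

    Parameters
    ----------
    table_id:
        NCBI translation table identifier. Default 2, the vertebrate
        mitochondrial code.
    start_codons:
        Codons accepted as translation initiators. The default {ATG, GTG}
        covers the codons observed in crocodile-newt mitogenomes; other
        vertebrates may need ATA or ATT added.
    """

    table_id: int = 2
    start_codons: frozenset[str] = frozenset({"ATG", "GTG"})

    def __post_init__(self) -> None:
        overlap = self.start_codons & self.stop_codons
        if overlap:
            raise ValidationError(
                f"start and stop codon sets must be disjoint; both contain {sorted(overlap)}"
            )

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(_ncbi_table(self.table_id).stop_codons)

    @property
    def forward_table(self) -> dict[str, str]:
        """Codon -> one-letter amino acid (stop codons absent)."""
        return dict(_ncbi_table(self.table_id).forward_table)

    def amino_acid(self, codon: str) -> str | None:
        """Translate one codon; ``None`` for a stop, ``'X'`` if ambiguous."""
        codon = codon.upper()
        if codon in self.stop_codons:
            return None
        aa = self.forward_table.get(codon)
        if aa is None:
            return "X"
        return aa

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stop_codons


VERTEBRATE_MITO = GeneticCodeSpec()


@dataclass
class Translation:
    """Result of translating a mitochondrial CDS.

    Attributes
    ----------
    protein:
        Amino-acid string (terminal stop codon excluded).
    stop_codon:
        The literal terminal bases: a full stop codon, "T"/"TA" for
        incomplete stops, or the final (non-stop) codon when no valid stop
        is present.
    stop_label:
        Annotation-style rendering: "TAA", "TAG", "AGA", "AGG", "T(AA)"
        or "TA(A)"; equals ``stop_codon`` verbatim when the stop is invalid.
    stop_complete:
        True when the CDS ends on a full three-base stop codon.
    has_valid_stop:
        False when the terminal bases are neither a stop codon nor an
        incomplete T/TA remainder.
    """

    protein: str
    stop_codon: str
    stop_label: str
    stop_complete: bool
    has_valid_stop: bool
    warnings: list[str] = field(default_factory=list)


def translate_mito(cds: str, code: GeneticCodeSpec = VERTEBRATE_MITO) -> Translation:
    """Translate a coding-strand CDS and classify its stop codon.

    The trailing remainder of a CDS whose length is not a multiple of three
    is classified as an incomplete stop when it is "T" or "TA" (rendered
    "T(AA)" / "TA(A)"); any other remainder is reported as an invalid stop.
    An in-frame stop codon anywhere before the terminal codon raises
    :class:`InternalStopError`.
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValidationError(f"CDS of length {len(cds)} is shorter than one codon")

    rem = len(cds) % 3
    body = cds[: len(cds) - rem] if rem else cds
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    notes: list[str] = []

    if rem == 0:
        terminal = codons[-1]
        if code.is_stop(terminal):
            stop_codon, stop_label, complete, valid = terminal, terminal, True, True
            coding = codons[:-1]
        else:
            stop_codon, stop_label, complete, valid = terminal, terminal, False, False
            coding = codons
            notes.append(f"CDS does not end on a stop codon (terminal codon {terminal})")
    else:
        tail = cds[len(cds) - rem :]
        coding = codons
        if tail == "T":
            stop_codon, stop_label, complete, valid = "T", "T(AA)", False, True
        elif tail == "TA":
            stop_codon, stop_label, complete, valid = "TA", "TA(A)", False, True
        else:
            stop_codon, stop_label, complete, valid = tail, tail, False, False
            notes.append(f"trailing remainder {tail!r} is not an incomplete stop (expected T or TA)")

    internal = [i + 1 for i, c in enumerate(coding) if code.is_stop(c)]
    if internal:
        raise InternalStopError(
            f"internal stop codon(s) at codon index {internal}", codon_indices=internal
        )

    protein_chars = []
    for i, codon in enumerate(coding, start=1):
        aa = code.amino_acid(codon)
        if aa == "X" and not _UNAMBIGUOUS.issuperset(codon):
            msg = f"ambiguous codon {codon} at codon {i} translated as X"
            notes.append(msg)
            warnings.warn(msg, stacklevel=2)
        protein_chars.append(aa if aa is not None else "*")

    return Translation(
        protein="".join(protein_chars),
        stop_codon=stop_codon,
        stop_label=stop_label,
        stop_complete=complete,
        has_valid_stop=valid,
        warnings=notes,
    )
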