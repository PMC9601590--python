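"""Readers and writers for FASTA and the five-column feature-table dialect.

FASTA goes through Biopython's SeqIO with an alphabet check on top (the
check reports the record and 1-based position of the first offending
character). The feature table is a tab-separated five-column dialect in the
spirit of INSDC feature tables::

    # gene  type    from    to      anticodon
    ND1     PCG     2707    3675
    tRNA-Glu        tRNA    14137   14070   GTT

Light-strand features are encoded by *reversed* coordinate order (from > to)
and stored canonically as ``start < end`` with ``strand='L'``. As a
consequence origin-wrapping features are not representable in this dialect
and :func:`write_feature_table` refuses them.
"""

from __future__ import annotations

import os
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError
from .genome import Feature, IUPAC_EXPANSION, SequenceRecord

FASTA_WRAP = 70


def read_fasta(path: str | os.PathLike, circular: bool = False) -> list[SequenceRecord]:
    """Read a (multi-)FASTA file into :class:`SequenceRecord` objects."""
    records: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
        for i, ch in enumerate(seq, start=1):
            if ch not in IUPAC_EXPANSION:
                raise FormatError(
                    f"{path}: record {rec.id!r} has non-nucleotide character "
                    f"{ch!r} at position {i}"
                )
        records.append(
            SequenceRecord(id=rec.id, residues=seq, circular=circular,
                           description=rec.description)
        )
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike) -> None:
    seqrecs = [
        SeqRecord(Seq(r.residues), id=r.id,
                  description=r.description[len(r.id):].strip() if r.description.startswith(r.id) else r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WRAP)
        writer.write_file(seqrecs)


def read_feature_table(path: str | os.PathLike, genome_length: int) -> list[Feature]:
    """Parse the five-column dialect; rows are returned in genome order."""
    features: list[Feature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 4:
                raise FormatError(
                    f"{path}:{lineno}: expected >=4 tab-separated columns, got {len(cols)}"
                )
            name, ftype = cols[0].strip(), cols[1].strip()
            try:
                a, b = int(cols[2]), int(cols[3])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            anticodon = cols[4].strip() or None if len(cols) > 4 else None
            for coord in (a, b):
                if coord < 1 or coord > genome_length:
                    raise FormatError(
                        f"{path}:{lineno}: coordinate {coord} outside [1, {genome_length}]"
                    )
            if a > b:
                start, end, strand = b, a, "L"
            else:
                start, end, strand = a, b, "H"
            try:
                features.append(
                    Feature(name=name, ftype=ftype, start=start, end=end,
                            strand=strand, anticodon=anticodon)
                )
            except ValidationError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    features.sort(key=lambda f: (f.start, f.end))
    return features


def write_feature_table(features: Iterable[Feature], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("# gene\ttype\tfrom\tto\tanticodon\n")
        for f in features:
            if f.wraps:
                raise FormatError(
                    f"feature {f.name!r} wraps the origin and cannot be encoded "
                    "in the reversed-coordinate dialect"
                )
            a, b = (f.end, f.start) if f.strand == "L" else (f.start, f.end)
            fh.write(f"{f.name}\t{f.ftype}\t{a}\t{b}\t{f.anticodon or ''}\n")
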