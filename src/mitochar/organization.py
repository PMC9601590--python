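"""Gene-organization analytics on the circle.

Reproduces the classic mitogenome organization table: per-feature lengths,
start/stop codons for protein-coding genes (with incomplete-stop
classification), strand, and the signed gap to the next feature in circle
order. A negative gap is an overlap between neighbouring features; a
positive gap is intergenic spacer (IGN). The gap printed for a row is the
gap *following* that feature, and the last row gaps back to the first, so
the signed gaps and the feature lengths obey the conservation law::

    sum(lengths) + sum(signed gaps) == genome length

exactly on every circular input. The light-strand replication origin (OL)
and the control region participate in the adjacency chain as first-class
features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .genetic_code import GeneticCodeSpec, VERTEBRATE_MITO, translate_mito
from .genome import AnnotatedMitogenome, extract_feature_sequence
from .errors import ValidationError


@dataclass
class OrganizationRow:
    name: str
    ftype: str
    start: int
    end: int
    strand: str
    length: int
    gap_after: int  # signed; negative = overlap with the next feature
    next_name: str
    start_codon: str | None = None
    stop_codon: str | None = None  # annotation-style label, e.g. "T(AA)"
    stop_complete: bool | None = None
    anticodon: str | None = None


@dataclass
class SpacerSummary:
    total_overlap_bp: int
    overlap_pairs: int
    longest_overlap_bp: int
    longest_overlap_pair: tuple[str, str] | None
    total_intergenic_bp: int
    intergenic_locations: int
    longest_intergenic_bp: int
    longest_intergenic_pair: tuple[str, str] | None


def _signed_circular_gap(
    start: int, end: int, next_start: int, genome_length: int
) -> int:
    """Signed gap ``next_start - end - 1`` on the circle.

    The gap is negative (an overlap of ``end - next_start + 1`` bases) when
    the next feature starts inside the current feature's span; otherwise it
    is the forward distance to the next feature's start.
    """
    forward = (next_start - end - 1) % genome_length
    span = (end - start) % genome_length  # feature length - 1
    if (next_start - start) % genome_length <= span:
        return forward - genome_length  # next feature starts inside this one
    return forward


def build_gene_table(
    genome: AnnotatedMitogenome, code: GeneticCodeSpec = VERTEBRATE_MITO
) -> list[OrganizationRow]:
    """Organization rows in circle order (features sorted by start).

    PCG rows carry the observed first codon and the classified stop codon;
    a first codon outside the permitted start set triggers a warning but is
    still reported verbatim.
    """
    feats = genome.features
    if not feats:
        raise ValidationError("annotated genome has no features")
    n = len(genome)
    rows: list[OrganizationRow] = []
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % len(feats)]
        if len(feats) == 1:
            gap = n - f.length(n)  # lone feature gaps forward to itself
        else:
            gap = _signed_circular_gap(f.start, f.end, nxt.start, n)
        row = OrganizationRow(
            name=f.name, ftype=f.ftype, start=f.start, end=f.end, strand=f.strand,
            length=f.length(n), gap_after=gap, next_name=nxt.name, anticodon=f.anticodon,
        )
        if f.ftype == "PCG":
            cds = extract_feature_sequence(genome, f)
            row.start_codon = cds[:3]
            if row.start_codon not in code.start_codons:
                warnings.warn(
                    f"{f.name}: first codon {row.start_codon} not in permitted "
                    f"start set {sorted(code.start_codons)}",
                    stacklevel=2,
                )
            tr = translate_mito(cds, code)
            row.stop_codon = tr.stop_label
            row.stop_complete = tr.stop_complete
        rows.append(row)
    return rows


def spacer_summary(rows: list[OrganizationRow]) -> SpacerSummary:
    """Overlap and intergenic totals over the adjacency chain."""
    overlaps = [(abs(r.gap_after), (r.name, r.next_name)) for r in rows if r.gap_after < 0]
    gaps = [(r.gap_after, (r.name, r.next_name)) for r in rows if r.gap_after > 0]
    longest_ov = max(overlaps, default=(0, None))
    longest_gap = max(gaps, default=(0, None))
    return SpacerSummary(
        total_overlap_bp=sum(v for v, _ in overlaps),
        overlap_pairs=len(overlaps),
        longest_overlap_bp=longest_ov[0],
        longest_overlap_pair=longest_ov[1],
        total_intergenic_bp=sum(v for v, _ in gaps),
        intergenic_locations=len(gaps),
        longest_intergenic_bp=longest_gap[0],
        longest_intergenic_pair=longest_gap[1],
    )


def organization_dataframe(rows: list[OrganizationRow]) -> pd.DataFrame:
    """Tabular view; the gap column is the gap following each feature."""
    return pd.DataFrame(
        [
            {
                "gene": r.name, "type": r.ftype, "from": r.start, "to": r.end,
                "length_bp": r.length, "start_codon": r.start_codon or "",
                "stop_codon": r.stop_codon or "", "anticodon": r.anticodon or "",
                "strand": r.strand, "intergenic_nucleotides_after": r.gap_after,
            }
            for r in rows
        ]
    )
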