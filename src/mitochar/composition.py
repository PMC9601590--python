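"""Base composition, A+T content, and strand-asymmetry skews.

Skews quantify the compositional asymmetry between the two strands of the
mitochondrial duplex::

    AT-skew = (A - T) / (A + T)
    GC-skew = (G - C) / (G + C)

computed on the reported strand. Summaries are produced for the whole
genome, the control region (D-loop), each rRNA, the pooled tRNAs, the
pooled protein-coding genes, and the three codon positions of the pooled
PCGs. Percentages are conventionally reported to one decimal and skews to
two; unrounded values are retained on every summary object.

Codon positions are assigned by chopping the oriented PCG concatenation
into consecutive triplets ("concatenated" mode, the default, which matches
how the standard desktop tools compute codon-position compositions when fed
a concatenated coding sequence). Because four genes end on an incomplete
one-base stop codon, the alternative "per_gene" mode -- each gene framed
from its own first codon -- distributes those trailing bases differently.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from .errors import ValidationError
from .genome import AnnotatedMitogenome, extract_feature_sequence

_UNAMBIGUOUS = ("A", "T", "G", "C")


@dataclass
class CompositionSummary:
    """Counts, percentages and skews for one labelled region."""

    label: str
    size: int
    counts: dict[str, int]
    n_ambiguous: int = 0

    @property
    def unambiguous_total(self) -> int:
        return sum(self.counts.values())

    def percentage(self, base: str) -> float:
        """Percentage of `base` among unambiguous bases."""
        return 100.0 * self.counts[base] / self.unambiguous_total

    @property
    def at_content(self) -> float:
        return self.percentage("A") + self.percentage("T")

    @property
    def at_skew(self) -> float:
        return compute_skews(
            self.counts["A"], self.counts["T"], self.counts["G"], self.counts["C"]
        )[0]

    @property
    def gc_skew(self) -> float:
        return compute_skews(
            self.counts["A"], self.counts["T"], self.counts["G"], self.counts["C"]
        )[1]

    def as_row(self, rounded: bool = True) -> dict:
        nd = (lambda x, k: round(x, k)) if rounded else (lambda x, k: x)
        return {
            "region": self.label,
            "size_bp": self.size,
            "A_pct": nd(self.percentage("A"), 1),
            "T_pct": nd(self.percentage("T"), 1),
            "C_pct": nd(self.percentage("C"), 1),
            "G_pct": nd(self.percentage("G"), 1),
            "AT_content_pct": nd(self.at_content, 1),
            "AT_skew": nd(self.at_skew, 2),
            "GC_skew": nd(self.gc_skew, 2),
        }


def compute_skews(a: float, t: float, g: float, c: float) -> tuple[float, float]:
    """AT- and GC-skew from counts, fractions or percentages (scale-free).

    A zero denominator yields NaN for that skew (undefined).
    """
    if min(a, t, g, c) < 0:
        raise ValidationError("base quantities must be non-negative")
    at = (a - t) / (a + t) if a + t > 0 else math.nan
    gc = (g - c) / (g + c) if g + c > 0 else math.nan
    return at, gc


def base_composition(seq: str, label: str = "") -> CompositionSummary:
    """Composition of one sequence; ambiguous bases counted separately."""
    seq = seq.upper()
    if not seq:
        raise ValidationError(f"region {label!r}: empty sequence")
    counts = {b: seq.count(b) for b in _UNAMBIGUOUS}
    n_amb = len(seq) - sum(counts.values())
    if n_amb == len(seq):
        raise ValidationError(f"region {label!r}: all bases ambiguous")
    if n_amb:
        warnings.warn(
            f"region {label!r}: {n_amb} ambiguous base(s) excluded from percentages",
            stacklevel=2,
        )
    return CompositionSummary(label=label, size=len(seq), counts=counts, n_ambiguous=n_amb)


def pooled_pcg_sequence(genome: AnnotatedMitogenome) -> str:
    """Oriented PCG sequences concatenated in annotation order."""
    return "".join(
        extract_feature_sequence(genome, f) for f in genome.features_of_type("PCG")
    )


def regional_summaries(
    genome: AnnotatedMitogenome, codon_frame: str = "concatenated"
) -> list[CompositionSummary]:
    """One summary per region class plus PCG codon positions.

    Regions: whole genome, D-loop (CR), each rRNA by name, pooled tRNAs,
    pooled PCGs, and PCG codon positions 1-3. A region class absent from
    the annotation is omitted with a warning.
    """
    if codon_frame not in ("concatenated", "per_gene"):
        raise ValidationError(f"unknown codon_frame {codon_frame!r}")
    out = [base_composition(genome.record.residues, "Genome")]

    crs = genome.features_of_type("CR")
    if crs:
        out.append(base_composition(extract_feature_sequence(genome, crs[0]), "D-loop"))
    else:
        warnings.warn("no control region annotated; D-loop summary omitted", stacklevel=2)

    rrnas = genome.features_of_type("rRNA")
    if not rrnas:
        warnings.warn("no rRNA annotated; rRNA summaries omitted", stacklevel=2)
    for f in rrnas:
        out.append(base_composition(extract_feature_sequence(genome, f), f.name))

    trnas = genome.features_of_type("tRNA")
    if trnas:
        pooled = "".join(extract_feature_sequence(genome, f) for f in trnas)
        out.append(base_composition(pooled, "tRNAs"))
    else:
        warnings.warn("no tRNA annotated; tRNA summary omitted", stacklevel=2)

    pcgs = genome.features_of_type("PCG")
    if pcgs:
        if codon_frame == "concatenated":
            pooled = pooled_pcg_sequence(genome)
            positions = {1: [], 2: [], 3: []}
            for i, ch in enumerate(pooled):
                positions[i % 3 + 1].append(ch)
        else:
            pooled_parts = []
            positions = {1: [], 2: [], 3: []}
            for f in pcgs:
                cds = extract_feature_sequence(genome, f)
                pooled_parts.append(cds)
                for i, ch in enumerate(cds):
                    positions[i % 3 + 1].append(ch)
            pooled = "".join(pooled_parts)
        ordinal = {1: "PCGs-1st", 2: "PCGs-2nd", 3: "PCGs-3rd"}
        for p in (1, 2, 3):
            out.append(base_composition("".join(positions[p]), ordinal[p]))
        out.append(base_composition(pooled, "PCGs"))
    else:
        warnings.warn("no PCG annotated; PCG summaries omitted", stacklevel=2)
    return out


def per_gene_skews(genome: AnnotatedMitogenome) -> pd.DataFrame:
    """AT- and GC-skew of each PCG on its coding-strand sequence."""
    pcgs = genome.features_of_type("PCG")
    if not pcgs:
        raise ValidationError("per-gene skews require at least one PCG")
    rows = []
    for f in pcgs:
        summ = base_composition(extract_feature_sequence(genome, f), f.name)
        rows.append({"gene": f.name, "AT_skew": summ.at_skew, "GC_skew": summ.gc_skew})
    return pd.DataFrame(rows)


def composition_dataframe(
    summaries: list[CompositionSummary], rounded: bool = True
) -> pd.DataFrame:
    return pd.DataFrame([s.as_row(rounded=rounded) for s in summaries])


def load_reference_genome_compositions() -> pd.DataFrame:
    """Published whole-mitogenome compositions of 33 salamandrid species.

    Percentages, A+T content and skews as printed for the GenBank-accessioned
    mitogenomes bundled as a fixture; used to validate the skew arithmetic.
    """
    path = resources.files("mitochar.data") / "salamandrid_mitogenome_composition.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")


def load_reference_region_compositions() -> pd.DataFrame:
    """Published per-region compositions of two crocodile-newt mitogenomes."""
    path = resources.files("mitochar.data") / "tylototriton_region_composition.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t", comment="#")
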