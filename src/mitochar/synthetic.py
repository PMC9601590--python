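"""Synthetic mitogenomes and diverged taxon sets with known ground truth.

The generator emulates the canonical vertebrate mitogenome architecture:
37 genes (13 PCGs, 22 tRNAs, 2 rRNAs) plus the control region and the
light-strand replication origin (OL), with a fixed gene order, realistic
overlaps and intergenic gaps, heavy/light strand assignment, and the PCG
start/stop conventions including incomplete stop codons. The default
template hard-codes the published 16,265-bp crocodile-newt coordinate set
(GenBank OP598114), so tests can assert its literal totals (41 bp of
overlap in 10 pairs, 146 bp of intergenic spacer, longest gap 108 bp,
pooled tRNAs 1537 bp, pooled PCGs 11,383 bp).

Generation strategy: the start and stop codons of every PCG are pinned onto
the circle first (strand-mapped); each PCG is then built codon by codon,
sampling sense codons compatible with any already-fixed bases (from pins or
previously built overlapping genes), weighted by the PCG base-frequency
target. If an overlap leaves a fully fixed stop codon in a later gene's
frame the whole genome is resampled from a fresh substream (a dead end is
rare, so a bounded retry converges quickly and stays deterministic for a
given seed). Non-coding regions then fill the remaining positions i.i.d.
from their class's frequency target.

The taxon-set simulator introduces codon-aware substitutions along a star
tree, accepting nonsynonymous proposals with probability equal to the
per-gene dN/dS target (synonymous proposals are always accepted and
stop-creating proposals always rejected), and records the realized counts
as ground truth. No indels are introduced, so the output is aligned by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import SpecError, ValidationError
from .genetic_code import GeneticCodeSpec, VERTEBRATE_MITO
from .genome import (
    AnnotatedMitogenome,
    Feature,
    IUPAC_EXPANSION,
    SequenceRecord,
    reverse_complement,
)

_BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: (name, type, start, end, strand, anticodon, start codon, stop label)
#: Published 16,265-bp crocodile-newt architecture (GenBank OP598114);
#: anticodon strings are carried verbatim from the published table.
DEFAULT_TEMPLATE: tuple = (
    ("tRNA-Phe", "tRNA", 1, 68, "H", "GAA", None, None),
    ("12S rRNA", "rRNA", 69, 996, "H", None, None, None),
    ("tRNA-Val", "tRNA", 996, 1065, "H", "TAC", None, None),
    ("16S rRNA", "rRNA", 1068, 2630, "H", None, None, None),
    ("tRNA-Leu1", "tRNA", 2632, 2706, "H", "TAA", None, None),
    ("ND1", "PCG", 2707, 3675, "H", None, "ATG", "TAG"),
    ("tRNA-Ile", "tRNA", 3675, 3745, "H", "GAT", None, None),
    ("tRNA-Gln", "tRNA", 3748, 3818, "L", "CAT", None, None),
    ("tRNA-Met", "tRNA", 3821, 3890, "H", "TCA", None, None),
    ("ND2", "PCG", 3891, 4934, "H", None, "ATG", "TAA"),
    ("tRNA-Trp", "tRNA", 4933, 5001, "H", "GTC", None, None),
    ("tRNA-Ala", "tRNA", 5003, 5071, "L", "TTT", None, None),
    ("tRNA-Asn", "tRNA", 5072, 5144, "L", "TCC", None, None),
    ("OL", "OL", 5147, 5179, "H", None, None, None),
    ("tRNA-Cys", "tRNA", 5179, 5244, "L", "TCG", None, None),
    ("tRNA-Tyr", "tRNA", 5245, 5311, "L", "GTG", None, None),
    ("COI", "PCG", 5313, 6863, "H", None, "GTG", "TAA"),
    ("tRNA-Ser1", "tRNA", 6864, 6934, "L", "GCT", None, None),
    ("tRNA-Asp", "tRNA", 6936, 7005, "H", "TAG", None, None),
    ("COII", "PCG", 7007, 7694, "H", None, "ATG", "T(AA)"),
    ("tRNA-Lys", "tRNA", 7695, 7767, "H", "TGT", None, None),
    ("ATP8", "PCG", 7769, 7936, "H", None, "ATG", "TAA"),
    ("ATP6", "PCG", 7927, 8610, "H", None, "GTG", "TAA"),
    ("COIII", "PCG", 8610, 9393, "H", None, "ATG", "T(AA)"),
    ("tRNA-Gly", "tRNA", 9394, 9463, "H", "TGG", None, None),
    ("ND3", "PCG", 9464, 9811, "H", None, "ATG", "TAA"),
    ("tRNA-Arg", "tRNA", 9810, 9878, "H", "TTC", None, None),
    ("ND4L", "PCG", 9879, 10175, "H", None, "ATG", "TAA"),
    ("ND4", "PCG", 10169, 11546, "H", None, "ATG", "T(AA)"),
    ("tRNA-His", "tRNA", 11547, 11614, "H", "TGA", None, None),
    ("tRNA-Ser2", "tRNA", 11615, 11682, "H", "GTA", None, None),
    ("tRNA-Leu2", "tRNA", 11682, 11753, "H", "GCA", None, None),
    ("ND5", "PCG", 11754, 13565, "H", None, "ATG", "TAA"),
    ("ND6", "PCG", 13551, 14069, "L", None, "ATG", "AGA"),
    ("tRNA-Glu", "tRNA", 14070, 14137, "L", "GTT", None, None),
    ("CYTB", "PCG", 14140, 15280, "H", None, "ATG", "T(AA)"),
    ("tRNA-Thr", "tRNA", 15281, 15348, "H", "TGC", None, None),
    ("tRNA-Pro", "tRNA", 15457, 15527, "L", "TTG", None, None),
    ("D-loop", "CR", 15550, 16265, "H", None, None, None),
)

DEFAULT_GENOME_LENGTH = 16265

#: Base-frequency targets per region class (A, C, G, T). Derived from
#: published per-region compositions of crocodile-newt mitogenomes.
DEFAULT_BASE_FREQS: dict[str, tuple[float, float, float, float]] = {
    "PCG": (0.310, 0.270, 0.147, 0.273),
    "rRNA": (0.394, 0.215, 0.170, 0.221),
    "tRNA": (0.323, 0.177, 0.198, 0.302),
    "CR": (0.286, 0.212, 0.152, 0.349),
    "OL": (0.286, 0.212, 0.152, 0.349),
    "intergenic": (0.336, 0.263, 0.145, 0.257),
}


@dataclass
class TemplateRow:
    name: str
    ftype: str
    start: int
    end: int
    strand: str
    anticodon: str | None
    start_codon: str | None
    stop_label: str | None

    def length(self, genome_length: int) -> int:
        if self.start <= self.end:
            return self.end - self.start + 1
        return genome_length - self.start + 1 + self.end


@dataclass
class GenomeSpec:
    """Parameters of a synthetic mitogenome."""

    template: Sequence = DEFAULT_TEMPLATE
    genome_length: int = DEFAULT_GENOME_LENGTH
    base_freqs: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASE_FREQS)
    )
    ambiguity_rate: float = 0.0
    code: GeneticCodeSpec = VERTEBRATE_MITO
    max_attempts: int = 500

    def rows(self) -> list[TemplateRow]:
        return [TemplateRow(*r) for r in self.template]

    def freqs(self, region_class: str) -> tuple[float, float, float, float]:
        f = self.base_freqs.get(region_class, self.base_freqs.get("intergenic"))
        if f is None or abs(sum(f) - 1.0) > 0.01:
            raise SpecError(f"base frequencies for {region_class!r} must sum to 1")
        total = sum(f)
        return tuple(x / total for x in f)


@dataclass
class GroundTruth:
    """What the generator actually realized, for downstream verification."""

    seed: int
    rows: list[dict] = field(default_factory=list)  # per-feature expectations
    region_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    ambiguities: list[tuple[int, str, str]] = field(default_factory=list)  # (pos, code, true base)


@dataclass
class MutationTruth:
    """Ground truth of a simulated taxon set."""

    seed: int
    omega: dict[str, float] = field(default_factory=dict)
    branch_lengths: dict[str, float] = field(default_factory=dict)
    #: gene -> taxon -> (accepted synonymous, accepted nonsynonymous)
    realized: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)


class _DeadEnd(Exception):
    pass


def _expected_rows(spec: GenomeSpec) -> list[dict]:
    rows = spec.rows()
    L = spec.genome_length
    out = []
    for i, r in enumerate(rows):
        if i + 1 < len(rows):
            gap = rows[i + 1].start - r.end - 1
        else:
            gap = rows[0].start + L - r.end - 1
        out.append(
            {
                "name": r.name, "ftype": r.ftype, "start": r.start, "end": r.end,
                "strand": r.strand, "length": r.length(L), "gap_after": gap,
                "start_codon": r.start_codon, "stop_label": r.stop_label,
                "anticodon": r.anticodon,
            }
        )
    return out


def _coding_positions(row: TemplateRow, genome_length: int) -> list[int]:
    """Genomic positions (1-based) of the coding sequence, 5'->3'."""
    if row.start <= row.end:
        span = list(range(row.start, row.end + 1))
    else:
        span = list(range(row.start, genome_length + 1)) + list(range(1, row.end + 1))
    return span[::-1] if row.strand == "L" else span


def _stop_pin(stop_label: str) -> str:
    """Concrete terminal bases implied by a stop label."""
    if stop_label.endswith("(AA)"):
        return stop_label[0]  # "T(AA)" -> "T"
    if stop_label.endswith("(A)"):
        return stop_label[:2]  # "TA(A)" -> "TA"
    return stop_label


def _validate_template(spec: GenomeSpec) -> None:
    rows = spec.rows()
    L = spec.genome_length
    for i, r in enumerate(rows):
        if not (1 <= r.start <= L and 1 <= r.end <= L):
            raise SpecError(f"{r.name}: coordinates outside [1, {L}]")
        if r.ftype == "PCG":
            if r.start_codon is None or r.stop_label is None:
                raise SpecError(f"{r.name}: PCG template row needs start and stop codons")
            pin = _stop_pin(r.stop_label)
            if r.length(L) % 3 != len(pin) % 3:
                raise SpecError(
                    f"{r.name}: length {r.length(L)} inconsistent with stop {r.stop_label}"
                )
    for i, r in enumerate(rows):
        nxt = rows[(i + 1) % len(rows)]
        overlap = r.end - nxt.start + 1 if i + 1 < len(rows) else r.end - (nxt.start + L) + 1
        if overlap > 0 and (overlap >= r.length(L) or overlap >= nxt.length(L)):
            raise SpecError(
                f"overlap of {overlap} bp between {r.name} and {nxt.name} "
                "is as long as one of the features"
            )


def _generate_once(spec: GenomeSpec, rng: np.random.Generator) -> list[str | None]:
    L = spec.genome_length
    arr: list[str | None] = [None] * L
    code = spec.code
    stop_codons = sorted(code.stop_codons)
    sense = sorted(code.forward_table)
    pcg_freqs = spec.freqs("PCG")
    base_w = dict(zip(("A", "C", "G", "T"), pcg_freqs))

    def put(pos: int, base: str) -> None:
        cur = arr[pos - 1]
        if cur is not None and cur != base:
            raise _DeadEnd
        arr[pos - 1] = base

    def put_coding(positions: list[int], offset: int, bases: str, strand: str) -> None:
        for k, b in enumerate(bases):
            g = positions[offset + k]
            put(g, b if strand == "H" else _COMP[b])

    pcg_rows = [r for r in spec.rows() if r.ftype == "PCG"]
    pos_map = {r.name: _coding_positions(r, L) for r in pcg_rows}

    # pin every start codon and stop codon first
    for r in pcg_rows:
        positions = pos_map[r.name]
        put_coding(positions, 0, r.start_codon, r.strand)
        pin = _stop_pin(r.stop_label)
        put_coding(positions, len(positions) - len(pin), pin, r.strand)

    # build each PCG codon by codon
    for r in pcg_rows:
        positions = pos_map[r.name]
        n = len(positions)
        rem = n % 3
        n_codons = n // 3
        stop_is_complete = rem == 0
        for ci in range(n_codons):
            offset = ci * 3
            fixed = []
            for k in range(3):
                g = positions[offset + k]
                cur = arr[g - 1]
                if cur is None:
                    fixed.append(None)
                else:
                    fixed.append(cur if r.strand == "H" else _COMP[cur])
            if all(f is not None for f in fixed):
                codon = "".join(fixed)
                terminal_stop = stop_is_complete and ci == n_codons - 1
                if code.is_stop(codon) != terminal_stop:
                    raise _DeadEnd
                continue
            pool = stop_codons if (stop_is_complete and ci == n_codons - 1) else sense
            allowed = [
                c for c in pool
                if all(f is None or c[k] == f for k, f in enumerate(fixed))
            ]
            if not allowed:
                raise _DeadEnd
            weights = np.array(
                [base_w[c[0]] * base_w[c[1]] * base_w[c[2]] for c in allowed]
            )
            codon = allowed[rng.choice(len(allowed), p=weights / weights.sum())]
            put_coding(positions, offset, codon, r.strand)

    # fill non-coding feature spans, then intergenic leftovers
    class_of = ["intergenic"] * L
    for r in spec.rows():
        if r.ftype == "PCG":
            continue
        if r.start <= r.end:
            span = range(r.start, r.end + 1)
        else:
            span = list(range(r.start, L + 1)) + list(range(1, r.end + 1))
        for g in span:
            class_of[g - 1] = r.ftype
    for g in range(1, L + 1):
        if arr[g - 1] is None:
            f = spec.freqs(class_of[g - 1])
            arr[g - 1] = _BASES[rng.choice(4, p=np.array(f) / sum(f))]
    return arr


def generate_mitogenome(
    spec: GenomeSpec | None = None, seed: int = 0
) -> tuple[AnnotatedMitogenome, GroundTruth]:
    """Generate an annotated circular mitogenome matching the template.

    Deterministic for a fixed seed. PCGs begin with the template's start
    codon, contain no internal stop codons under the vertebrate
    mitochondrial code, and end with the template's (complete or
    incomplete) stop codon; overlapping features share bases consistently.
    """
    spec = spec or GenomeSpec()
    _validate_template(spec)
    arr = None
    for attempt in range(spec.max_attempts):
        rng = np.random.default_rng([seed & 0x7FFFFFFF, attempt])
        try:
            arr = _generate_once(spec, rng)
            break
        except _DeadEnd:
            continue
    if arr is None:
        raise SpecError(f"could not satisfy the template in {spec.max_attempts} attempts")

    truth = GroundTruth(seed=seed, rows=_expected_rows(spec))
    if spec.ambiguity_rate > 0:
        rng = np.random.default_rng([seed & 0x7FFFFFFF, 10_007])
        n_amb = rng.binomial(spec.genome_length, spec.ambiguity_rate)
        for pos in sorted(rng.choice(spec.genome_length, size=n_amb, replace=False) + 1):
            true = arr[pos - 1]
            codes = [c for c, exp in IUPAC_EXPANSION.items() if len(exp) == 2 and true in exp]
            code_ = codes[rng.choice(len(codes))]
            truth.ambiguities.append((int(pos), code_, true))
            arr[pos - 1] = code_

    residues = "".join(arr)
    record = SequenceRecord(
        id=f"synthetic-mt-seed{seed}",
        residues=residues,
        circular=True,
        description=f"synthetic-mt-seed{seed} synthetic vertebrate mitogenome, seed={seed}",
    )
    features = [
        Feature(name=r.name, ftype=r.ftype, start=r.start, end=r.end,
                strand=r.strand, anticodon=r.anticodon)
        for r in spec.rows()
    ]
    genome = AnnotatedMitogenome(record=record, features=features)

    for cls in ("PCG", "tRNA", "rRNA", "CR", "OL"):
        feats = genome.features_of_type(cls)
        if feats:
            from .genome import extract_feature_sequence

            pooled = "".join(extract_feature_sequence(genome, f) for f in feats)
            truth.region_counts[cls] = {b: pooled.count(b) for b in _BASES}
    return genome, truth


# ---------------------------------------------------------------------------
# diverged taxon sets

def random_cds(n_codons: int, seed: int = 0,
               code: GeneticCodeSpec = VERTEBRATE_MITO,
               freqs: tuple[float, float, float, float] = DEFAULT_BASE_FREQS["PCG"]) -> str:
    """A random stop-free CDS of ``n_codons`` codons (no terminal stop)."""
    rng = np.random.default_rng(seed)
    base_w = dict(zip(("A", "C", "G", "T"), freqs))
    sense = sorted(code.forward_table)
    weights = np.array([base_w[c[0]] * base_w[c[1]] * base_w[c[2]] for c in sense])
    weights = weights / weights.sum()
    idx = rng.choice(len(sense), size=n_codons, p=weights)
    return "".join(sense[i] for i in idx)


def _ancestral_cds_set(
    source: AnnotatedMitogenome | Mapping[str, str], code: GeneticCodeSpec
) -> dict[str, str]:
    if isinstance(source, AnnotatedMitogenome):
        from .genome import extract_feature_sequence

        out = {}
        for f in source.features_of_type("PCG"):
            cds = extract_feature_sequence(source, f)
            cds = cds[: len(cds) - len(cds) % 3]
            if cds and code.is_stop(cds[-3:]):
                cds = cds[:-3]
            out[f.name] = cds
        return out
    return {g: s[: len(s) - len(s) % 3] for g, s in source.items()}


def mutate_set(
    source: AnnotatedMitogenome | Mapping[str, str],
    n_taxa: int,
    omega: Mapping[str, float] | float,
    branch_length: float | Sequence[float] = 0.05,
    kappa: float = 2.0,
    seed: int = 0,
    code: GeneticCodeSpec = VERTEBRATE_MITO,
) -> tuple[dict[str, dict[str, str]], MutationTruth]:
    """Simulate ``n_taxa`` sequences per gene along a star tree.

    Parameters
    ----------
    source:
        An annotated genome (its PCGs become the ancestral CDS set) or a
        mapping gene -> ancestral CDS.
    omega:
        Per-gene dN/dS target (scalar applies to all genes). Must be > 0;
        nonsynonymous proposals are accepted with probability min(1, omega).
    branch_length:
        Expected substitution *proposals* per nucleotide site from the
        ancestor to each taxon (scalar or per-taxon sequence).
    kappa:
        Transition/transversion proposal ratio.

    Returns
    -------
    (alignments, truth): alignments maps gene -> taxon -> sequence (equal
    lengths, gap-free, alignment-free by construction); truth records the
    targets and the realized synonymous/nonsynonymous acceptance counts.
    """
    if n_taxa < 2:
        raise ValidationError(f"need >= 2 taxa, got {n_taxa}")
    ancestral = _ancestral_cds_set(source, code)
    if not ancestral:
        raise ValidationError("source contains no protein-coding genes")
    if isinstance(omega, (int, float)):
        omega_by_gene = {g: float(omega) for g in ancestral}
    else:
        omega_by_gene = {g: float(omega[g]) for g in ancestral}
    for g, w in omega_by_gene.items():
        if w <= 0:
            raise SpecError(f"gene {g!r}: dN/dS target must be > 0 (got {w})")
    taxa = [f"taxon{t + 1:02d}" for t in range(n_taxa)]
    if isinstance(branch_length, (int, float)):
        blens = {t: float(branch_length) for t in taxa}
    else:
        blens = {t: float(b) for t, b in zip(taxa, branch_length)}

    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    alignments: dict[str, dict[str, str]] = {g: {} for g in ancestral}
    truth = MutationTruth(seed=seed, omega=dict(omega_by_gene), branch_lengths=dict(blens))
    for g in ancestral:
        truth.realized[g] = {}

    for taxon in taxa:
        for gene, anc in ancestral.items():
            seq = list(anc)
            n_sites = len(seq)
            w = omega_by_gene[gene]
            n_prop = rng.poisson(blens[taxon] * n_sites)
            acc_syn = acc_non = 0
            for _ in range(n_prop):
                site = int(rng.integers(n_sites))
                old = seq[site]
                others = [b for b in _BASES if b != old]
                probs = np.array([kappa if b == transitions[old] else 1.0 for b in others])
                new = others[rng.choice(3, p=probs / probs.sum())]
                c0 = site - site % 3
                codon = seq[c0 : c0 + 3]
                new_codon = codon.copy()
                new_codon[site - c0] = new
                nc = "".join(new_codon)
                if code.is_stop(nc):
                    continue
                syn = code.forward_table["".join(codon)] == code.forward_table[nc]
                if syn:
                    seq[site] = new
                    acc_syn += 1
                elif rng.random() < min(1.0, w):
                    seq[site] = new
                    acc_non += 1
            alignments[gene][taxon] = "".join(seq)
            truth.realized[gene][taxon] = (acc_syn, acc_non)
    return alignments, truth


# ---------------------------------------------------------------------------
# assembly-variant scenario

def make_assembly_variants(
    genome: AnnotatedMitogenome,
    n_ambiguities: int = 2,
    fragment_length: int | None = None,
    seed: int = 0,
    flank_guard: int = 25,
) -> tuple[SequenceRecord, list[SequenceRecord | list[SequenceRecord]], GroundTruth]:
    """Emulate the cross-assembler scenario for the consensus module.

    Returns a primary assembly carrying ``n_ambiguities`` IUPAC-degenerate
    positions (each code compatible with the true base), plus two alternate
    assemblies derived from the truth: one full-length (circularly rotated)
    and one cut into unambiguous fragments when ``fragment_length`` is set.
    Ambiguous positions are spaced at least ``2 * flank_guard + 1`` bp apart
    so each retains an unambiguous matching context.
    """
    if n_ambiguities < 0:
        raise ValidationError("n_ambiguities must be >= 0")
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    truth_seq = genome.record.residues
    L = len(truth_seq)

    positions: list[int] = []
    guard = 2 * flank_guard + 1
    tries = 0
    while len(positions) < n_ambiguities:
        tries += 1
        if tries > 10_000 * max(1, n_ambiguities):
            raise SpecError("could not place ambiguities with the required spacing")
        p = int(rng.integers(1, L + 1))
        if all(min(abs(p - q), L - abs(p - q)) >= guard for q in positions):
            positions.append(p)
    positions.sort()

    truth = GroundTruth(seed=seed)
    primary_list = list(truth_seq)
    for p in positions:
        true = truth_seq[p - 1]
        codes = [c for c, exp in IUPAC_EXPANSION.items() if len(exp) == 2 and true in exp]
        code_ = codes[int(rng.integers(len(codes)))]
        primary_list[p - 1] = code_
        truth.ambiguities.append((p, code_, true))
    primary = SequenceRecord(
        id=f"{genome.record.id}-primary",
        residues="".join(primary_list),
        circular=True,
        description=f"primary assembly with {n_ambiguities} ambiguous site(s), seed={seed}",
    )

    offset = int(rng.integers(L))
    rotated = truth_seq[offset:] + truth_seq[:offset]
    alternates: list[SequenceRecord | list[SequenceRecord]] = [
        SequenceRecord(id=f"{genome.record.id}-altA", residues=rotated, circular=True,
                       description=f"full-length alternate assembly, seed={seed}")
    ]
    if fragment_length is None:
        alternates.append(
            SequenceRecord(id=f"{genome.record.id}-altB", residues=truth_seq, circular=True,
                           description=f"full-length alternate assembly, seed={seed}")
        )
    else:
        if fragment_length < guard + 2:
            raise SpecError("fragment_length too short to preserve flank contexts")
        step = max(1, fragment_length - guard)
        frags: list[SequenceRecord] = []
        doubled = truth_seq + truth_seq
        k = 0
        for start in range(0, L, step):
            chunk = doubled[start : start + fragment_length]
            if len(chunk) < guard + 1:
                continue
            if rng.random() < 0.5:
                chunk = reverse_complement(chunk)
            k += 1
            frags.append(
                SequenceRecord(id=f"{genome.record.id}-altB-frag{k}", residues=chunk,
                               circular=False,
                               description=f"alternate assembly fragment, seed={seed}")
            )
        alternates.append(frags)
    return primary, alternates, truth


# ---------------------------------------------------------------------------
# random circular layouts (property-test helper)

def random_feature_layout(
    seed: int = 0, n_features: int | None = None, genome_length: int | None = None
) -> AnnotatedMitogenome:
    """A random circular genome with a random non-coding feature layout.

    Features may overlap their successors or leave gaps; useful for
    exercising the circular length/gap conservation law without the cost of
    a full template genome.
    """
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    L = genome_length or int(rng.integers(500, 4000))
    n = n_features or int(rng.integers(2, 25))
    starts = np.sort(rng.choice(L, size=n, replace=False)) + 1
    features = []
    for i, s in enumerate(starts):
        nxt = starts[(i + 1) % n]
        room = (nxt - s) % L or L
        length = int(rng.integers(1, max(2, min(room + rng.integers(0, 10), L // 2))))
        end = (s + length - 1 - 1) % L + 1
        features.append(
            Feature(name=f"f{i + 1}", ftype="tRNA", start=int(s), end=int(end),
                    strand="H" if rng.random() < 0.7 else "L")
        )
    residues = "".join(_BASES[i] for i in rng.integers(0, 4, size=L))
    record = SequenceRecord(id=f"layout-seed{seed}", residues=residues, circular=True)
    return AnnotatedMitogenome(record=record, features=features)
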