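"""Codon counting, relative synonymous codon usage, and Nei-Gojobori Ka/Ks.

RSCU
----
The relative synonymous codon usage of a codon is its observed count divided
by the mean count over its synonymous family: RSCU = x * n / sum(family),
where n is the family size. Values within a family therefore sum to n, and a
uniformly used family has RSCU = 1 everywhere. Families follow the vertebrate
mitochondrial code, with the two-tRNA amino acids split by codon block the
way mitogenome codon-usage figures conventionally label them: Leu1 = CUN,
Leu2 = UUR, Ser1 = UCN, Ser2 = AGY. RSCU tables are reported in the RNA
alphabet (CUA rather than CTA); all internal work is in DNA.

Ka/Ks (Nei-Gojobori 1986 counting with Jukes-Cantor correction)
---------------------------------------------------------------
Potential synonymous sites per codon are the summed per-position fractions of
single-base changes that preserve the amino acid; changes that would create a
stop codon are excluded from both numerator and denominator of the fraction,
so every codon contributes exactly N + S = 3 sites. Observed differences
between a codon pair differing at k positions are apportioned by averaging
over all k! substitution orderings, discarding orderings that pass through a
stop codon (if every ordering is discarded -- possible only for a handful of
codon pairs under the mitochondrial code -- all orderings are used). Site
totals are averaged over the two sequences, p-distances pN = Nd/N and
pS = Sd/S are corrected with the Jukes-Cantor formula
d = -(3/4) ln(1 - (4/3) p), and the per-gene statistic aggregates pairwise
values as mean(Ka)/mean(Ks), which is robust to near-zero per-pair Ks.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations, product
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import InternalStopError, ValidationError
from .genetic_code import GeneticCodeSpec, VERTEBRATE_MITO

_BASES = "ACGT"
_UNAMBIGUOUS = frozenset(_BASES)


# ---------------------------------------------------------------------------
# codon counting and RSCU

def codon_counts(
    cds_list: Iterable[str] | Mapping[str, str],
    code: GeneticCodeSpec = VERTEBRATE_MITO,
) -> tuple[Counter, Counter]:
    """Count complete sense codons over a collection of coding sequences.

    Incomplete terminal codons are dropped; stop codons are tallied
    separately and excluded from the sense counts (so they never enter
    RSCU). A stop codon before the terminal codon raises
    :class:`InternalStopError` naming the gene and codon index.

    Returns
    -------
    (sense_counts, stop_counts)
    """
    if isinstance(cds_list, Mapping):
        items = list(cds_list.items())
    else:
        items = [(f"cds{i + 1}", s) for i, s in enumerate(cds_list)]
    sense: Counter = Counter()
    stops: Counter = Counter()
    for name, seq in items:
        seq = seq.upper()
        codons = [seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3)]
        for j, codon in enumerate(codons, start=1):
            if code.is_stop(codon):
                if j != len(codons):
                    raise InternalStopError(
                        f"{name}: internal stop codon {codon} at codon {j}",
                        codon_indices=[j],
                    )
                stops[codon] += 1
            elif _UNAMBIGUOUS.issuperset(codon):
                sense[codon] += 1
    return sense, stops


@lru_cache(maxsize=None)
def synonymous_families(code: GeneticCodeSpec = VERTEBRATE_MITO) -> dict[str, tuple[str, ...]]:
    """Family label -> codons (DNA alphabet), two-tRNA amino acids split."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in code.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    families: dict[str, tuple[str, ...]] = {}
    for aa, codons in sorted(by_aa.items()):
        if aa == "L":
            families["Leu1"] = tuple(sorted(c for c in codons if c.startswith("CT")))
            families["Leu2"] = tuple(sorted(c for c in codons if c.startswith("TT")))
        elif aa == "S":
            families["Ser1"] = tuple(sorted(c for c in codons if c.startswith("TC")))
            families["Ser2"] = tuple(sorted(c for c in codons if c.startswith("AG")))
        else:
            families[_AA3.get(aa, aa)] = tuple(sorted(codons))
    return families


_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "M": "Met",
    "F": "Phe", "P": "Pro", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def rscu(counts: Mapping[str, int], code: GeneticCodeSpec = VERTEBRATE_MITO) -> pd.DataFrame:
    """RSCU table (RNA alphabet) from sense-codon counts.

    Columns: codon, family, count, family_size, rscu. A family with zero
    total usage has NaN RSCU (undefined / missing).
    """
    rows = []
    for family, codons in synonymous_families(code).items():
        total = sum(counts.get(c, 0) for c in codons)
        n = len(codons)
        for c in codons:
            x = counts.get(c, 0)
            value = x * n / total if total > 0 else math.nan
            rows.append(
                {
                    "codon": c.replace("T", "U"),
                    "family": family,
                    "count": x,
                    "family_size": n,
                    "rscu": value,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Nei-Gojobori

@lru_cache(maxsize=None)
def _site_counts(codon: str, code: GeneticCodeSpec) -> tuple[float, float]:
    """(synonymous, nonsynonymous) potential sites of one sense codon."""
    aa = code.forward_table[codon]
    s = 0.0
    for pos in range(3):
        viable = 0
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if code.is_stop(alt):
                continue
            viable += 1
            if code.forward_table[alt] == aa:
                syn += 1
        if viable:
            s += syn / viable
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _diff_counts(c1: str, c2: str, code: GeneticCodeSpec) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons by substitution-pathway averaging."""
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        return 0.0, 0.0

    def walk(order: tuple[int, ...]) -> tuple[float, float] | None:
        sd = nd = 0.0
        cur = c1
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if code.is_stop(nxt) and step < len(order) - 1:
                return None  # pathway passes through a stop codon
            if code.is_stop(nxt):  # endpoint is a stop: caller excludes these
                return None
            if code.forward_table[cur] == code.forward_table[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        return sd, nd

    paths = [walk(order) for order in permutations(diffs)]
    valid = [p for p in paths if p is not None]
    if not valid:
        # Every ordering crosses a stop (rare, e.g. TGA<->AAA under the
        # mitochondrial code): fall back to averaging over all orderings,
        # classifying each step by amino-acid identity with '*' for stops.
        def walk_any(order):
            sd = nd = 0.0
            cur = c1
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                a1 = code.forward_table.get(cur, "*")
                a2 = code.forward_table.get(nxt, "*")
                if a1 == a2:
                    sd += 1
                else:
                    nd += 1
                cur = nxt
            return sd, nd

        valid = [walk_any(order) for order in permutations(diffs)]
    sd = sum(p[0] for p in valid) / len(valid)
    nd = sum(p[1] for p in valid) / len(valid)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    """JC-corrected distance; NaN when saturated (p >= 3/4)."""
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass
class PairwiseKaKs:
    """Nei-Gojobori statistics for one aligned sequence pair."""

    n_codons: int  # codon pairs actually compared
    N: float  # potential nonsynonymous sites (pair-averaged)
    S: float  # potential synonymous sites (pair-averaged)
    Nd: float  # observed nonsynonymous differences
    Sd: float  # observed synonymous differences
    pN: float
    pS: float
    ka: float  # JC-corrected; NaN if saturated
    ks: float
    ratio: float  # ka/ks; NaN when undefined (ks == 0 or saturation)

    @property
    def saturated(self) -> bool:
        return math.isnan(self.ka) or math.isnan(self.ks)


def nei_gojobori_pair(
    cds1: str, cds2: str, code: GeneticCodeSpec = VERTEBRATE_MITO
) -> PairwiseKaKs:
    """Pairwise Ka/Ks between two codon-aligned coding sequences.

    The sequences must be equal length; an incomplete terminal codon is
    trimmed. Codon pairs where either codon contains a gap or ambiguity, or
    is a stop codon, are skipped. The result is exactly symmetric in its
    arguments.
    """
    if len(cds1) != len(cds2):
        raise ValidationError(
            f"aligned CDSs differ in length ({len(cds1)} vs {len(cds2)})"
        )
    cds1, cds2 = cds1.upper(), cds2.upper()
    usable = len(cds1) - len(cds1) % 3
    s1 = s2 = 0.0
    sd = nd = 0.0
    n_codons = 0
    for i in range(0, usable, 3):
        a, b = cds1[i : i + 3], cds2[i : i + 3]
        if not (_UNAMBIGUOUS.issuperset(a) and _UNAMBIGUOUS.issuperset(b)):
            continue
        if code.is_stop(a) or code.is_stop(b):
            continue
        n_codons += 1
        s1 += _site_counts(a, code)[0]
        s2 += _site_counts(b, code)[0]
        d = _diff_counts(*sorted((a, b)), code)
        sd += d[0]
        nd += d[1]
    if n_codons == 0:
        raise ValidationError("no comparable codons between the two sequences")
    S = (s1 + s2) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else math.nan
    pN = nd / N if N > 0 else math.nan
    ka = _jukes_cantor(pN)
    ks = _jukes_cantor(pS)
    ratio = ka / ks if ks and not math.isnan(ka) and not math.isnan(ks) else math.nan
    return PairwiseKaKs(
        n_codons=n_codons, N=N, S=S, Nd=nd, Sd=sd, pN=pN, pS=pS, ka=ka, ks=ks, ratio=ratio
    )


def gene_kaks(
    gene_alignments: Mapping[str, Mapping[str, str]],
    code: GeneticCodeSpec = VERTEBRATE_MITO,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene aggregated Ka/Ks over all taxon pairs.

    Parameters
    ----------
    gene_alignments:
        gene -> (taxon -> aligned CDS). Each gene needs >= 2 taxa.

    Returns
    -------
    (gene_table, pair_table): the gene table carries mean Ka, mean Ks over
    pairs with defined values and the aggregated ratio mean(Ka)/mean(Ks)
    (NaN when undefined, e.g. identical taxa or full saturation); the pair
    table lists every pairwise result for transparency.
    """
    gene_rows, pair_rows = [], []
    for gene, aln in gene_alignments.items():
        taxa = sorted(aln)
        if len(taxa) < 2:
            raise ValidationError(f"gene {gene!r}: need >= 2 taxa, got {len(taxa)}")
        kas, kss = [], []
        for i, t1 in enumerate(taxa):
            for t2 in taxa[i + 1 :]:
                pw = nei_gojobori_pair(aln[t1], aln[t2], code)
                pair_rows.append(
                    {"gene": gene, "taxon1": t1, "taxon2": t2, "N": pw.N, "S": pw.S,
                     "Nd": pw.Nd, "Sd": pw.Sd, "pN": pw.pN, "pS": pw.pS,
                     "Ka": pw.ka, "Ks": pw.ks, "Ka_Ks": pw.ratio}
                )
                if not pw.saturated:
                    kas.append(pw.ka)
                    kss.append(pw.ks)
        if kas:
            mean_ka = sum(kas) / len(kas)
            mean_ks = sum(kss) / len(kss)
            ratio = mean_ka / mean_ks if mean_ks > 0 else math.nan
        else:
            mean_ka = mean_ks = ratio = math.nan
        gene_rows.append(
            {"gene": gene, "n_pairs": len(taxa) * (len(taxa) - 1) // 2,
             "n_defined_pairs": len(kas), "mean_Ka": mean_ka, "mean_Ks": mean_ks,
             "Ka_Ks": ratio}
        )
    return pd.DataFrame(gene_rows), pd.DataFrame(pair_rows)
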