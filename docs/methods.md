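# Methods

This note documents the models, conventions and numerical choices behind
`mitochar`, and what the synthetic-data generator does and does not
emulate.

## Coordinates and the circle

All coordinates are 1-based inclusive, the convention of published
mitogenome organization tables. A feature with `start > end` wraps the
circle origin. Light-strand (L) features are stored canonically with
`start < end` plus a strand flag; reverse-complement orientation is applied
only when a sequence is extracted. The five-column feature-table dialect
encodes the L strand by reversed coordinate order (`from > to`), which
means an origin-wrapping feature cannot be represented in that dialect;
`write_feature_table` refuses such features (the default template has
none — its origin sits at the tRNA-Phe start, so the D-loop ends exactly at
the last position of the circle).

The gap printed for an organization row is the signed gap *following* that
feature, with the last row gapping back to the first. A gap is negative
(an overlap) exactly when the next feature starts inside the current
feature's circular span; otherwise it is the forward distance to the next
start. Under this rule the conservation law
`Σ length + Σ gap = genome length` holds exactly on every circular input,
and it is asserted over hundreds of random layouts in the tests. A lone
feature gaps forward to itself (zero when it spans the whole circle).

Two published-prose discrepancies are worth flagging: from the template's
coordinates the longest overlap (15 bp) falls between ND5 and ND6 (the
ND4L/ND4 overlap is 7 bp), and positive gaps number 13 locations
(totalling 146 bp). Narrative summaries elsewhere attribute the 15-bp
overlap to ND4L/ND4 and count 15 IGN locations; this package reports only
what the coordinates imply.

## Translation and stop classification

Translation uses the vertebrate mitochondrial code (NCBI table 2:
TGA = Trp, ATA = Met, AGA/AGG additional stops). Permitted start codons
default to {ATG, GTG} — the set observed in crocodile-newt mitogenomes —
and are configurable, since other vertebrates initiate on ATA or ATT. Stop
classification is decided purely from CDS length mod 3 plus the terminal
bases: a full terminal stop codon is complete; a trailing `T` or `TA` is an
incomplete stop (polyadenylation-completed), rendered `T(AA)` / `TA(A)`;
anything else is flagged invalid. An in-frame stop before the terminal
codon is an error that names the codon index. Ambiguity codes are legal in
sequences but translate to `X` with a warning.

## Consensus correction

Ambiguous sites are resolved by flank-anchored exact matching rather than
whole-genome alignment: alternates are often fragmented, and ~16-kb
mitogenomes essentially never repeat a 40-mer, so a 20-bp exact context on
each side (default; minimum 8) places a site uniquely. Each alternate
assembly casts one vote — the base it shows between matching flanks,
searched in both orientations and circularly where applicable. An
alternate whose context matches more than one locus abstains (placement
ambiguity must not create votes); a vote outside the IUPAC expansion of
the primary's code is discarded and logged. Resolution is unanimity, else
strict majority, else unresolved; ties stay unresolved deliberately — the
conservative choice for sequences headed to a public archive. How a real
disagreement between alternate assemblers *should* be weighed is
underdetermined; the strict-majority policy is this module's own documented
choice.

## Composition and skews

`AT-skew = (A−T)/(A+T)` and `GC-skew = (G−C)/(G+C)` are computed from
unrounded counts (or any scale-free quantities: the formulas are ratios).
A zero denominator is reported as undefined (NaN). Percentages are
reported to one decimal and skews to two, matching the field's tables;
unrounded values are retained on every summary and in the JSON sidecars.
Ambiguous bases are excluded from both numerators and denominators and
logged — final published mitogenomes contain none.

PCG codon-position summaries default to "concatenated" framing: the
oriented PCG sequences are concatenated in annotation order and chopped
into global triplets. This matches how the standard desktop tools produce
codon-position compositions from a concatenated coding sequence and yields
position sizes 3795/3794/3794 on the 11,383-bp default template
(11383 = 3·3794 + 1). The biologically framed alternative
(`codon_frame="per_gene"`, each gene framed from its own first codon)
distributes the four incomplete-stop trailing bases differently, giving
3797/3793/3793. Both are available; the default reproduces the published
table values.

## RSCU

`RSCU = x·n / Σ(family)`, with families from the vertebrate mitochondrial
code and the two-tRNA amino acids split by codon block (Leu1 = CUN,
Leu2 = UUR, Ser1 = UCN, Ser2 = AGY), the way mitogenome codon-usage figures
label them. Stop codons and incomplete terminal codons never enter the
counts; a family with zero total usage has undefined (NaN) RSCU. Tables
are emitted in the RNA alphabet.

## Ka/Ks (Nei–Gojobori with Jukes–Cantor correction)

The counting method is implemented explicitly rather than delegated.
Potential-site fractions: at each codon position the synonymous fraction
is computed over the *viable* single-base changes, excluding changes that
would create a stop codon from both numerator and denominator, so each
codon contributes exactly N + S = 3 sites (conventions differ between
tools here — some count stop-creating changes as nonsynonymous — which is
why the choice is stated). Observed differences at codons differing at k
positions are averaged over all k! substitution orderings, discarding
orderings that pass through a stop; in the rare degenerate case where
every ordering is discarded (e.g. TGA↔AAA under this code, where both
one-step intermediates are stops) all orderings are used as a fallback.
Codon pairs containing gaps, ambiguity codes, or stop codons are skipped
pairwise. Site totals are averaged over the two sequences; pN = Nd/N and
pS = Sd/S are corrected by `d = −(3/4)·ln(1 − (4/3)p)`, undefined
(saturated) at p ≥ 3/4. The pairwise statistic is exactly symmetric in its
arguments.

Gene-level aggregation is mean(Ka)/mean(Ks) over pairs with defined
values — robust to near-zero per-pair Ks — with the full per-pair table
also emitted; whether published gene-level figures aggregated as
mean-of-ratios or ratio-of-means is generally unstated, so the choice here
is documented rather than asserted as anyone else's.

## Phylogeny preparation

Model-based inference (Bayesian/ML) and partition-scheme selection are out
of scope; the package exports relaxed-PHYLIP and NEXUS supermatrices plus
RAxML-style partition lines (`DNA, ND1_pos1 = 1-969\3`), three
codon-position blocks per gene, so external tools can be run. Taxon sets
must match across genes — no automatic gap-filling.

For self-contained verification: p-distances use pairwise deletion of
gap/ambiguous columns (complete deletion would discard too much on nearly
complete sequences); a pair with no comparable columns is an error.
Neighbor joining is the Saitou–Nei Q-criterion agglomeration with
deterministic tie-breaking by the lexicographic order of each cluster's
smallest leaf label, terminating in a basal trifurcation solved by the
three-point formulas. Negative branch lengths are clamped to zero and
logged (standard practice). On additive matrices the generating topology
and branch lengths are recovered exactly; the tests assert this on
hundreds of random trees and cross-check topologies against an independent
NJ implementation.

## Synthetic data: what it emulates, and what it does not

The default template hard-codes a published 16,265-bp crocodile-newt
coordinate set — 39 rows with their strands, overlaps, gaps, start codons
and stop classes — so tests can assert its literal totals (41 bp overlap /
10 pairs, 146 bp IGN, longest gap 108 bp, tRNAs 1537 bp, PCGs 11,383 bp).
The printed anticodon strings are carried verbatim as pass-through
annotation. Region base-frequency targets default to the published
per-region compositions.

Generation pins all PCG start/stop codons onto the circle first, then
samples each PCG codon-by-codon from the sense codons compatible with
already-fixed bases, weighted by the PCG frequency target; overlapping
genes therefore share bases consistently, and a dead end (a fully fixed
codon that would be a stop in a later gene's frame) triggers a bounded,
seed-deterministic resampling of the whole genome. Non-coding regions fill
i.i.d. from their class targets. Realized composition therefore tracks the
targets to binomial sampling error plus a small bias from excluding the
four (A/T-rich) stop codons — within about one percentage point of A+T at
16 kb, as the tests check at three region sizes.

The taxon-set simulator proposes substitutions along a star tree (Poisson
number of proposals per branch, transition/transversion ratio kappa = 2 by
default), always rejects stop-creating changes, always accepts synonymous
changes, and accepts nonsynonymous changes with probability min(1, ω) for
the gene's dN/dS target ω. This per-site acceptance/rejection scheme is
not a full codon-model matrix exponential, but it is sufficient for
rank-recovery: with 13 genes at 500 codons, 12 taxa and graded ω between
0.03 and 0.65 (ATP8-analog fastest, COI-analog slowest, all under
purifying selection), estimated gene ranks correlate with the simulated
targets at Spearman ≈ 0.99 over 20 replicates, and no gene's estimate
crosses 1.

What the generator does *not* emulate: tRNA secondary structure, indel
evolution, heteroplasmy, within-gene rate heterogeneity, or realistic
codon-usage bias beyond base frequencies. Passing tests therefore
demonstrate the analytics' correctness on architecture-faithful input, not
robustness to alignment error or annotation noise in real data.

## Problem sizes and determinism

Default verification sizes — 200 random layouts for the conservation law,
100 additive matrices (≤ 12 taxa) for NJ, 20 replicates of the 13-gene ×
12-taxon × 500-codon rank-recovery experiment — were chosen so the whole
suite and the acceptance script each run in well under a minute on one
CPU. Every stochastic component draws from an explicit seed
(`numpy.random.default_rng`); generated artifacts embed the seed in their
headers, and re-running any command with the same inputs and seed is
byte-identical.
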