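"""Supermatrix assembly, p-distances, and neighbor-joining verification trees.

The 13 protein-coding genes of a mitogenome set are concatenated into a
supermatrix with a gene x codon-position partition scheme (three partitions
per gene, each a stride-3 block), exported in relaxed PHYLIP, NEXUS and
RAxML-style partition formats so model-based inference can be run
externally. For self-contained verification the module provides uncorrected
p-distances (pairwise deletion of gap/ambiguous columns) and a
Saitou-Nei neighbor-joining tree with deterministic lexicographic
tie-breaking and Newick output. NJ recovers the generating topology exactly
on additive distance matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ValidationError

logger = logging.getLogger(__name__)

_VALID = frozenset("ACGT")


# ---------------------------------------------------------------------------
# supermatrix

@dataclass
class Partition:
    """One codon-position block of one gene within the supermatrix."""

    name: str  # e.g. "ND1_pos2"
    gene: str
    codon_position: int  # 1, 2 or 3
    start: int  # 1-based first column of the gene's range
    end: int  # 1-based last column of the gene's range
    stride: int = 3

    @property
    def n_sites(self) -> int:
        return len(range(self.start + self.codon_position - 1, self.end + 1, self.stride))

    def raxml_line(self) -> str:
        return (
            f"DNA, {self.name} = "
            f"{self.start + self.codon_position - 1}-{self.end}\\{self.stride}"
        )


@dataclass
class Supermatrix:
    taxa: list[str]
    sequences: dict[str, str]
    partitions: list[Partition] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.sequences.values())))


def concatenate_pcgs(
    gene_alignments: Mapping[str, Mapping[str, str]]
) -> Supermatrix:
    """Concatenate per-gene alignments over a shared taxon set.

    Every gene must cover the same taxa (no automatic gap-filling) and have
    a length divisible by three (stop codons already trimmed). The partition
    scheme lists three codon-position blocks per gene; their site counts sum
    to the supermatrix length.
    """
    if not gene_alignments:
        raise ValidationError("no gene alignments supplied")
    genes = list(gene_alignments)
    taxa = sorted(gene_alignments[genes[0]])
    parts: list[Partition] = []
    offset = 0
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    for gene in genes:
        aln = gene_alignments[gene]
        if sorted(aln) != taxa:
            missing = set(taxa) ^ set(aln)
            raise ValidationError(f"gene {gene!r}: taxon set mismatch ({sorted(missing)})")
        lengths = {len(s) for s in aln.values()}
        if len(lengths) != 1:
            raise ValidationError(f"gene {gene!r}: unequal aligned lengths {sorted(lengths)}")
        (glen,) = lengths
        if glen % 3:
            raise ValidationError(f"gene {gene!r}: aligned length {glen} not divisible by 3")
        for t in taxa:
            chunks[t].append(aln[t].upper())
        for pos in (1, 2, 3):
            parts.append(
                Partition(name=f"{gene}_pos{pos}", gene=gene, codon_position=pos,
                          start=offset + 1, end=offset + glen)
            )
        offset += glen
    return Supermatrix(taxa=taxa, sequences={t: "".join(chunks[t]) for t in taxa},
                       partitions=parts)


def write_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP (name, two spaces, sequence)."""
    with open(path, "w") as fh:
        fh.write(f"{len(sm.taxa)} {sm.n_columns}\n")
        for t in sm.taxa:
            fh.write(f"{t}  {sm.sequences[t]}\n")


def write_nexus(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("#NEXUS\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={len(sm.taxa)} NCHAR={sm.n_columns};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        for t in sm.taxa:
            fh.write(f"    {t}  {sm.sequences[t]}\n")
        fh.write("  ;\nEND;\n")
        if sm.partitions:
            fh.write("BEGIN SETS;\n")
            for p in sm.partitions:
                fh.write(
                    f"  CHARSET {p.name} = "
                    f"{p.start + p.codon_position - 1}-{p.end}\\{p.stride};\n"
                )
            fh.write("END;\n")


def write_raxml_partitions(sm: Supermatrix, path) -> None:
    with open(path, "w") as fh:
        for p in sm.partitions:
            fh.write(p.raxml_line() + "\n")


# ---------------------------------------------------------------------------
# distances

@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError(
                f"distance matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(self.values < 0):
            raise ValidationError("distance matrix has negative entries")
        if np.any(np.diag(self.values) != 0):
            raise ValidationError("distance matrix diagonal must be zero")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i, j = self.labels.index(pair[0]), self.labels.index(pair[1])
        return float(self.values[i, j])


def p_distance_matrix(alignment: Mapping[str, str]) -> DistanceMatrix:
    """Proportion of differing sites per pair, with pairwise deletion.

    Columns where either sequence has a gap or ambiguity code are excluded
    for that pair only. A pair with zero comparable sites is an error.
    """
    labels = sorted(alignment)
    if len(labels) < 2:
        raise ValidationError("p-distance requires >= 2 taxa")
    lengths = {len(alignment[t]) for t in labels}
    if len(lengths) != 1:
        raise ValidationError(f"aligned sequences differ in length: {sorted(lengths)}")
    arr = np.array([list(alignment[t].upper()) for t in labels])
    valid = np.isin(arr, list(_VALID))
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(both.sum())
            if comparable == 0:
                raise ValidationError(
                    f"taxa {labels[i]!r} and {labels[j]!r} share no comparable sites"
                )
            mism = int((arr[i][both] != arr[j][both]).sum())
            d[i, j] = d[j, i] = mism / comparable
    return DistanceMatrix(labels=labels, values=d)


# ---------------------------------------------------------------------------
# neighbor joining

@dataclass
class Node:
    name: str | None = None
    length: float | None = None  # branch to parent; None at the root
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if self.is_leaf:
            body = self.name or ""
        else:
            body = "(" + ",".join(c._nwk() for c in self.children) + ")"
            if self.name:
                body += self.name
        if self.length is not None:
            body += f":{self.length:.10g}"
        return body


@dataclass
class Tree:
    """Unrooted tree stored with a basal trifurcation (root has 3 children
    for >= 3 taxa)."""

    root: Node

    @property
    def n_leaves(self) -> int:
        return len(self.root.leaves())

    def to_newick(self) -> str:
        return self.root.newick()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def _clamp(length: float, context: str) -> float:
    if length < 0:
        logger.info("negative NJ branch length %.6g at %s clamped to 0", length, context)
        return 0.0
    return length


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining with the Q-criterion.

    Ties on Q are broken deterministically by the lexicographic order of
    each cluster's smallest leaf label. Negative branch lengths are clamped
    to zero (logged). For an additive input matrix the generating topology
    and branch lengths are recovered exactly.
    """
    n0 = len(dm.labels)
    if n0 < 3:
        raise ValidationError(f"neighbor joining requires >= 3 taxa, got {n0}")
    nodes: list[Node] = [Node(name=t) for t in dm.labels]
    reps: list[str] = list(dm.labels)  # lexicographic representative per cluster
    d = dm.values.astype(float).copy()
    active = list(range(n0))

    while len(active) > 3:
        m = len(active)
        best = None
        totals = {i: sum(d[i, k] for k in active if k != i) for i in active}
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - totals[i] - totals[j]
                key = (q, *sorted((reps[i], reps[j])))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i, j] / 2.0 + (totals[i] - totals[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        pair = f"({reps[i]},{reps[j]})"
        nodes_i, nodes_j = nodes[i], nodes[j]
        nodes_i.length = _clamp(li, pair)
        nodes_j.length = _clamp(lj, pair)
        new = Node(children=[nodes_i, nodes_j])
        # distances from the new cluster to the remaining ones
        k_new = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[k_new, k] = d[k, k_new] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        nodes.append(new)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [k_new]

    i, j, k = active
    # three-point formulas for the final trifurcation
    li = (d[i, j] + d[i, k] - d[j, k]) / 2.0
    lj = (d[i, j] + d[j, k] - d[i, k]) / 2.0
    lk = (d[i, k] + d[j, k] - d[i, j]) / 2.0
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = _clamp(length, f"terminal {reps[idx]}")
    order = sorted((i, j, k), key=lambda x: reps[x])
    return Tree(root=Node(children=[nodes[x] for x in order]))
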