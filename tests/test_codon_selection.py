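"""Codon counting, RSCU, and Nei-Gojobori Ka/Ks against exhaustive oracles."""

import itertools
import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mitochar as mc
from mitochar.codon_selection import (
    _diff_counts,
    _site_counts,
    codon_counts,
    gene_kaks,
    nei_gojobori_pair,
    rscu,
    synonymous_families,
)
from mitochar.errors import InternalStopError
from mitochar.genetic_code import VERTEBRATE_MITO
from mitochar.synthetic import mutate_set, random_cds

CODE = VERTEBRATE_MITO
SENSE = sorted(CODE.forward_table)
STOPS = set(CODE.stop_codons)


class TestCodonCounts:
    def test_manual_codon_walk(self):
        sense, stops = codon_counts(["ATGCTACTATAA"])
        assert sense["CTA"] == 2 and sense["ATG"] == 1
        assert "TAA" not in sense and stops["TAA"] == 1

    def test_empty_input(self):
        sense, stops = codon_counts([])
        assert sum(sense.values()) == 0 and sum(stops.values()) == 0

    def test_incomplete_terminal_codon_dropped(self):
        cds = "ATG" + "CAT" * 228 + "T"  # 688 bases
        sense, _ = codon_counts([cds])
        assert sum(sense.values()) == 229  # floor(688 / 3)

    def test_internal_stop_names_gene_and_index(self):
        with pytest.raises(InternalStopError, match="ND9"):
            codon_counts({"ND9": "ATGTAGCAT"})


class TestRSCU:
    def test_uniform_family_usage_gives_ones(self):
        counts = {c: 5 for c in SENSE}
        table = rscu(counts)
        assert table.rscu.round(9).eq(1.0).all()

    def test_single_codon_of_fourfold_family_scores_four(self):
        table = rscu({"GCA": 7}).set_index("codon")
        assert table.loc["GCA", "rscu"] == pytest.approx(4.0)  # Ala family GCN

    def test_split_leucine_family(self):
        # Leu1 = CUN block (4 codons) under the split-family convention
        table = rscu({"CTA": 3, "CTG": 1}).set_index("codon")
        assert table.loc["CUA", "family"] == "Leu1"
        assert table.loc["CUA", "rscu"] == pytest.approx(3 * 4 / 4)
        assert table.loc["UUA", "family"] == "Leu2"

    def test_unused_family_is_missing(self):
        table = rscu({"GCA": 1}).set_index("codon")
        assert math.isnan(table.loc["CGA", "rscu"])

    def test_rna_alphabet_output(self):
        table = rscu({"CTA": 1})
        assert set("T").isdisjoint("".join(table.codon))

    @given(st.dictionaries(st.sampled_from(SENSE), st.integers(0, 50), max_size=40))
    @settings(max_examples=50)
    def test_family_sums_equal_family_sizes(self, counts):
        table = rscu(counts)
        for family, group in table.groupby("family"):
            if group["count"].sum() > 0:
                assert group.rscu.sum() == pytest.approx(group.family_size.iloc[0])

    def test_families_partition_the_sense_codons(self):
        fams = synonymous_families(CODE)
        codons = [c for f in fams.values() for c in f]
        assert sorted(codons) == SENSE
        assert len(fams["Leu1"]) == 4 and len(fams["Ser2"]) == 2


def oracle_site_fractions(codon):
    """Independent enumeration of synonymous site fractions (test oracle)."""
    from Bio.Seq import Seq

    aa = str(Seq(codon).translate(table=2))
    syn = 0.0
    for pos in range(3):
        changes = []
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOPS:
                continue
            changes.append(str(Seq(alt).translate(table=2)) == aa)
        if changes:
            syn += sum(changes) / len(changes)
    return syn


def oracle_pathways(c1, c2):
    """Brute-force substitution-pathway averaging (test oracle)."""
    from Bio.Seq import Seq

    diffs = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in itertools.permutations(diffs):
        cur, sd, nd, blocked = c1, 0, 0, False
        for step, pos in enumerate(order):
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                blocked = True
                break
            if str(Seq(cur).translate(table=2)) == str(Seq(nxt).translate(table=2)):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestNeiGojobori:
    def test_identical_sequences_have_zero_distances(self):
        pw = nei_gojobori_pair("ATGCATCAT", "ATGCATCAT")
        assert pw.Nd == pw.Sd == 0
        assert pw.ka == 0 and pw.ks == 0
        assert math.isnan(pw.ratio)

    def test_synonymous_glu_pair(self):
        pw = nei_gojobori_pair("GAA", "GAG")
        assert pw.Sd == 1.0 and pw.Nd == 0.0
        # with a single codon the synonymous p-distance saturates (pS >= 3/4)
        assert pw.pS >= 0.75 and math.isnan(pw.ks)
        # dilute with 4-fold-degenerate codons so pS stays below saturation
        diluted = nei_gojobori_pair("GAACTTCCCGGA", "GAGCTTCCCGGA")
        assert diluted.Sd == 1.0 and diluted.Nd == 0.0
        assert diluted.ks > 0 and diluted.ka == 0

    def test_site_counts_match_exhaustive_oracle(self):
        for codon in SENSE:
            s, n = _site_counts(codon, CODE)
            assert s == pytest.approx(oracle_site_fractions(codon)), codon
            assert s + n == pytest.approx(3.0), codon

    def test_all_two_difference_pairs_match_pathway_oracle(self):
        checked = 0
        for c1 in SENSE:
            for c2 in SENSE:
                if sum(a != b for a, b in zip(c1, c2)) != 2:
                    continue
                expected = oracle_pathways(c1, c2)
                got = _diff_counts(c1, c2, CODE)
                if expected is not None:
                    assert got == pytest.approx(expected), (c1, c2)
                assert sum(got) == pytest.approx(2.0), (c1, c2)
                checked += 1
        assert checked > 1000

    def test_symmetry_under_argument_order(self):
        a = random_cds(120, seed=3)
        b = mutate_set({"g": a}, 2, omega=0.5, branch_length=0.15, seed=4)[0]["g"]["taxon02"]
        p1 = nei_gojobori_pair(a, b)
        p2 = nei_gojobori_pair(b, a)
        assert (p1.N, p1.S, p1.Nd, p1.Sd, p1.ka, p1.ks) == (p2.N, p2.S, p2.Nd, p2.Sd, p2.ka, p2.ks)

    def test_site_conservation_over_compared_codons(self):
        a = random_cds(200, seed=5)
        b = random_cds(200, seed=6)
        pw = nei_gojobori_pair(a, b)
        assert pw.N + pw.S == pytest.approx(3 * pw.n_codons)

    def test_length_mismatch_rejected(self):
        with pytest.raises(mc.errors.ValidationError):
            nei_gojobori_pair("ATGCAT", "ATG")

    def test_gapped_and_stop_codons_skipped(self):
        pw = nei_gojobori_pair("ATG---TAACAT", "ATGCAT" + "TAG" + "CAT")
        assert pw.n_codons == 2  # gap codon and stop-aligned codon excluded


class TestGeneKaKs:
    def test_identical_taxa_undefined(self):
        aln = {"g": {"a": "ATGCAT", "b": "ATGCAT"}}
        gene_table, pairs = gene_kaks(aln)
        assert math.isnan(gene_table.Ka_Ks.iloc[0])
        assert len(pairs) == 1

    def test_three_taxa_hand_computation(self):
        # nine codons; b carries one synonymous change, c carries two
        # synonymous changes plus one nonsynonymous (CTA Leu -> ATA Met/Ile)
        a = "GAACATATGCTATGGCGAAAATTCGTA"
        b = "GAGCATATGCTATGGCGAAAATTCGTA"
        c = "GAACACATGATATGGCGAAAGTTCGTA"
        gene_table, pairs = gene_kaks({"g": {"a": a, "b": b, "c": c}})
        by_pair = {(r.taxon1, r.taxon2): r for r in pairs.itertuples()}
        assert (by_pair[("a", "b")].Sd, by_pair[("a", "b")].Nd) == (1, 0)
        assert (by_pair[("a", "c")].Sd, by_pair[("a", "c")].Nd) == (2, 1)
        assert (by_pair[("b", "c")].Sd, by_pair[("b", "c")].Nd) == (3, 1)
        # expected aggregate from independently re-derived pairwise values
        def jc(p):
            return -0.75 * math.log(1 - 4 * p / 3)

        def expected_pair(x, y, sd, nd):
            s = (
                sum(oracle_site_fractions(x[i : i + 3]) for i in range(0, 27, 3))
                + sum(oracle_site_fractions(y[i : i + 3]) for i in range(0, 27, 3))
            ) / 2
            n = 27 - s
            return jc(nd / n), jc(sd / s)

        kas, kss = zip(
            expected_pair(a, b, 1, 0), expected_pair(a, c, 2, 1), expected_pair(b, c, 3, 1)
        )
        expected = (sum(kas) / 3) / (sum(kss) / 3)
        assert gene_table.Ka_Ks.iloc[0] == pytest.approx(expected)

    def test_purifying_simulation_never_estimates_positive_selection(self):
        genes = {f"g{i}": random_cds(500, seed=40 + i) for i in range(4)}
        omega = {"g0": 0.05, "g1": 0.2, "g2": 0.45, "g3": 0.65}
        alns, _ = mutate_set(genes, 6, omega=omega, branch_length=0.08, seed=41)
        gene_table, _ = gene_kaks(alns)
        assert gene_table.Ka_Ks.max() <= 1.05

    def test_estimated_ordering_tracks_simulated_targets(self):
        genes = {f"g{i}": random_cds(400, seed=60 + i) for i in range(3)}
        omega = {"g0": 0.03, "g1": 0.25, "g2": 0.6}
        alns, _ = mutate_set(genes, 6, omega=omega, branch_length=0.08, seed=61)
        gene_table, _ = gene_kaks(alns)
        est = dict(zip(gene_table.gene, gene_table.Ka_Ks))
        assert est["g0"] < est["g1"] < est["g2"]
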