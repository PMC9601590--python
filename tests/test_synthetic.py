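"""The synthetic-data generator and its ground-truth guarantees."""

import numpy as np
import pytest

import mitochar as mc
from mitochar.errors import SpecError, ValidationError
from mitochar.genetic_code import VERTEBRATE_MITO
from mitochar.genome import extract_feature_sequence
from mitochar.synthetic import (
    DEFAULT_BASE_FREQS,
    DEFAULT_TEMPLATE,
    GenomeSpec,
    generate_mitogenome,
    make_assembly_variants,
    mutate_set,
    random_cds,
)


class TestGenerateMitogenome:
    def test_default_architecture_counts(self, template_genome):
        genome, _ = template_genome
        assert len(genome) == 16265
        assert len(genome.features_of_type("PCG")) == 13
        assert len(genome.features_of_type("tRNA")) == 22
        assert len(genome.features_of_type("rRNA")) == 2
        assert len(genome.features_of_type("CR")) == 1
        assert len(genome.features_of_type("OL")) == 1

    def test_same_seed_is_deterministic(self):
        g1, _ = generate_mitogenome(seed=42)
        g2, _ = generate_mitogenome(seed=42)
        assert g1.record.residues == g2.record.residues

    def test_different_seeds_differ(self):
        g1, _ = generate_mitogenome(seed=42)
        g2, _ = generate_mitogenome(seed=43)
        assert g1.record.residues != g2.record.residues

    def test_pcgs_obey_start_and_stop_conventions(self, template_genome):
        genome, truth = template_genome
        expected = {r["name"]: r for r in truth.rows if r["ftype"] == "PCG"}
        for f in genome.features_of_type("PCG"):
            cds = extract_feature_sequence(genome, f)
            assert cds[:3] == expected[f.name]["start_codon"]
            tr = mc.translate_mito(cds)  # raises on internal stops
            assert tr.stop_label == expected[f.name]["stop_label"]

    def test_overlapping_features_share_bases_consistently(self, template_genome):
        genome, _ = template_genome
        # ATP8 7769..7936 and ATP6 7927..8610 share ten bases on the H strand
        atp8 = extract_feature_sequence(genome, genome.feature("ATP8"))
        atp6 = extract_feature_sequence(genome, genome.feature("ATP6"))
        assert atp8[-10:] == atp6[:10]

    def test_at_rich_target_recovered_within_sampling_tolerance(self):
        freqs = {k: (0.30, 0.20, 0.20, 0.30) for k in DEFAULT_BASE_FREQS}
        spec = GenomeSpec(base_freqs=freqs)
        genome, _ = generate_mitogenome(spec, seed=9)
        seq = genome.record.residues
        at = (seq.count("A") + seq.count("T")) / len(seq)
        assert at == pytest.approx(0.60, abs=0.01)

    def test_composition_tolerance_shrinks_with_region_size(self):
        # binomial sampling: relative deviation drops as regions grow
        genome, _ = generate_mitogenome(seed=5)
        devs = {}
        for cls in ("CR", "rRNA", "PCG"):
            feats = genome.features_of_type(cls)
            pooled = "".join(extract_feature_sequence(genome, f) for f in feats)
            target = GenomeSpec().freqs(cls)
            realized = tuple(pooled.count(b) / len(pooled) for b in "ACGT")
            devs[cls] = (len(pooled), max(abs(r - t) for r, t in zip(realized, target)))
        for size, dev in devs.values():
            assert dev < 3 * np.sqrt(0.25 / size) + 0.02

    def test_unsatisfiable_template_rejected(self):
        bad = (
            ("g1", "PCG", 1, 9, "H", None, "ATG", "TAA"),
            ("g2", "PCG", 2, 13, "H", None, "ATG", "T(AA)"),  # overlap 8 of length 9
        )
        with pytest.raises(SpecError):
            generate_mitogenome(GenomeSpec(template=bad, genome_length=100), seed=0)

    def test_seed_embedded_in_record_header(self):
        genome, _ = generate_mitogenome(seed=77)
        assert "seed=77" in genome.record.description


class TestMutateSet:
    def test_zero_branch_length_gives_identical_taxa(self):
        genes = {"g": random_cds(50, seed=1)}
        alns, _ = mutate_set(genes, 3, omega=0.5, branch_length=0.0, seed=2)
        seqs = set(alns["g"].values())
        assert seqs == {genes["g"]}

    def test_pure_synonymous_regime(self):
        """dN/dS target near zero permits only synonymous changes."""
        genes = {"g": random_cds(300, seed=3)}
        alns, truth = mutate_set(genes, 2, omega=1e-12, branch_length=0.2, seed=4)
        pw = mc.nei_gojobori_pair(alns["g"]["taxon01"], alns["g"]["taxon02"])
        assert pw.ks > 0
        assert pw.ka == pytest.approx(0.0, abs=1e-12)
        realized_non = sum(n for _, n in truth.realized["g"].values())
        assert realized_non == 0

    def test_no_stops_introduced(self):
        genes = {"g": random_cds(200, seed=5)}
        alns, _ = mutate_set(genes, 4, omega=0.8, branch_length=0.3, seed=6)
        for seq in alns["g"].values():
            for i in range(0, len(seq), 3):
                assert seq[i : i + 3] not in VERTEBRATE_MITO.stop_codons

    def test_nonpositive_omega_rejected(self):
        with pytest.raises(SpecError):
            mutate_set({"g": random_cds(10, seed=0)}, 2, omega=0.0)

    def test_alignments_from_genome_source(self, template_genome):
        genome, _ = template_genome
        alns, truth = mutate_set(genome, 2, omega=0.2, branch_length=0.01, seed=7)
        assert set(alns) == {f.name for f in genome.features_of_type("PCG")}
        for gene, aln in alns.items():
            lengths = {len(s) for s in aln.values()}
            assert len(lengths) == 1
            assert next(iter(lengths)) % 3 == 0


class TestAssemblyVariants:
    def test_requested_number_of_ambiguities(self, template_genome):
        genome, _ = template_genome
        primary, _, truth = make_assembly_variants(genome, n_ambiguities=2, seed=1)
        sites = mc.locate_ambiguities(primary)
        assert len(sites) == len(truth.ambiguities) == 2

    def test_codes_compatible_with_truth(self, template_genome):
        genome, _ = template_genome
        primary, _, truth = make_assembly_variants(genome, n_ambiguities=10, seed=2)
        for pos, code, true_base in truth.ambiguities:
            assert true_base in mc.genome.IUPAC_EXPANSION[code]
            assert primary.residues[pos - 1] == code

    def test_zero_ambiguities_is_truth(self, template_genome):
        genome, _ = template_genome
        primary, _, _ = make_assembly_variants(genome, n_ambiguities=0, seed=3)
        assert primary.residues == genome.record.residues

    def test_fragments_cover_every_site_with_context(self, template_genome):
        genome, _ = template_genome
        primary, alternates, truth = make_assembly_variants(
            genome, n_ambiguities=4, fragment_length=300, seed=4
        )
        fragmented = [a for a in alternates if isinstance(a, list)][0]
        corrected, report = mc.resolve_ambiguities(primary, [fragmented], flank=20)
        assert report.n_resolved == 4
        assert corrected.residues == genome.record.residues
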