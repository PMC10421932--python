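import numpy as np
import pytest

from conftest import random_peptide
from tfxkit import genefind, reference, synthgen
from tfxkit.formats import SequenceRecord
from tfxkit.genefind import (GeneFindError, SearchParams, build_synteny_map,
                             chain_hits_to_genes, compare_synteny,
                             find_exon_hits, local_align_protein,
                             sixframe_translate)


class TestSixFrame:
    def test_forward_frame_zero(self):
        frames = sixframe_translate(SequenceRecord("s", "ATGGCC"))
        fwd0 = [f for f in frames if f.strand == "+" and f.offset == 0][0]
        assert fwd0.peptide == "MA"

    def test_reverse_frame_zero(self):
        # revcomp of ATGGCC is GGCCAT -> "GH"
        frames = sixframe_translate(SequenceRecord("s", "ATGGCC"))
        rev0 = [f for f in frames if f.strand == "-" and f.offset == 0][0]
        assert rev0.peptide == "GH"

    def test_coordinate_map_forward(self):
        frames = sixframe_translate(SequenceRecord("s", "ATGGCCTTT"))
        fwd0 = [f for f in frames if f.strand == "+" and f.offset == 0][0]
        assert fwd0.scaffold_interval(1, 2) == (3, 6)

    def test_coordinate_map_reverse_round_trip(self):
        seq = "ATGGCCTTTAAACCC"
        frames = sixframe_translate(SequenceRecord("s", seq))
        rev1 = [f for f in frames if f.strand == "-" and f.offset == 1][0]
        s, e = rev1.scaffold_interval(0, 1)
        assert (e - s) == 3 and 0 <= s < e <= len(seq)

    def test_non_dna_rejected(self):
        with pytest.raises(GeneFindError, match="non-DNA"):
            sixframe_translate(SequenceRecord("s", "ATGU"))

    def test_n_translates_to_x(self):
        frames = sixframe_translate(SequenceRecord("s", "ATGNNN"))
        fwd0 = [f for f in frames if f.strand == "+" and f.offset == 0][0]
        assert fwd0.peptide == "MX"


class TestLocalAlign:
    def test_cysteine_pair_scores_eighteen(self):
        # BLOSUM62 C-C diagonal is 9
        assert local_align_protein("CC", "CC").score == 18

    def test_self_alignment_identity_one(self):
        res = local_align_protein("MKTWQR", "MKTWQR")
        assert res.identity == 1.0

    def test_empty_input_rejected(self):
        with pytest.raises(GeneFindError, match="empty"):
            local_align_protein("", "ACD")

    def test_scores_match_bruteforce_dp_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            q = random_peptide(rng, int(rng.integers(3, 31)))
            t = random_peptide(rng, int(rng.integers(3, 31)))
            assert local_align_protein(q, t).score == \
                pytest.approx(reference.sw_score_bruteforce(q, t))


class TestFindExonHits:
    def test_empty_panel_rejected(self, demo_genome):
        _, _, genome = demo_genome
        with pytest.raises(GeneFindError, match="panel"):
            find_exon_hits(genome.scaffolds[0], [])

    def test_implanted_exact_exon_recovered(self):
        """An undiverged implanted exon is hit at identity 1.0 with the
        exact truth interval, on either strand."""
        config = synthgen.default_genome_config(seed=13, divergence=0.0,
                                                n_pseudogenes=0,
                                                n_orphan_exon_sets=0,
                                                n_dup3_genes=0)
        family = synthgen.generate_protein_family(config.groups, seed=13)
        genome = synthgen.generate_genome(config, family)
        scaffold = genome.scaffolds[0]
        hits = find_exon_hits(scaffold, family.panel)
        truth = {(s, e): (g.strand, role)
                 for g in genome.genes for s, e, role in g.exons}
        found = 0
        for (s, e), (strand, role) in truth.items():
            matching = [h for h in hits if h.interval == (s, e)]
            if matching:
                found += 1
                assert matching[0].strand == strand
                assert matching[0].identity == 1.0
        assert found == len(truth)

    def test_random_dna_yields_no_hits_for_generic_query(self):
        """Empirical null: a generic 25-residue query finds nothing in
        uniform random DNA at default thresholds."""
        rng = np.random.default_rng(99)
        query = [SequenceRecord("null:E2", random_peptide(rng, 25))]
        total = 0
        for trial in range(25):
            dna = "".join(rng.choice(list("ACGT"), size=2000))
            scaffold = SequenceRecord(f"rand{trial}", dna)
            total += len(find_exon_hits(scaffold, query))
        assert total == 0


class TestChaining:
    def test_truth_chains_recovered(self, demo_genome, demo_recovery):
        _, _, genome = demo_genome
        _, models, report = demo_recovery
        assert report.exon_recovery >= 0.95
        assert report.status_accuracy == 1.0

    def test_dup3_flagged_five_prime_of_e3(self, demo_recovery):
        _, models, report = demo_recovery
        assert report.dup3_recovery == 1.0
        four = [m for m in models if "E3dup" in m.roles]
        for m in four:
            assert m.roles.index("E3dup") < m.roles.index("E3")

    def test_opposite_strands_never_chained(self, demo_recovery):
        _, models, _ = demo_recovery
        for m in models:
            assert len({h.strand for h in m.hits}) == 1

    def test_model_invariants_hold(self, demo_genome, demo_recovery):
        _, _, genome = demo_genome
        _, models, _ = demo_recovery
        n = len(genome.scaffolds[0].sequence)
        params = SearchParams()
        for m in models:
            coords = [iv for iv, _ in m.exons]
            if m.strand == "-":
                coords = coords[::-1]
            for (s1, e1), (s2, e2) in zip(coords, coords[1:]):
                assert e1 <= s2
                assert s2 - e1 <= params.max_intron_bp
            for (s, e), _ in m.exons:
                assert 0 <= s < e <= n

    def test_single_hits_become_orphan_models(self, demo_genome, demo_recovery):
        _, _, genome = demo_genome
        _, models, _ = demo_recovery
        orphan_truth = [g for g in genome.genes if g.status == "orphan_exon_set"]
        for g in orphan_truth:
            s, e, role = g.exons[0]
            match = [m for m in models
                     if m.exons[0][0] == (s, e) and len(m.exons) == 1]
            assert match and match[0].status == "orphan_exon_set"

    def test_intact_model_protein_equals_truth(self, demo_genome, demo_recovery):
        _, _, genome = demo_genome
        _, models, _ = demo_recovery
        by_span = {}
        for g in genome.genes:
            span = (min(s for s, _, _ in g.exons), max(e for _, e, _ in g.exons))
            by_span[span] = g
        matched = 0
        for m in models:
            g = by_span.get(m.span)
            if g is None or g.status != "intact":
                continue
            matched += 1
            assert m.protein == genome.proteins[g.protein_id].sequence
        assert matched >= 8


class TestStatusCalling:
    def test_exon_outside_scaffold_rejected(self):
        model = genefind.GeneModel("m", "s", "+", [((0, 60), "E1"), ((80, 140), "E2")])
        with pytest.raises(GeneFindError, match="bounds"):
            genefind.call_gene_status(model, "A" * 100)

    def test_stop_lesion_called_pseudogene(self, demo_genome, demo_recovery):
        _, _, genome = demo_genome
        _, models, _ = demo_recovery
        pseudo = [g for g in genome.genes if g.status == "pseudogene"]
        assert pseudo
        for g in pseudo:
            span = (min(s for s, _, _ in g.exons), max(e for _, e, _ in g.exons))
            match = [m for m in models if m.span == span]
            assert match and match[0].status == "pseudogene"


class TestSynteny:
    @staticmethod
    def _truth_map(genome, species):
        marker = [g for g in genome.genes if "marker" in g.orthogroup][0]
        return build_synteny_map(genome.genes, marker.orthogroup, species)

    def test_identical_species_tau_one(self, demo_genome):
        _, _, genome = demo_genome
        a = self._truth_map(genome, "A")
        b = self._truth_map(genome, "B")
        shared, tau = compare_synteny(a, b)
        assert shared == len(a.entries)
        assert tau == pytest.approx(1.0)

    def test_reversed_map_tau_minus_one(self, demo_genome):
        _, _, genome = demo_genome
        a = self._truth_map(genome, "A")
        reversed_entries = tuple(
            genefind.SyntenyEntry(e.gene_id, e.orthogroup,
                                  len(a.entries) - 1 - e.position, e.orientation)
            for e in a.entries)
        b = genefind.SyntenyMap("B", a.scaffold_id, a.anchor_gene_id,
                                reversed_entries)
        _, tau = compare_synteny(a, b)
        assert tau == pytest.approx(-1.0)

    def test_one_gene_loss_shares_n_minus_one(self):
        cfg_a = synthgen.default_genome_config("spA", seed=21)
        fam = synthgen.generate_protein_family(cfg_a.groups, seed=21,
                                               divergence=0.05)
        genome_a = synthgen.generate_genome(cfg_a, fam)
        lost = [g.orthogroup for g in genome_a.genes
                if g.status == "intact" and "marker" not in g.orthogroup][0]
        cfg_b = synthgen.default_genome_config(
            "spB", seed=21, drop_orthogroups=(lost,))
        genome_b = synthgen.generate_genome(cfg_b, fam)
        map_a = self._truth_map(genome_a, "spA")
        map_b = self._truth_map(genome_b, "spB")
        shared, _ = compare_synteny(map_a, map_b)
        # orphan placements are seed-local, so compare gene orthogroups
        genes_a = {e.orthogroup for e in map_a.entries if "orphan" not in e.orthogroup}
        genes_b = {e.orthogroup for e in map_b.entries if "orphan" not in e.orthogroup}
        assert genes_a - genes_b == {lost}

    def test_missing_marker_rejected(self, demo_genome):
        _, _, genome = demo_genome
        non_marker = [g for g in genome.genes if "marker" not in g.orthogroup]
        with pytest.raises(GeneFindError, match="marker"):
            build_synteny_map(non_marker, "og_marker_top1mt_0")
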