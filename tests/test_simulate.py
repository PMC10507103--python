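"""Generators: determinism, parameter fidelity, and truth self-consistency."""

import numpy as np
import pytest

from endosym import simulate
from endosym.io import write_fasta, write_gff
from endosym.simulate import CompositionSource, RearrangementOp


class TestCompositionSource:
    def test_rows_sum_to_one(self, symbiont_source):
        assert np.allclose(symbiont_source.markov.sum(axis=1), 1.0, atol=1e-9)

    def test_invalid_table_rejected(self):
        bad = np.full((64, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            CompositionSource(gc=0.25, markov=bad, label="x")

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            CompositionSource(gc=0.25, markov=np.ones((4, 4)) / 4, label="x")


class TestGenGenome:
    def test_gc_within_two_points(self, symbiont_source):
        g = simulate.gen_genome(symbiont_source, 100_000, seed=1)
        gc = (g.seq.count("G") + g.seq.count("C")) / len(g.seq)
        assert 0.23 <= gc <= 0.27

    def test_deterministic(self, symbiont_source):
        g1 = simulate.gen_genome(symbiont_source, 5_000, seed=5)
        g2 = simulate.gen_genome(symbiont_source, 5_000, seed=5)
        assert g1.seq == g2.seq

    def test_degenerate_all_a_table(self):
        markov = np.zeros((64, 4))
        markov[:, 0] = 1.0
        source = CompositionSource(gc=0.0, markov=markov, label="x")
        g = simulate.gen_genome(source, 1_000, seed=1)
        assert set(g.seq[3:]) == {"A"}  # after the order-3 burn-in

    def test_min_length_enforced(self, symbiont_source):
        with pytest.raises(ValueError):
            simulate.gen_genome(symbiont_source, 500, seed=1)


class TestGenMetagenome:
    def test_counts_and_truth(self):
        contigs, depths, truth = simulate.gen_metagenome(n_host=40, n_symb=8, seed=7)
        assert len(contigs) == 48
        assert sum(1 for v in truth.contig_labels.values() if v == "symbiont") == 8
        assert set(depths) == {c.id for c in contigs}

    def test_symbiont_depth_near_class_mean(self):
        contigs, depths, truth = simulate.gen_metagenome(
            n_host=40, n_symb=8, cov_host=60, cov_symb=300, seed=3)
        symb_depths = [depths[c] for c, l in truth.contig_labels.items()
                       if l == "symbiont"]
        assert 270 <= np.mean(symb_depths) <= 330

    def test_byte_identical_fasta(self, tmp_path):
        out1, out2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        for out in (out1, out2):
            contigs, _, _ = simulate.gen_metagenome(n_host=5, n_symb=2, seed=9)
            write_fasta(contigs, out)
        assert out1.read_bytes() == out2.read_bytes()

    def test_zero_contigs_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_metagenome(n_host=0, n_symb=0)


class TestGenReads:
    def test_read_count_arithmetic(self, symbiont_source):
        contig = simulate.gen_genome(symbiont_source, 10_000, seed=1, contig_id="c")
        reads, _ = simulate.gen_reads([contig], {"c": 10.0}, read_len=100, seed=1)
        assert len(reads) == 1000

    def test_error_free_reads_are_substrings(self, symbiont_source):
        contig = simulate.gen_genome(symbiont_source, 5_000, seed=2, contig_id="c")
        reads, _ = simulate.gen_reads([contig], {"c": 2.0}, read_len=80,
                                      error_rate=0.0, seed=2)
        rc = simulate.revcomp_seq(contig.seq)
        for read in reads:
            assert read.seq in contig.seq or read.seq in rc

    def test_error_rate_realized(self, symbiont_source):
        contig = simulate.gen_genome(symbiont_source, 10_000, seed=3, contig_id="c")
        reads, truth = simulate.gen_reads([contig], {"c": 10.0}, read_len=100,
                                          error_rate=0.01, seed=3)
        rc = simulate.revcomp_seq(contig.seq)
        mismatches = total = 0
        for read in reads[:100]:
            best = None
            for ref in (contig.seq, rc):
                for i in range(len(ref) - len(read.seq) + 1):
                    diff = sum(a != b for a, b in zip(read.seq, ref[i:i + 100]))
                    if best is None or diff < best:
                        best = diff
                    if best == 0:
                        break
            mismatches += best
            total += 100
        assert 0.008 <= mismatches / total <= 0.012

    def test_short_read_len_rejected(self, symbiont_source):
        contig = simulate.gen_genome(symbiont_source, 5_000, seed=1, contig_id="c")
        with pytest.raises(ValueError, match="read_len"):
            simulate.gen_reads([contig], {"c": 1.0}, read_len=20, k=31)

    def test_truth_tracks_origin(self, symbiont_source):
        contig = simulate.gen_genome(symbiont_source, 2_000, seed=1, contig_id="c")
        reads, truth = simulate.gen_reads([contig], {"c": 1.0}, read_len=100, seed=1)
        assert set(truth.read_origin.values()) == {"c"}
        assert set(truth.read_origin) == {r.id for r in reads}


class TestGenAnnotation:
    def test_class_fractions_within_one_point(self, symbiont_source):
        genome = simulate.gen_genome(symbiont_source, 300_000, seed=4, contig_id="g")
        annotation, _ = simulate.gen_annotation(
            genome, pseudo_frac=0.034, repeat_frac=0.041, seed=4)
        pseudo_bp = sum(r.length for r in annotation.by_class("pseudogene"))
        assert 0.024 * 300_000 <= pseudo_bp <= 0.044 * 300_000
        repeat_bp = sum(r.length for r in annotation.by_class("repeat"))
        assert 0.031 * 300_000 <= repeat_bp <= 0.051 * 300_000

    def test_all_zero_fractions_cds_only(self, small_genome):
        annotation, _ = simulate.gen_annotation(
            small_genome, pseudo_frac=0.0, repeat_frac=0.0, phage_frac=0.0, seed=1)
        assert {r.feature_class for r in annotation.records} == {"CDS"}

    def test_deterministic_gff_bytes(self, small_genome, tmp_path):
        for name in ("a.gff3", "b.gff3"):
            annotation, _ = simulate.gen_annotation(small_genome, seed=5)
            write_gff(annotation, tmp_path / name)
        assert (tmp_path / "a.gff3").read_bytes() == (tmp_path / "b.gff3").read_bytes()

    def test_infeasible_packing_rejected(self, small_genome):
        with pytest.raises(ValueError, match="infeasible"):
            simulate.gen_annotation(small_genome, gene_density=0.8,
                                    pseudo_frac=0.2, seed=1)

    def test_hypothetical_fraction_and_length_signal(self, small_annotation):
        annotation, _ = small_annotation
        cds = annotation.cds()
        hyp = [r for r in cds if r.product == "hypothetical protein"]
        ann = [r for r in cds if r.product != "hypothetical protein"]
        assert 0.35 <= len(hyp) / len(cds) <= 0.65
        assert np.mean([r.protein_length for r in ann]) > \
            1.2 * np.mean([r.protein_length for r in hyp])


class TestGenHgtHitTable:
    def test_exact_truth_positive_count(self, small_annotation):
        annotation, _ = small_annotation
        table, truth = simulate.gen_hgt_hit_table(annotation, 5, seed=1)
        assert len(truth.hgt_genes) == 5

    def test_positives_pass_brute_force_rule(self, small_annotation):
        annotation, _ = small_annotation
        table, truth = simulate.gen_hgt_hit_table(annotation, 8, seed=2)
        for gene_id in truth.hgt_genes:
            valid = [h for h in table.hits_for(gene_id)
                     if h.evalue < 1e-5 and h.qcov > 0.5]
            n_f = sum(1 for h in valid if h.subject_kingdom == "fungal")
            n_b = sum(1 for h in valid if h.subject_kingdom == "bacterial")
            if n_b > 0:
                assert n_f > 2 * n_b
            else:
                assert n_f >= 3
            # planted positives are never Glomeromycotina-only
            assert any("Glomeromycotina" not in h.subject_lineage
                       for h in valid if h.subject_kingdom == "fungal")

    def test_deterministic(self, small_annotation):
        annotation, _ = small_annotation
        t1, _ = simulate.gen_hgt_hit_table(annotation, 5, seed=3)
        t2, _ = simulate.gen_hgt_hit_table(annotation, 5, seed=3)
        assert t1 == t2

    def test_n_hgt_exceeding_cds_rejected(self, small_annotation):
        annotation, _ = small_annotation
        with pytest.raises(ValueError):
            simulate.gen_hgt_hit_table(annotation, len(annotation.cds()) + 1)

    def test_empty_pool_rejected(self, small_annotation):
        annotation, _ = small_annotation
        with pytest.raises(ValueError, match="taxa_pool"):
            simulate.gen_hgt_hit_table(annotation, 1, taxa_pool={"fungal": []})


class TestGenSyntenyPair:
    def test_no_ops_identity(self):
        a, b, blocks, _ = simulate.gen_synteny_pair(ancestor_len=20_000, ops=[],
                                                    seed=1)
        assert a.seq == b.seq
        assert blocks == [(0, 20_000, 0, 20_000, "+")]

    def test_single_inversion_geometry(self):
        op = RearrangementOp("inversion", 10_000, 20_000)
        a, b, blocks, _ = simulate.gen_synteny_pair(ancestor_len=50_000, ops=[op],
                                                    seed=3)
        assert len(blocks) == 3
        assert blocks[1] == (10_000, 20_000, 10_000, 20_000, "-")
        assert b.seq[10_000:20_000] == simulate.revcomp_seq(a.seq[10_000:20_000])

    def test_deletion(self):
        op = RearrangementOp("deletion", 5_000, 7_000)
        a, b, blocks, _ = simulate.gen_synteny_pair(ancestor_len=20_000, ops=[op],
                                                    seed=1)
        assert len(b.seq) == 18_000
        assert all(not (s < 7_000 and e > 5_000) or (s, e) == (0, 5_000)
                   for s, e, *_ in blocks)

    def test_random_inversions_match_interval_oracle(self):
        # brute-force oracle: breakpoints at op boundaries; count merged blocks
        for seed in (3, 4, 5):
            a, b, blocks, _ = simulate.gen_synteny_pair(
                ancestor_len=100_000, n_inv=5, seed=seed)
            # every base of the ancestor appears exactly once across blocks
            covered = sorted((s, e) for s, e, *_ in blocks)
            assert covered[0][0] == 0 and covered[-1][1] == 100_000
            for (s1, e1), (s2, e2) in zip(covered, covered[1:]):
                assert e1 == s2
            # B coordinates partition B likewise
            b_iv = sorted((bs, be) for _, _, bs, be, _ in blocks)
            assert b_iv[0][0] == 0 and b_iv[-1][1] == len(b.seq)
            # each block's sequence matches under its strand
            for s, e, bs, be, strand in blocks:
                if strand == "+":
                    assert b.seq[bs:be] == a.seq[s:e]
                else:
                    assert b.seq[bs:be] == simulate.revcomp_seq(a.seq[s:e])
            # 5 disjoint inversions cut the genome into at most 11 blocks
            assert len(blocks) <= 11

    def test_overlapping_ops_rejected(self):
        ops = [RearrangementOp("inversion", 1_000, 3_000),
               RearrangementOp("inversion", 2_000, 4_000)]
        with pytest.raises(ValueError, match="overlapping"):
            simulate.gen_synteny_pair(ancestor_len=10_000, ops=ops, seed=1)

    def test_translocation_blocks_match_sequence(self):
        op = RearrangementOp("translocation", 2_000, 4_000, destination=8_000)
        a, b, blocks, _ = simulate.gen_synteny_pair(ancestor_len=10_000, ops=[op],
                                                    seed=2)
        assert len(b.seq) == 10_000
        for s, e, bs, be, strand in blocks:
            assert b.seq[bs:be] == a.seq[s:e]


class TestGenTreePair:
    def test_congruent_pair_is_relabel(self):
        host, symb, assoc, truth = simulate.gen_tree_pair(8, congruent=True, seed=1)
        from endosym.cophylogeny import robinson_foulds
        rf, _ = robinson_foulds(host, symb, assoc)
        assert rf == 0
        assert truth.congruent is True

    def test_swaps_break_congruence(self):
        host, symb, assoc, _ = simulate.gen_tree_pair(8, congruent=False,
                                                      n_swaps=3, seed=2)
        from endosym.cophylogeny import robinson_foulds
        rf, _ = robinson_foulds(host, symb, assoc)
        assert rf > 0

    def test_deterministic_newick(self):
        t1 = simulate.gen_tree_pair(10, seed=5)
        t2 = simulate.gen_tree_pair(10, seed=5)
        assert t1[0].as_string(schema="newick") == t2[0].as_string(schema="newick")
        assert t1[1].as_string(schema="newick") == t2[1].as_string(schema="newick")

    def test_congruent_with_swaps_rejected(self):
        with pytest.raises(ValueError):
            simulate.gen_tree_pair(8, congruent=True, n_swaps=2)

    def test_min_leaves(self):
        with pytest.raises(ValueError):
            simulate.gen_tree_pair(3)
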