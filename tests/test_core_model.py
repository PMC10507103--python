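"""Domain types, config, and round-trip properties of every reader/writer."""

import numpy as np
import pytest

from endosym.config import Config
from endosym.io import (
    parse_association,
    parse_depth_table,
    parse_fasta,
    parse_gff,
    parse_hit_table,
    parse_newick,
    parse_newick_string,
    write_association,
    write_depth_table,
    write_fasta,
    write_gff,
    write_hit_table,
    write_newick,
)
from endosym.model import (
    AnnotationSet,
    Association,
    Contig,
    GeneRecord,
    HitRecord,
    HitTable,
)


class TestContig:
    def test_empty_id_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            Contig(id="", seq="ACGT")

    def test_empty_seq_rejected(self):
        with pytest.raises(ValueError):
            Contig(id="a", seq="")

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            Contig(id="a", seq="ACGT", depth=-1.0)

    def test_bad_truth_rejected(self):
        with pytest.raises(ValueError):
            Contig(id="a", seq="ACGT", truth="fungus")


class TestGeneRecord:
    def test_interval_must_be_half_open(self):
        with pytest.raises(ValueError):
            GeneRecord("g", "c", 10, 10, "+", "CDS", protein_length=5)

    def test_cds_requires_protein_length(self):
        with pytest.raises(ValueError, match="protein_length"):
            GeneRecord("g", "c", 0, 300, "+", "CDS")

    def test_non_cds_rejects_protein_length(self):
        with pytest.raises(ValueError):
            GeneRecord("g", "c", 0, 300, "+", "repeat", protein_length=10)

    def test_annotation_set_checks_contig_bounds(self):
        rec = GeneRecord("g", "c", 0, 500, "+", "CDS", protein_length=100)
        with pytest.raises(ValueError, match="extends past"):
            AnnotationSet("G", [rec], 400, {"c": 400})

    def test_annotation_set_checks_unknown_contig(self):
        rec = GeneRecord("g", "other", 0, 100, "+", "CDS", protein_length=10)
        with pytest.raises(ValueError, match="unknown contig"):
            AnnotationSet("G", [rec], 400, {"c": 400})


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n")
        contigs = parse_fasta(p)
        assert len(contigs) == 1
        assert contigs[0].id == "a"
        assert len(contigs[0]) == 4

    def test_uppercase_and_n(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nacgt\n>b\nNNNN\n")
        contigs = parse_fasta(p)
        assert [c.id for c in contigs] == ["a", "b"]
        assert contigs[0].seq == "ACGT"

    def test_non_acgtn_replaced(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACRYGT\n")
        assert parse_fasta(p)[0].seq == "ACNNGT"

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(ValueError, match="no records"):
            parse_fasta(p)

    def test_duplicate_id_errors(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(ValueError, match="a"):
            parse_fasta(p)

    def test_round_trip_100_random_contigs(self, tmp_path):
        rng = np.random.default_rng(42)
        contigs = [
            Contig(id=f"c{i}", seq="".join(rng.choice(list("ACGTN"),
                                                      size=rng.integers(1, 400))))
            for i in range(100)
        ]
        p = tmp_path / "rt.fasta"
        write_fasta(contigs, p)
        back = parse_fasta(p)
        assert [c.id for c in back] == [c.id for c in contigs]
        assert [c.seq for c in back] == [c.seq for c in contigs]


class TestGff:
    def test_coordinate_convention(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "c\tsrc\tCDS\t1\t300\t.\t+\t.\tID=g1;product=thing;protein_length=99\n"
        )
        annotation = parse_gff(p, {"c": 1000})
        rec = annotation.records[0]
        assert (rec.start, rec.end) == (0, 300)
        assert rec.protein_length == 99

    def test_default_product(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("c\tsrc\tCDS\t1\t300\t.\t+\t.\tID=g1\n")
        assert parse_gff(p, {"c": 1000}).records[0].product == "hypothetical protein"

    def test_feature_past_contig_end_errors(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("c\tsrc\tCDS\t1\t300\t.\t+\t.\tID=g1\n")
        with pytest.raises(ValueError, match="extends past"):
            parse_gff(p, {"c": 100})

    def test_unknown_contig_errors(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text("zzz\tsrc\tCDS\t1\t60\t.\t+\t.\tID=g1\n")
        with pytest.raises(ValueError, match="unknown contig"):
            parse_gff(p, {"c": 100})

    def test_round_trip_50_genes(self, tmp_path):
        rng = np.random.default_rng(7)
        records = []
        pos = 0
        for i in range(50):
            pos += int(rng.integers(1, 50))
            length = int(rng.integers(1, 100)) * 3
            cls = ["CDS", "pseudogene", "repeat", "phage"][int(rng.integers(4))]
            records.append(GeneRecord(
                gene_id=f"g{i}", contig_id="c", start=pos, end=pos + length,
                strand="+" if rng.random() < 0.5 else "-", feature_class=cls,
                product=f"product {i}",
                protein_length=length // 3 if cls == "CDS" else None,
            ))
            pos += length
        annotation = AnnotationSet("G", records, 20_000, {"c": 20_000})
        p = tmp_path / "rt.gff3"
        write_gff(annotation, p)
        back = parse_gff(p, {"c": 20_000}, genome_id="G")
        assert back.records == annotation.records

    def test_double_conversion_is_identity(self, tmp_path):
        # disk(1-based) -> memory(0-based) -> disk must reproduce the line
        p = tmp_path / "a.gff3"
        line = "c\tendosym\tCDS\t17\t316\t.\t-\t.\tID=g1;product=x;protein_length=99"
        p.write_text(line + "\n")
        annotation = parse_gff(p, {"c": 1000}, genome_id="G")
        out = tmp_path / "b.gff3"
        write_gff(annotation, out)
        body = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert body == [line]


class TestHitTable:
    def _table(self):
        return HitTable([
            HitRecord("q1", "s1", "fungal", ["Fungi", "Mucoromycota"],
                      1e-20, 0.6, 55.0, 60),
            HitRecord("q1", "s2", "bacterial", ["Bacteria"], 1e-10, 0.9, 40.0, 90),
            HitRecord("q2", "s3", "viral", ["Viruses"], 1e-8, 0.5, 80.0, 50),
        ])

    def test_qcov_computed_from_alnlen(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q\ts\t50.0\t60\t0\t0\t1\t60\t1\t60\t1e-10\t100\tfungal\tFungi\t100\n")
        table = parse_hit_table(p)
        assert table.hits_for("q")[0].qcov == pytest.approx(0.60)

    def test_empty_file_empty_table(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("")
        assert len(parse_hit_table(p)) == 0

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q\ts\t50.0\t60\n")
        with pytest.raises(ValueError, match=":1"):
            parse_hit_table(p)

    def test_negative_evalue_errors(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text("q\ts\t50.0\t60\t0\t0\t1\t60\t1\t60\t-1e-10\t100\tfungal\tFungi\t100\n")
        with pytest.raises(ValueError, match="negative evalue"):
            parse_hit_table(p)

    def test_round_trip_1000_rows(self, tmp_path):
        rng = np.random.default_rng(3)
        kingdoms = ["fungal", "bacterial", "archaeal", "viral", "other"]
        hits = []
        for i in range(1000):
            qlen = int(rng.integers(50, 500))
            aln = int(rng.integers(1, qlen + 1))
            hits.append(HitRecord(
                query_id=f"q{int(rng.integers(0, 50))}",
                subject_id=f"s{i}",
                subject_kingdom=kingdoms[int(rng.integers(5))],
                subject_lineage=["L1", f"L{int(rng.integers(10))}"],
                evalue=float(10.0 ** rng.uniform(-50, 0)),
                qcov=aln / qlen,
                pct_identity=float(np.round(rng.uniform(20, 100), 3)),
                aln_len=aln,
            ))
        table = HitTable(hits)
        p = tmp_path / "rt.tsv"
        write_hit_table(table, p)
        back = parse_hit_table(p)
        assert len(back) == len(table)
        for q in table.queries():
            for h1, h2 in zip(table.hits_for(q), back.hits_for(q)):
                assert h1.subject_id == h2.subject_id
                assert h1.subject_kingdom == h2.subject_kingdom
                assert h1.subject_lineage == h2.subject_lineage
                assert h1.aln_len == h2.aln_len
                assert h1.qcov == pytest.approx(h2.qcov, abs=1e-9)
                assert h1.evalue == pytest.approx(h2.evalue, rel=1e-2)


class TestNewick:
    def test_four_leaves_one_split(self):
        tree = parse_newick_string("(A,B,(C,D));")
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        assert sorted(leaves) == ["A", "B", "C", "D"]
        internal = [n for n in tree.preorder_node_iter()
                    if not n.is_leaf() and n.parent_node is not None]
        assert len(internal) == 1

    def test_round_trip_branch_lengths(self, tmp_path):
        newick = "((A:0.123456789,B:0.2):0.05,(C:1.5,D:2.25):0.1);"
        tree = parse_newick_string(newick)
        p = tmp_path / "t.nwk"
        write_newick(tree, p)
        back = parse_newick(p)
        lengths = sorted(e.length for e in back.preorder_edge_iter()
                         if e.length is not None)
        expected = sorted(e.length for e in tree.preorder_edge_iter()
                          if e.length is not None)
        assert lengths == pytest.approx(expected, abs=1e-9)

    def test_unbalanced_parens_error(self):
        with pytest.raises(ValueError, match="parse error"):
            parse_newick_string("((A,B);")

    def test_single_child_collapses(self):
        # documented choice: degenerate single-child nesting is accepted and
        # collapses to the same leaf set
        tree = parse_newick_string("(A,(B));")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == ["A", "B"]


class TestDepthAndAssociation:
    def test_depth_round_trip(self, tmp_path):
        depths = {"c1": 60.5, "c2": 300.25}
        p = tmp_path / "d.tsv"
        write_depth_table(depths, p)
        assert parse_depth_table(p) == depths

    def test_negative_depth_errors(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("c1\t-5\n")
        with pytest.raises(ValueError):
            parse_depth_table(p)

    def test_association_round_trip(self, tmp_path):
        assoc = Association([("H1", "S1"), ("H1", "S2"), ("H2", "S3")])
        p = tmp_path / "a.tsv"
        write_association(assoc, p)
        assert parse_association(p).pairs == assoc.pairs


class TestConfig:
    def test_defaults_match_documented_thresholds(self):
        config = Config()
        assert config.hgt_e_max == 1e-5
        assert config.hgt_qcov_min == 0.50
        assert config.hgt_ratio == 2.0
        assert config.recruit_k == 31
        assert config.recruit_mkf == 0.05
        assert config.anchor_min_aa == 6
        assert config.chain_max_gap_aa == 30

    def test_file_round_trip(self, tmp_path):
        config = Config(hgt_ratio=3.0, recruit_k=21, rng_seed=99)
        p = tmp_path / "c.cfg"
        config.to_file(p)
        assert Config.from_file(p) == config

    def test_hash_changes_with_values(self):
        assert Config().hash() != Config(hgt_ratio=3.0).hash()

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            Config(recruit_k=0)

    def test_unknown_key_rejected(self, tmp_path):
        p = tmp_path / "c.cfg"
        p.write_text("bogus=1\n")
        with pytest.raises(ValueError, match="unknown config key"):
            Config.from_file(p)
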