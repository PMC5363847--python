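"""Genome model: annotation parsing and the exclusive feature partition."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nucscan import (FEATURE_LABELS, GeneAnnotation, GeneRecord,
                     GenomeAssembly, compute_genome_ratios,
                     derive_feature_partition, load_annotation)

from conftest import mirror_annotation, mirror_genome


def _write(tmp_path, text, name="ann.genePred"):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestLoadAnnotation:
    def test_empty_file(self, tmp_path):
        ann = load_annotation(_write(tmp_path, ""))
        assert len(ann) == 0

    def test_single_record_fields(self, tmp_path):
        line = "geneA chr1 + 1000 2000 1200 1800 2 1000,1500 1300,2000\n"
        ann = load_annotation(_write(tmp_path, line))
        (rec,) = ann.records
        assert rec.tss == 1000
        assert rec.exons == ((1000, 1300), (1500, 2000))
        assert rec.coding

    def test_minus_strand_tss_is_last_covered_base(self, tmp_path):
        line = "g chr1 - 1000 2000 1000 2000 1 1000, 2000,\n"
        ann = load_annotation(_write(tmp_path, line))
        assert ann.records[0].tss == 1999

    def test_malformed_line_names_line_number(self, tmp_path):
        path = _write(tmp_path, "g chr1 + 0 100 0 100 1 0, 100,\n"
                                "broken line without coordinates\n")
        with pytest.raises(ValueError, match="line 2"):
            load_annotation(path)

    def test_inverted_tx_bounds_dropped_with_warning(self, tmp_path, caplog):
        path = _write(tmp_path, "g chr1 + 2000 1000 2000 1000 1 2000, 1000,\n")
        with caplog.at_level("WARNING"):
            ann = load_annotation(path)
        assert len(ann) == 0
        assert "txStart >= txEnd" in caplog.text

    def test_unknown_chromosome_dropped(self, tmp_path, worked_genome, caplog):
        path = _write(tmp_path, "g chrZ + 100 200 100 200 1 100, 200,\n")
        with caplog.at_level("WARNING"):
            ann = load_annotation(path, worked_genome)
        assert len(ann) == 0
        assert "absent from genome" in caplog.text

    def test_roundtrip_through_writer(self, tmp_path, worked_gene):
        path = tmp_path / "rt.genePred"
        GeneAnnotation([worked_gene]).write_genepred(path)
        assert load_annotation(path).records == [worked_gene]


class TestFeaturePartition:
    def test_no_genes_single_intergenic_interval(self, worked_genome):
        part = derive_feature_partition(GeneAnnotation([]), worked_genome)
        starts, ends, codes = part.intervals("chr1")
        assert list(starts) == [0] and list(ends) == [10_000]
        assert FEATURE_LABELS[codes[0]] == "intergenic"

    def test_worked_example_base_counts(self, worked_partition):
        # hand tiling: promoter [1000,2000), utr5 exonic [2000,2500),
        # exon CDS-exonic [2500,3000)+[4000,4500), intron [3000,4000),
        # utr3 exonic [4500,5000), intergenic elsewhere
        counts = worked_partition.base_counts()
        assert counts == {"promoter": 1000, "utr5": 500, "exon": 1000,
                          "intron": 1000, "utr3": 500, "intergenic": 6000}
        assert sum(counts.values()) == 10_000

    def test_promoter_clipped_at_chromosome_start(self, worked_genome):
        rec = GeneRecord("g", "chr1", "+", 300, 1500, 300, 1500, ((300, 1500),))
        part = derive_feature_partition(GeneAnnotation([rec]), worked_genome, 1000)
        assert part.base_counts()["promoter"] == 300

    def test_noncoding_transcript_all_exon_no_utrs(self, worked_genome):
        rec = GeneRecord("g", "chr1", "+", 2000, 3000, 2500, 2500, ((2000, 3000),))
        counts = derive_feature_partition(
            GeneAnnotation([rec]), worked_genome).base_counts()
        assert counts["exon"] == 1000 and counts["utr5"] == 0 and counts["utr3"] == 0

    def test_promoter_takes_precedence_over_neighbour_exon(self, worked_genome):
        # gene B's promoter overlaps gene A's exon; promoter wins per base
        a = GeneRecord("a", "chr1", "+", 2000, 3000, 2000, 3000, ((2000, 3000),))
        b = GeneRecord("b", "chr1", "+", 3500, 4500, 3500, 4500, ((3500, 4500),))
        counts = derive_feature_partition(
            GeneAnnotation([a, b]), worked_genome, 1000).base_counts()
        assert counts["promoter"] == 2000  # [1000,2000) + [2500,3500)
        assert counts["exon"] == 1500      # gene A loses [2500,3000)

    def test_record_order_never_changes_partition(self, worked_genome):
        a = GeneRecord("a", "chr1", "+", 2000, 3000, 2000, 3000, ((2000, 3000),))
        b = GeneRecord("b", "chr1", "-", 2500, 3500, 2500, 3500, ((2500, 3500),))
        p1 = derive_feature_partition(GeneAnnotation([a, b]), worked_genome)
        p2 = derive_feature_partition(GeneAnnotation([b, a]), worked_genome)
        for (s1, e1, c1), (s2, e2, c2) in [(p1.intervals("chr1"), p2.intervals("chr1"))]:
            assert (s1 == s2).all() and (e1 == e2).all() and (c1 == c2).all()

    def test_mirror_and_strand_flip_mirrors_partition(self, worked_genome,
                                                      worked_gene):
        L = 10_000
        fwd = derive_feature_partition(
            GeneAnnotation([worked_gene]), worked_genome, 1000)
        rev = derive_feature_partition(
            mirror_annotation(GeneAnnotation([worked_gene]), L),
            mirror_genome(worked_genome), 1000)
        s, e, c = fwd.intervals("chr1")
        ms, me, mc = rev.intervals("chr1")
        assert (ms == (L - e)[::-1]).all()
        assert (me == (L - s)[::-1]).all()
        assert (mc == c[::-1]).all()

    @given(st.lists(st.tuples(st.integers(0, 9_000), st.integers(100, 900),
                              st.booleans()), max_size=8))
    def test_base_count_conservation(self, worked_genome, genes):
        records = []
        for i, (start, span, plus) in enumerate(genes):
            end = min(start + span, 10_000)
            if end - start < 10:
                continue
            records.append(GeneRecord(f"g{i}", "chr1", "+" if plus else "-",
                                      start, end, start, end, ((start, end),)))
        part = derive_feature_partition(GeneAnnotation(records), worked_genome)
        assert sum(part.base_counts().values()) == 10_000


class TestGenomeRatios:
    def test_all_intergenic(self, worked_genome):
        part = derive_feature_partition(GeneAnnotation([]), worked_genome)
        table = compute_genome_ratios(part).set_index("label")["percent"]
        assert table["intergenic"] == 100.0
        assert table.drop("intergenic").eq(0).all()

    def test_worked_example_percentages(self, worked_partition):
        table = compute_genome_ratios(worked_partition).set_index("label")["percent"]
        expected = {"promoter": 10, "utr5": 5, "exon": 10, "intron": 10,
                    "utr3": 5, "intergenic": 60}
        for label, pct in expected.items():
            assert table[label] == pytest.approx(pct)
        assert table.sum() == pytest.approx(100.0)

    def test_two_identical_chromosomes_same_ratios(self, worked_gene):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=10_000))
        g1 = GenomeAssembly(sequences={"chr1": seq})
        g2 = GenomeAssembly(sequences={"chr1": seq, "chr2": seq})
        ann1 = GeneAnnotation([worked_gene])
        rec2 = GeneRecord("geneB", "chr2", worked_gene.strand,
                          worked_gene.tx_start, worked_gene.tx_end,
                          worked_gene.cds_start, worked_gene.cds_end,
                          worked_gene.exons)
        ann2 = GeneAnnotation([worked_gene, rec2])
        r1 = compute_genome_ratios(derive_feature_partition(ann1, g1))
        r2 = compute_genome_ratios(derive_feature_partition(ann2, g2))
        assert np.allclose(r1["percent"], r2["percent"])
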