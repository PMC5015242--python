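"""Gene-model reading, interval queries, promoter windows and positional
classification of lncRNAs."""

from __future__ import annotations

import numpy as np
import pytest

from lncscreen.annotation import (
    AnnotationSet,
    classify_lnc_position,
    mature_length,
    nearest_coding_partners,
    promoter_window,
)
from lncscreen.gtfio import GtfParseError, read_gtf, write_gtf
from lncscreen.models import BiotypeTaxonomy, GeneModel, GenomicInterval

from conftest import make_gene


class TestGtfReading:
    def test_header_only_file_gives_empty_annotation(self, tmp_path):
        path = tmp_path / "empty.gtf"
        path.write_text("# just a header\n")
        assert len(read_gtf(path)) == 0

    def test_two_gene_fixture_matches_hand_conversion(self, two_gene_gtf):
        annot = read_gtf(two_gene_gtf)
        assert len(annot) == 2
        a = annot["GENEA"]
        # 1-based inclusive 1001..3000 -> 0-based half-open [1000, 3000)
        assert (a.span.start, a.span.end, a.strand) == (1000, 3000, "+")
        assert a.biotype == "protein_coding"
        assert [(e.start, e.end) for e in a.exons] == [(1000, 1400), (2600, 3000)]
        b = annot["GENEB"]
        assert (b.span.start, b.span.end, b.strand) == (5000, 6000, "-")
        assert b.biotype == "lincRNA"
        assert b.tss == 5999

    def test_antisense_trio_has_662_nt_three_exon_lnc(self, antisense_trio_gtf):
        annot = read_gtf(antisense_trio_gtf)
        lnc = annot["LNC1"]
        assert len(lnc.exons) == 3
        assert mature_length(lnc) == 662

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gtf"
        path.write_text('chr1\tx\tgene\t1\t100\t.\t+\t.\tgene_id "G"; gene_type "protein_coding";\nnot-a-gtf-line\n')
        with pytest.raises(GtfParseError, match="line 2"):
            read_gtf(path)

    def test_unknown_biotype_errors_without_fallback(self, tmp_path):
        path = tmp_path / "odd.gtf"
        path.write_text('chr1\tx\tgene\t1\t100\t.\t+\t.\tgene_id "G"; gene_type "vault_RNA";\n')
        with pytest.raises(GtfParseError, match="vault_RNA"):
            read_gtf(path)
        annot = read_gtf(path, BiotypeTaxonomy(fallback="miscRNA"))
        assert annot["G"].biotype == "miscRNA"

    def test_gene_biotype_attribute_accepted_as_synonym(self, tmp_path):
        path = tmp_path / "syn.gtf"
        path.write_text('chr1\tx\tgene\t1\t100\t.\t+\t.\tgene_id "G"; gene_biotype "antisense";\n')
        assert read_gtf(path)["G"].biotype == "antisense"

    def test_exon_outside_gene_span_is_a_validation_error(self, tmp_path):
        path = tmp_path / "bad_exon.gtf"
        path.write_text(
            'chr1\tx\tgene\t100\t200\t.\t+\t.\tgene_id "G"; gene_type "protein_coding";\n'
            'chr1\tx\texon\t150\t300\t.\t+\t.\tgene_id "G"; gene_type "protein_coding";\n'
        )
        with pytest.raises(ValueError, match="outside"):
            read_gtf(path)

    def test_round_trip_preserves_models(self, antisense_trio_gtf, tmp_path):
        annot = read_gtf(antisense_trio_gtf)
        out = tmp_path / "rt.gtf"
        write_gtf(annot, out)
        again = read_gtf(out)
        assert len(again) == len(annot)
        for gene in annot:
            other = again[gene.gene_id]
            assert other.span == gene.span
            assert other.exons == gene.exons
            assert other.biotype == gene.biotype
            assert other.gene_name == gene.gene_name


class TestGeneModel:
    def test_mature_length_examples(self):
        g = make_gene("G", "chr1", 0, 100)
        assert mature_length(g) == 100
        g2 = make_gene("G2", "chr1", 0, 35, exons=[(0, 10), (20, 35)])
        assert mature_length(g2) == 25

    def test_invalid_strand_rejected(self):
        with pytest.raises(ValueError, match="strand"):
            GenomicInterval("chr1", 0, 10, ".")

    def test_tss_follows_strand(self):
        assert make_gene("G", "chr1", 100, 200, "+").tss == 100
        assert make_gene("G", "chr1", 100, 200, "-").tss == 199


class TestPromoterWindow:
    def test_plus_strand_window_is_upstream(self):
        g = make_gene("G", "chr1", 100_000, 105_000, "+")
        w = promoter_window(g)
        assert (w.start, w.end) == (90_000, 100_000)

    def test_minus_strand_window_is_upstream(self):
        g = make_gene("G", "chr1", 45_000, 50_000, "-")
        w = promoter_window(g)
        assert (w.start, w.end) == (50_000, 60_000)

    def test_clipped_at_chromosome_origin(self):
        g = make_gene("G", "chr1", 4_000, 6_000, "+")
        w = promoter_window(g)
        assert (w.start, w.end) == (0, 4_000)
        assert len(w) == 4_000

    def test_window_never_overlaps_gene_body(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            start = int(rng.integers(0, 50_000))
            length = int(rng.integers(500, 20_000))
            strand = "+" if rng.integers(2) == 0 else "-"
            g = make_gene("G", "chr1", start, start + length, strand)
            w = promoter_window(g, width=10_000)
            if w is None:
                assert strand == "+" and start == 0
                continue
            assert not w.overlaps(g.span)
            expected = min(10_000, g.tss) if strand == "+" else 10_000
            assert len(w) == expected


class TestClassification:
    def test_antisense_trio_classifies_as_antisense(self, antisense_trio_gtf):
        annot = read_gtf(antisense_trio_gtf)
        assert classify_lnc_position(annot["LNC1"], annot) == "antisense"
        partners = nearest_coding_partners(annot["LNC1"], annot)
        assert {g.gene_id for g in partners} == {"CODE1", "CODE2"}

    def test_no_overlap_is_lincRNA(self):
        annot = AnnotationSet(
            [
                make_gene("C", "chr1", 0, 5_000),
                make_gene("L", "chr1", 20_000, 21_000, biotype="lincRNA"),
            ]
        )
        assert classify_lnc_position(annot["L"], annot) == "lincRNA"

    def test_sense_intronic_inside_coding_intron(self):
        coding = make_gene("C", "chr1", 0, 10_000, exons=[(0, 1_000), (9_000, 10_000)])
        lnc = make_gene("L", "chr1", 3_000, 4_000, biotype="sense_intronic")
        annot = AnnotationSet([coding, lnc])
        assert classify_lnc_position(lnc, annot) == "sense_intronic"

    def test_sense_overlapping_coding_inside_lnc_intron(self):
        lnc = make_gene(
            "L", "chr1", 0, 20_000, biotype="sense_overlapping",
            exons=[(0, 500), (19_000, 20_000)],
        )
        coding = make_gene("C", "chr1", 5_000, 9_000)
        annot = AnnotationSet([lnc, coding])
        assert classify_lnc_position(lnc, annot) == "sense_overlapping"

    def test_opposite_strand_overlap_wins_precedence(self):
        coding = make_gene("C", "chr1", 0, 10_000, "-")
        lnc = make_gene("L", "chr1", 2_000, 3_000, "+", biotype="antisense")
        annot = AnnotationSet([coding, lnc])
        assert classify_lnc_position(lnc, annot) == "antisense"


class TestNearest:
    def test_closer_gene_wins(self):
        annot = AnnotationSet(
            [
                make_gene("LEFT", "chr1", 0, 9_000),
                make_gene("RIGHT", "chr1", 16_000, 20_000),
                make_gene("L", "chr1", 10_000, 11_000, biotype="lincRNA"),
            ]
        )
        partners = nearest_coding_partners(annot["L"], annot)
        assert [g.gene_id for g in partners] == ["LEFT"]

    def test_equidistant_tie_returns_both(self):
        annot = AnnotationSet(
            [
                make_gene("LEFT", "chr1", 0, 8_000),
                make_gene("RIGHT", "chr1", 13_000, 20_000),
                make_gene("L", "chr1", 10_000, 11_000, biotype="lincRNA"),
            ]
        )
        partners = nearest_coding_partners(annot["L"], annot)
        assert [g.gene_id for g in partners] == ["LEFT", "RIGHT"]

    def test_no_coding_gene_on_chromosome(self):
        annot = AnnotationSet([make_gene("L", "chr1", 0, 1_000, biotype="lincRNA")])
        assert nearest_coding_partners(annot["L"], annot) == []


def _random_annotation(rng: np.random.Generator, n: int) -> AnnotationSet:
    genes = []
    for i in range(n):
        start = int(rng.integers(0, 500_000))
        length = int(rng.integers(100, 20_000))
        strand = "+" if rng.integers(2) == 0 else "-"
        biotype = rng.choice(["protein_coding", "lincRNA", "antisense", "pseudogene"])
        chrom = f"chr{int(rng.integers(1, 4))}"
        genes.append(make_gene(f"G{i:04d}", chrom, start, start + length, strand, str(biotype)))
    return AnnotationSet(genes)


class TestIndexAgainstLinearScan:
    """The interval index must agree with a brute-force scan."""

    def test_overlap_and_nearest_queries(self):
        rng = np.random.default_rng(42)
        for trial in range(5):
            annot = _random_annotation(rng, int(rng.integers(50, 500)))
            genes = list(annot)
            for _ in range(40):
                start = int(rng.integers(0, 500_000))
                end = start + int(rng.integers(1, 30_000))
                chrom = f"chr{int(rng.integers(1, 4))}"
                query = GenomicInterval(chrom, start, end, "+")
                expected = sorted(
                    (g.gene_id for g in genes if g.span.overlaps(query))
                )
                got = sorted(g.gene_id for g in annot.overlapping(query))
                assert got == expected
                # nearest among coding genes
                coding = [g for g in genes if g.biotype == "protein_coding" and g.chrom == chrom]
                got_near, got_gap = annot.nearest(query, coding_only=True)
                if not coding:
                    assert (got_near, got_gap) == ([], -1)
                    continue
                gaps = {g.gene_id: g.span.gap_to(query) for g in coding}
                best = min(gaps.values())
                assert got_gap == best
                assert sorted(g.gene_id for g in got_near) == sorted(
                    gid for gid, gap in gaps.items() if gap == best
                )

    def test_lincRNA_iff_no_overlapping_coding_partner(self):
        rng = np.random.default_rng(7)
        annot = _random_annotation(rng, 300)
        for gene in annot:
            if gene.biotype not in ("lincRNA", "antisense"):
                continue
            cls = classify_lnc_position(gene, annot)
            partners = nearest_coding_partners(gene, annot)
            has_overlap = any(g.span.overlaps(gene.span) for g in partners)
            assert (cls == "lincRNA") == (not has_overlap)
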