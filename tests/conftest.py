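"""Shared fixtures: hand-written GTF text and small synthetic configs."""

from __future__ import annotations

import pytest

from lncscreen.models import GeneModel, GenomicInterval
from lncscreen.synthetic import PlantedDE, PlantedPair, SyntheticConfig


def make_gene(
    gene_id: str,
    chrom: str,
    start: int,
    end: int,
    strand: str = "+",
    biotype: str = "protein_coding",
    exons: list[tuple[int, int]] | None = None,
) -> GeneModel:
    """Convenience constructor; defaults to a single full-span exon."""
    exon_bounds = exons if exons is not None else [(start, end)]
    return GeneModel(
        gene_id=gene_id,
        gene_name=gene_id,
        biotype=biotype,
        span=GenomicInterval(chrom, start, end, strand),
        exons=[GenomicInterval(chrom, a, b, strand) for a, b in exon_bounds],
    )


# Hand-written 2-gene, 3-exon GTF (1-based inclusive on disk). GeneA spans
# 1001..3000 with exons 1001..1400 and 2601..3000; GeneB is a minus-strand
# lincRNA with one exon.
TWO_GENE_GTF = """\
# hand-written fixture
chr1\ttest\tgene\t1001\t3000\t.\t+\t.\tgene_id "GENEA"; gene_type "protein_coding"; gene_name "GeneA";
chr1\ttest\texon\t1001\t1400\t.\t+\t.\tgene_id "GENEA"; gene_type "protein_coding"; gene_name "GeneA";
chr1\ttest\texon\t2601\t3000\t.\t+\t.\tgene_id "GENEA"; gene_type "protein_coding"; gene_name "GeneA";
chr1\ttest\tgene\t5001\t6000\t.\t-\t.\tgene_id "GENEB"; gene_type "lincRNA"; gene_name "GeneB";
chr1\ttest\texon\t5001\t6000\t.\t-\t.\tgene_id "GENEB"; gene_type "lincRNA"; gene_name "GeneB";
"""

# An antisense lncRNA modelled on a 662-nt three-exon transcript that
# overlaps two protein-coding genes on the opposite strand (first exon in
# the first coding gene's intron, last exon over the second coding gene's
# second exon). Coordinates are synthetic.
ANTISENSE_TRIO_GTF = """\
chr1\ttest\tgene\t10001\t18000\t.\t-\t.\tgene_id "CODE1"; gene_type "protein_coding"; gene_name "Optc-like";
chr1\ttest\texon\t10001\t10500\t.\t-\t.\tgene_id "CODE1"; gene_type "protein_coding"; gene_name "Optc-like";
chr1\ttest\texon\t17001\t18000\t.\t-\t.\tgene_id "CODE1"; gene_type "protein_coding"; gene_name "Optc-like";
chr1\ttest\tgene\t20001\t28000\t.\t-\t.\tgene_id "CODE2"; gene_type "protein_coding"; gene_name "Prelp-like";
chr1\ttest\texon\t20001\t20500\t.\t-\t.\tgene_id "CODE2"; gene_type "protein_coding"; gene_name "Prelp-like";
chr1\ttest\texon\t23001\t23600\t.\t-\t.\tgene_id "CODE2"; gene_type "protein_coding"; gene_name "Prelp-like";
chr1\ttest\texon\t27001\t28000\t.\t-\t.\tgene_id "CODE2"; gene_type "protein_coding"; gene_name "Prelp-like";
chr1\ttest\tgene\t12001\t23300\t.\t+\t.\tgene_id "LNC1"; gene_type "antisense"; gene_name "Gm-like";
chr1\ttest\texon\t12001\t12200\t.\t+\t.\tgene_id "LNC1"; gene_type "antisense"; gene_name "Gm-like";
chr1\ttest\texon\t15001\t15162\t.\t+\t.\tgene_id "LNC1"; gene_type "antisense"; gene_name "Gm-like";
chr1\ttest\texon\t23001\t23300\t.\t+\t.\tgene_id "LNC1"; gene_type "antisense"; gene_name "Gm-like";
"""


@pytest.fixture
def two_gene_gtf(tmp_path):
    path = tmp_path / "two_gene.gtf"
    path.write_text(TWO_GENE_GTF)
    return path


@pytest.fixture
def antisense_trio_gtf(tmp_path):
    path = tmp_path / "antisense_trio.gtf"
    path.write_text(ANTISENSE_TRIO_GTF)
    return path


def small_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """A desk-scale config: 400 genes, a few planted pairs, one 80-fold
    planted gene at an informative baseline."""
    defaults = dict(
        seed=seed,
        n_genes=400,
        planted_pairs=[
            PlantedPair("antisense-overlap", 0.9, 3),
            PlantedPair("adjacent-with-promoter-overlap", 0.9, 2),
            PlantedPair("sense-intronic", 0.9, 1),
        ],
        planted_de=[PlantedDE(fold=80.0, biotype="antisense", baseline_cpm=45.0)],
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@pytest.fixture
def small_bundle(tmp_path):
    """Generated annotation + counts for a small config (in memory)."""
    from lncscreen.synthetic import generate_annotation, generate_counts

    config = small_config(seed=7)
    annot, truth, enhancers = generate_annotation(config)
    matrix = generate_counts(config, annot, truth)
    return config, annot, truth, enhancers, matrix
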