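"""Indexed gene annotation: overlap/nearest queries, promoter windows and
positional classification of lncRNAs.

The positional taxonomy follows the standard gene-level definitions:

* antisense — transcribed from the strand opposite a protein-coding gene it
  overlaps;
* lincRNA — intergenic, no coding-gene overlap on either strand;
* sense_intronic — same strand, contained in an intron of a coding gene with
  no exon overlap;
* sense_overlapping — same strand, a coding gene sits entirely inside one of
  the lncRNA's introns;
* three_prime_overlapping — same strand, the overlap is confined to the
  3'-most exon region of the coding gene (a gene-level proxy for the 3' UTR,
  which exon/span models do not encode).

When geometry is ambiguous the precedence is antisense > sense_intronic >
sense_overlapping > three_prime_overlapping > lincRNA. Annotated subclass
tags from the GTF always win over the geometric classifier.
"""

from __future__ import annotations

from typing import Iterable, Iterator

import numpy as np
from intervaltree import IntervalTree

from .models import BiotypeTaxonomy, GeneModel, GenomicInterval, LNC_SUBCLASSES

__all__ = [
    "AnnotationSet",
    "promoter_window",
    "classify_lnc_position",
    "nearest_coding_partners",
    "lnc_subclass",
    "mature_length",
]


class AnnotationSet:
    """A collection of gene models with per-chromosome interval indexes.

    Overlap queries use an interval tree; nearest-gap queries use vectorized
    span arrays. Both are verifiable against a pure-Python linear scan.
    """

    def __init__(self, genes: Iterable[GeneModel] = ()) -> None:
        self._genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        self._arrays: dict[tuple[str, bool], tuple[np.ndarray, np.ndarray, list[str]]] = {}
        for gene in genes:
            self.add(gene)

    def add(self, gene: GeneModel) -> None:
        if gene.gene_id in self._genes:
            raise ValueError(f"duplicate gene_id {gene.gene_id}")
        self._genes[gene.gene_id] = gene
        self._trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.span.start, gene.span.end, gene.gene_id
        )
        self._arrays.clear()  # span arrays are rebuilt lazily

    def __len__(self) -> int:
        return len(self._genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes.values())

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._genes

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._genes[gene_id]

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def genes_of_biotype(self, *biotypes: str) -> list[GeneModel]:
        return [g for g in self if g.biotype in biotypes]

    def _span_arrays(self, chrom: str, coding_only: bool):
        key = (chrom, coding_only)
        cached = self._arrays.get(key)
        if cached is None:
            genes = [
                g
                for g in self._genes.values()
                if g.chrom == chrom and (not coding_only or g.biotype == "protein_coding")
            ]
            genes.sort(key=lambda g: (g.span.start, g.gene_id))
            starts = np.array([g.span.start for g in genes], dtype=np.int64)
            ends = np.array([g.span.end for g in genes], dtype=np.int64)
            cached = (starts, ends, [g.gene_id for g in genes])
            self._arrays[key] = cached
        return cached

    def overlapping(self, interval: GenomicInterval) -> list[GeneModel]:
        """Genes whose spans share >= 1 bp with the interval (any strand)."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end)
        return sorted(
            (self._genes[h.data] for h in hits), key=lambda g: (g.span.start, g.gene_id)
        )

    def nearest(
        self,
        interval: GenomicInterval,
        coding_only: bool = False,
        exclude: str | None = None,
    ) -> tuple[list[GeneModel], int]:
        """Genes with the minimal span-to-span gap to the interval.

        Overlapping genes have gap 0; ties all returned; ``([], -1)`` when
        the chromosome holds no eligible gene.
        """
        starts, ends, ids = self._span_arrays(interval.chrom, coding_only)
        if exclude is not None and exclude in ids:
            keep = np.array([gid != exclude for gid in ids])
            starts, ends = starts[keep], ends[keep]
            ids = [gid for gid in ids if gid != exclude]
        if len(ids) == 0:
            return [], -1
        gaps = np.maximum(
            np.maximum(interval.start - ends, starts - interval.end), 0
        )
        best_gap = int(gaps.min())
        best = [self._genes[ids[i]] for i in np.flatnonzero(gaps == best_gap)]
        return best, best_gap


def mature_length(gene: GeneModel) -> int:
    """Sum of exon lengths (spliced transcript length) in nucleotides."""
    return gene.mature_length()


def promoter_window(gene: GeneModel, width: int = 10_000) -> GenomicInterval | None:
    """Strand-aware promoter window: up to ``width`` bp immediately upstream
    of the TSS, half-open, clipped at position 0.

    Returns None for a + strand gene starting at the chromosome origin
    (empty window).
    """
    if width <= 0:
        raise ValueError("promoter width must be positive")
    if gene.strand == "+":
        start = max(gene.span.start - width, 0)
        if start == gene.span.start:
            return None
        return GenomicInterval(gene.chrom, start, gene.span.start, gene.strand)
    return GenomicInterval(gene.chrom, gene.span.end, gene.span.end + width, gene.strand)


def _coding_overlaps(lnc: GeneModel, annot: AnnotationSet) -> list[GeneModel]:
    return [
        g
        for g in annot.overlapping(lnc.span)
        if g.biotype == "protein_coding" and g.gene_id != lnc.gene_id
    ]


def classify_lnc_position(lnc: GeneModel, annot: AnnotationSet) -> str:
    """Positional subclass of a lncRNA from its geometry against the coding
    genes in ``annot`` (see module docstring for definitions and precedence).
    """
    if not BiotypeTaxonomy.is_lncRNA(lnc.biotype) and lnc.biotype not in LNC_SUBCLASSES:
        raise ValueError(f"{lnc.gene_id} ({lnc.biotype}) is not a lncRNA")
    coding = _coding_overlaps(lnc, annot)
    if not coding:
        return "lincRNA"
    if any(g.strand != lnc.strand for g in coding):
        return "antisense"
    # same-strand overlaps only
    for g in coding:
        for intron in g.introns():
            if intron.start <= lnc.span.start and lnc.span.end <= intron.end:
                return "sense_intronic"
    for intron in lnc.introns():
        for g in coding:
            if intron.start <= g.span.start and g.span.end <= intron.end:
                return "sense_overlapping"
    for g in coding:
        region = g.three_prime_exon_region()
        lo = max(lnc.span.start, g.span.start)
        hi = min(lnc.span.end, g.span.end)
        if region.start <= lo and hi <= region.end:
            return "three_prime_overlapping"
    # residual same-strand overlap with no specific geometry: fold into the
    # least specific same-strand label
    return "sense_overlapping"


def nearest_coding_partners(lnc: GeneModel, annot: AnnotationSet) -> list[GeneModel]:
    """Nearest (adjacent or overlapping) protein-coding genes of a lncRNA.

    Overlapping coding genes take precedence over any gap; otherwise the
    coding gene(s) with minimal span-to-span gap on the chromosome are
    returned, with ties returning all tied genes. Empty when the chromosome
    carries no coding gene.
    """
    overlapped = _coding_overlaps(lnc, annot)
    if overlapped:
        return overlapped
    best, gap = annot.nearest(lnc.span, coding_only=True, exclude=lnc.gene_id)
    return best if gap >= 0 else []


def lnc_subclass(lnc: GeneModel, annot: AnnotationSet) -> str:
    """Subclass of a lncRNA: the annotated tag when the GTF carries one,
    otherwise the geometric classification."""
    if lnc.biotype in LNC_SUBCLASSES:
        return lnc.biotype
    return classify_lnc_position(lnc, annot)
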