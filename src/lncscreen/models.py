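"""Core genomic domain types: intervals, gene models, and the biotype taxonomy.

Coordinates are 0-based half-open internally; the GTF boundary converts
to and from the 1-based inclusive convention (see :mod:`lncscreen.gtfio`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "BiotypeTaxonomy",
    "DEFAULT_TAXONOMY",
    "LNC_SUBCLASSES",
    "SHORT_NC_SUBCLASSES",
    "SCREENED_LNC_SUBCLASSES",
]

VALID_STRANDS = ("+", "-")

#: lncRNA positional subclasses (leaves of the ncRNA/lncRNA branch).
LNC_SUBCLASSES = (
    "lincRNA",
    "antisense",
    "sense_intronic",
    "sense_overlapping",
    "three_prime_overlapping",
)

#: short ncRNA subclasses.
SHORT_NC_SUBCLASSES = ("miRNA", "snoRNA", "snRNA", "rRNA", "miscRNA")

#: lncRNA subclasses entering the cis-co-expression screen.
SCREENED_LNC_SUBCLASSES = ("lincRNA", "antisense", "sense_intronic")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}): need 0 <= start < end"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}: must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp on the same chromosome
        (strand is ignored)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> int:
        """Span-to-span gap in bp; 0 for overlapping or book-ended intervals."""
        if self.chrom != other.chrom:
            raise ValueError("gap undefined across chromosomes")
        return max(self.start - other.end, other.start - self.end, 0)

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class GeneModel:
    """A stranded gene with exons and a biotype.

    The TSS is ``span.start`` on the + strand and ``span.end - 1`` on the
    - strand. Exons must be sorted, non-overlapping and lie within the span.
    """

    gene_id: str
    gene_name: str
    biotype: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        prev_end = None
        for exon in self.exons:
            if exon.chrom != self.span.chrom or exon.strand != self.span.strand:
                raise ValueError(
                    f"gene {self.gene_id}: exon on {exon.chrom}{exon.strand} does "
                    f"not match gene span {self.span.chrom}{self.span.strand}"
                )
            if exon.start < self.span.start or exon.end > self.span.end:
                raise ValueError(
                    f"gene {self.gene_id}: exon [{exon.start}, {exon.end}) outside "
                    f"gene span [{self.span.start}, {self.span.end})"
                )
            if prev_end is not None and exon.start < prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: exons are not sorted/non-overlapping"
                )
            prev_end = exon.end

    @property
    def chrom(self) -> str:
        return self.span.chrom

    @property
    def strand(self) -> str:
        return self.span.strand

    @property
    def tss(self) -> int:
        return self.span.start if self.strand == "+" else self.span.end - 1

    def mature_length(self) -> int:
        """Spliced transcript length: sum of exon lengths in nucleotides."""
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        return sum(len(e) for e in self.exons)

    def introns(self) -> list[GenomicInterval]:
        """Intervals between consecutive exons (empty for single-exon genes)."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out

    def three_prime_exon_region(self) -> GenomicInterval:
        """Region from the start of the 3'-most exon to the gene end
        (strand-aware); used as a gene-level proxy for the 3' UTR."""
        if not self.exons:
            return self.span
        if self.strand == "+":
            last = self.exons[-1]
            return GenomicInterval(self.chrom, last.start, self.span.end, self.strand)
        first = self.exons[0]
        return GenomicInterval(self.chrom, self.span.start, first.end, self.strand)


class BiotypeTaxonomy:
    """Maps raw annotation biotype tags to a class tree.

    Top classes are ``protein_coding``, ``ncRNA`` and ``pseudogene``; the
    ncRNA class splits into lncRNA subclasses, short ncRNA subclasses and
    ``processed_transcript``. Every raw tag maps to exactly one leaf.
    """

    TOP_CLASSES = ("protein_coding", "ncRNA", "pseudogene")

    def __init__(
        self,
        tag_to_leaf: dict[str, str] | None = None,
        fallback: str | None = None,
    ) -> None:
        self.tag_to_leaf = dict(DEFAULT_TAG_MAP if tag_to_leaf is None else tag_to_leaf)
        self.fallback = fallback
        for leaf in self.tag_to_leaf.values():
            if self.leaf_path(leaf) is None:
                raise ValueError(f"unknown taxonomy leaf {leaf!r}")

    @staticmethod
    def leaf_path(leaf: str) -> tuple[str, ...] | None:
        """Path from the root to a leaf, or None if the leaf is unknown."""
        if leaf in ("protein_coding", "pseudogene"):
            return (leaf,)
        if leaf in LNC_SUBCLASSES:
            return ("ncRNA", "lncRNA", leaf)
        if leaf in SHORT_NC_SUBCLASSES:
            return ("ncRNA", "short_ncRNA", leaf)
        if leaf == "processed_transcript":
            return ("ncRNA", "processed_transcript")
        return None

    def classify(self, raw_tag: str) -> str:
        """Leaf biotype for a raw annotation tag."""
        leaf = self.tag_to_leaf.get(raw_tag)
        if leaf is None:
            if self.fallback is not None:
                return self.fallback
            raise KeyError(f"unknown biotype tag {raw_tag!r} and no fallback declared")
        return leaf

    def top_class(self, leaf: str) -> str:
        path = self.leaf_path(leaf)
        if path is None:
            raise ValueError(f"unknown taxonomy leaf {leaf!r}")
        return path[0]

    @staticmethod
    def is_lncRNA(leaf: str) -> bool:
        return leaf in LNC_SUBCLASSES

    @staticmethod
    def is_coding(leaf: str) -> bool:
        return leaf == "protein_coding"


# GENCODE-style raw tags -> taxonomy leaves. Pseudogene tags collapse onto one
# leaf; all lncRNA tags keep their positional subclass.
DEFAULT_TAG_MAP: dict[str, str] = {
    "protein_coding": "protein_coding",
    "lincRNA": "lincRNA",
    "antisense": "antisense",
    "sense_intronic": "sense_intronic",
    "sense_overlapping": "sense_overlapping",
    "3prime_overlapping_ncrna": "three_prime_overlapping",
    "3prime_overlapping_ncRNA": "three_prime_overlapping",
    "three_prime_overlapping": "three_prime_overlapping",
    "bidirectional_promoter_lncRNA": "lincRNA",
    "lncRNA": "lincRNA",
    "miRNA": "miRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "rRNA": "rRNA",
    "misc_RNA": "miscRNA",
    "miscRNA": "miscRNA",
    "processed_transcript": "processed_transcript",
    "pseudogene": "pseudogene",
    "processed_pseudogene": "pseudogene",
    "unprocessed_pseudogene": "pseudogene",
    "transcribed_processed_pseudogene": "pseudogene",
    "transcribed_unprocessed_pseudogene": "pseudogene",
    "polymorphic_pseudogene": "pseudogene",
    "unitary_pseudogene": "pseudogene",
    "IG_V_pseudogene": "pseudogene",
    "TR_V_pseudogene": "pseudogene",
}

#: Default taxonomy used by the readers when none is supplied.
DEFAULT_TAXONOMY = BiotypeTaxonomy()
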