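"""Readers and writers for the GTF (GENCODE attribute dialect) and BED formats.

GTF records are 1-based inclusive on disk and converted to the package's
0-based half-open convention on read; the writer applies the inverse
conversion so that a write/read round trip reproduces the models exactly.
Only ``gene`` and ``exon`` features are consumed; the biotype is taken from
the ``gene_type`` attribute, with ``gene_biotype`` accepted as a synonym.
"""

from __future__ import annotations

import re
from pathlib import Path

from .models import BiotypeTaxonomy, DEFAULT_TAXONOMY, GeneModel, GenomicInterval

__all__ = ["GtfParseError", "read_gtf", "write_gtf", "read_bed", "write_bed"]

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised for malformed GTF lines; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str) -> None:
        super().__init__(f"GTF line {lineno}: {message}")
        self.lineno = lineno


def _parse_attributes(field: str, lineno: int) -> dict[str, str]:
    attrs = dict(_ATTR_RE.findall(field))
    if "gene_id" not in attrs:
        raise GtfParseError(lineno, "missing gene_id attribute")
    return attrs


def read_gtf(path: str | Path, taxonomy: BiotypeTaxonomy | None = None) -> "AnnotationSet":
    """Read gene and exon features from a GTF file into an AnnotationSet.

    Parameters
    ----------
    path
        GTF file with GENCODE-style attributes (``gene_id "X"; gene_type "Y";``).
    taxonomy
        Biotype taxonomy used to map raw tags to leaves; defaults to the
        GENCODE mapping. Unknown tags raise unless the taxonomy declares a
        fallback class.
    """
    from .annotation import AnnotationSet  # local import to avoid a cycle

    taxonomy = taxonomy or DEFAULT_TAXONOMY
    spans: dict[str, tuple[GenomicInterval, str, str]] = {}
    exons: dict[str, list[GenomicInterval]] = {}
    order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(lineno, f"expected 9 tab-delimited fields, got {len(fields)}")
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attr_s = fields
            if feature not in ("gene", "exon"):
                continue
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise GtfParseError(lineno, f"non-integer coordinates {start_s!r}/{end_s!r}") from None
            if start1 < 1 or end1 < start1:
                raise GtfParseError(lineno, f"invalid 1-based coordinates {start1}-{end1}")
            try:
                interval = GenomicInterval(chrom, start1 - 1, end1, strand)
            except ValueError as exc:
                raise GtfParseError(lineno, str(exc)) from None
            attrs = _parse_attributes(attr_s, lineno)
            gene_id = attrs["gene_id"]
            if feature == "gene":
                raw_tag = attrs.get("gene_type", attrs.get("gene_biotype"))
                if raw_tag is None:
                    raise GtfParseError(lineno, "missing gene_type/gene_biotype attribute")
                try:
                    biotype = taxonomy.classify(raw_tag)
                except KeyError as exc:
                    raise GtfParseError(lineno, str(exc.args[0])) from None
                name = attrs.get("gene_name", gene_id)
                if gene_id in spans:
                    raise GtfParseError(lineno, f"duplicate gene record for {gene_id}")
                spans[gene_id] = (interval, name, biotype)
                order.append(gene_id)
            else:
                exons.setdefault(gene_id, []).append(interval)

    genes = []
    for gene_id in order:
        span, name, biotype = spans[gene_id]
        gene_exons = sorted(exons.get(gene_id, []), key=lambda e: e.start)
        try:
            genes.append(GeneModel(gene_id, name, biotype, span, gene_exons))
        except ValueError as exc:
            raise ValueError(f"validation error for gene {gene_id}: {exc}") from None
    orphans = set(exons) - set(spans)
    if orphans:
        raise ValueError(f"exon records without a gene record: {sorted(orphans)[:5]}")
    return AnnotationSet(genes)


# leaf biotype -> raw tag emitted by the writer (chosen so the default
# taxonomy maps it straight back to the same leaf)
_LEAF_TO_TAG = {
    "protein_coding": "protein_coding",
    "lincRNA": "lincRNA",
    "antisense": "antisense",
    "sense_intronic": "sense_intronic",
    "sense_overlapping": "sense_overlapping",
    "three_prime_overlapping": "3prime_overlapping_ncrna",
    "miRNA": "miRNA",
    "snoRNA": "snoRNA",
    "snRNA": "snRNA",
    "rRNA": "rRNA",
    "miscRNA": "misc_RNA",
    "processed_transcript": "processed_transcript",
    "pseudogene": "pseudogene",
}


def write_gtf(annot: "AnnotationSet", path: str | Path, source: str = "lncscreen") -> None:
    """Write an AnnotationSet back to GENCODE-dialect GTF (gene + exon rows)."""
    with open(path, "w") as fh:
        for gene in annot:
            tag = _LEAF_TO_TAG.get(gene.biotype, gene.biotype)
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_type "{tag}"; '
                f'gene_name "{gene.gene_name}";'
            )
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{gene.span.start + 1}\t{gene.span.end}"
                f"\t.\t{gene.strand}\t.\t{attrs}\n"
            )
            for i, exon in enumerate(gene.exons, start=1):
                fh.write(
                    f"{gene.chrom}\t{source}\texon\t{exon.start + 1}\t{exon.end}"
                    f"\t.\t{gene.strand}\t.\t{attrs} exon_number {i};\n"
                )


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read intervals from a BED3+ file (0-based half-open, as on disk).

    BED carries no mandatory strand; column 6 is used when present,
    otherwise '+' is assigned (the screen's enhancer logic is strandless).
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"BED line {lineno}: expected >= 3 columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            out.append(GenomicInterval(chrom, start, end, strand))
    return out


def write_bed(intervals: list[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
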