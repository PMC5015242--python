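"""Count matrices, CPM normalization, the mean-expression filter, and the
composition and alignment-summary reports.

CPM here divides a gene's exonic read-pair count by the sample's
genome-mapped read-pair total (the externally supplied library size), times
1e6 — not by the column sum of exonic counts. ``cpm_normalize`` offers
column-sum normalization as an option for generic reuse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .models import (
    BiotypeTaxonomy,
    LNC_SUBCLASSES,
    SHORT_NC_SUBCLASSES,
)

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "CompositionReport",
    "read_counts",
    "cpm_normalize",
    "filter_expressed",
    "composition_report",
    "alignment_summary",
    "round_half_away",
    "percent",
]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (5.5 -> 6, -5.5 -> -6); banker's rounding
    is deliberately not used so percentages match hand-rounded report style."""
    scale = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * scale + 0.5), x) / scale


def percent(count: float, total: float, ndigits: int = 1) -> float:
    """Percentage of a parent total, rounded half away from zero."""
    if total == 0:
        return 0.0
    return round_half_away(count / total * 100.0, ndigits)


@dataclass
class CountMatrix:
    """Integer gene x sample read-pair counts with per-sample metadata.

    ``library_sizes`` are read-pairs mapped to the reference genome and must
    be at least each sample's column sum of exonic counts.
    """

    counts: pd.DataFrame  # genes x samples, non-negative integers
    group_labels: pd.Series  # sample -> group name
    library_sizes: pd.Series  # sample -> positive integer

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, errors="raise")
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        samples = list(self.counts.columns)
        for name, series in (("group_labels", self.group_labels), ("library_sizes", self.library_sizes)):
            missing = set(samples) - set(series.index)
            if missing:
                raise ValueError(f"{name} missing samples: {sorted(missing)}")
        self.group_labels = self.group_labels.loc[samples]
        self.library_sizes = self.library_sizes.loc[samples].astype(np.int64)
        if (self.library_sizes <= 0).any():
            raise ValueError("library sizes must be positive")
        colsums = self.counts.sum(axis=0)
        bad = colsums[colsums > self.library_sizes]
        if len(bad):
            raise ValueError(
                f"column count sum exceeds library size for samples {list(bad.index)}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.group_labels[self.group_labels == group].index)


@dataclass
class ExpressionMatrix:
    """CPM values on the same axes as the source CountMatrix."""

    values: pd.DataFrame  # genes x samples, CPM
    group_labels: pd.Series

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def mean_cpm(self) -> pd.Series:
        """Unweighted per-gene mean CPM across all samples."""
        return self.values.mean(axis=1)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.group_labels[self.group_labels == group].index)


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a gene x sample counts TSV plus a sample-metadata TSV.

    The counts TSV has a gene-id column (first) and one column per sample;
    the metadata TSV columns are ``sample_id``, ``group``, ``library_size``.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    meta = pd.read_csv(samples_path, sep="\t")
    required = {"sample_id", "group", "library_size"}
    if not required.issubset(meta.columns):
        raise ValueError(f"sample metadata must have columns {sorted(required)}")
    meta = meta.set_index("sample_id")
    unknown = set(counts.columns) - set(meta.index)
    if unknown:
        raise ValueError(f"samples missing from metadata: {sorted(unknown)}")
    if not counts.empty:
        for col in counts.columns:
            vals = counts[col]
            if not np.issubdtype(vals.dtype, np.integer):
                if not np.allclose(vals, np.round(vals)):
                    raise ValueError(f"non-integer counts in sample {col}")
                counts[col] = vals.astype(np.int64)
    return CountMatrix(
        counts=counts,
        group_labels=meta["group"],
        library_sizes=meta["library_size"],
    )


def cpm_normalize(m: CountMatrix, denominator: str = "library_size") -> ExpressionMatrix:
    """Counts-per-million: count / library size x 1e6.

    ``denominator="column_sum"`` divides by the per-sample exonic count sum
    instead (generic reuse; not the default).
    """
    if denominator == "library_size":
        denom = m.library_sizes.astype(float)
    elif denominator == "column_sum":
        denom = m.counts.sum(axis=0).astype(float)
    else:
        raise ValueError("denominator must be 'library_size' or 'column_sum'")
    if (denom <= 0).any():
        raise ValueError("zero normalization denominator")
    values = m.counts.astype(float).div(denom, axis=1) * 1e6
    return ExpressionMatrix(values=values, group_labels=m.group_labels)


def filter_expressed(e: ExpressionMatrix, threshold: float = 1.0) -> set[str]:
    """Genes whose unweighted mean CPM across all samples is strictly above
    the threshold (default 1 CPM)."""
    if e.values.empty:
        raise ValueError("empty expression matrix")
    means = e.mean_cpm()
    return set(means.index[means > threshold])


@dataclass
class CompositionReport:
    """Nested biotype census of an expressed gene set with percentages.

    Percentages are of the appropriate parent total (top classes of the
    grand total; lncRNA subclasses of the lncRNA total; etc.), one decimal,
    half away from zero.
    """

    total: int
    top: dict[str, dict[str, float]]  # class -> {count, percent}
    ncRNA: dict[str, dict[str, float]]  # lncRNA / short_ncRNA / processed_transcript
    lncRNA: dict[str, dict[str, float]]  # positional subclasses
    short_ncRNA: dict[str, dict[str, float]]
    antisense_targets: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "top": self.top,
            "ncRNA": self.ncRNA,
            "lncRNA": self.lncRNA,
            "short_ncRNA": self.short_ncRNA,
            "antisense_targets": self.antisense_targets,
        }


def _census(counts: dict[str, int], total: int) -> dict[str, dict[str, float]]:
    return {
        name: {"count": n, "percent": percent(n, total)}
        for name, n in counts.items()
        if n or name in counts
    }


def composition_report(annot: AnnotationSet, expressed: set[str]) -> CompositionReport:
    """Biotype composition of an expressed gene set, plus the breakdown of
    gene classes overlapped by expressed antisense lncRNAs."""
    missing = [g for g in expressed if g not in annot]
    if missing:
        raise ValueError(f"expressed genes absent from annotation: {sorted(missing)[:5]}")
    top_counts = {c: 0 for c in BiotypeTaxonomy.TOP_CLASSES}
    nc_counts = {"lncRNA": 0, "short_ncRNA": 0, "processed_transcript": 0}
    lnc_counts = {c: 0 for c in LNC_SUBCLASSES}
    short_counts = {c: 0 for c in SHORT_NC_SUBCLASSES}
    antisense_genes = []
    for gid in expressed:
        gene = annot[gid]
        path = BiotypeTaxonomy.leaf_path(gene.biotype)
        if path is None:
            raise ValueError(f"gene {gid} has unknown biotype {gene.biotype}")
        top_counts[path[0]] += 1
        if path[0] == "ncRNA":
            nc_counts[path[1]] += 1
            if path[1] == "lncRNA":
                lnc_counts[path[2]] += 1
                if path[2] == "antisense":
                    antisense_genes.append(gene)
            elif path[1] == "short_ncRNA":
                short_counts[path[2]] += 1
    total = len(expressed)
    # classes of genes overlapped on the opposite strand by expressed
    # antisense lncRNAs (each target gene counted once)
    target_ids: set[str] = set()
    for lnc in antisense_genes:
        for g in annot.overlapping(lnc.span):
            if g.gene_id != lnc.gene_id and g.strand != lnc.strand:
                target_ids.add(g.gene_id)
    target_counts = {c: 0 for c in BiotypeTaxonomy.TOP_CLASSES}
    for gid in target_ids:
        path = BiotypeTaxonomy.leaf_path(annot[gid].biotype)
        target_counts[path[0]] += 1
    n_targets = len(target_ids)
    return CompositionReport(
        total=total,
        top=_census(top_counts, total),
        ncRNA=_census(nc_counts, top_counts["ncRNA"]),
        lncRNA=_census(lnc_counts, nc_counts["lncRNA"]),
        short_ncRNA=_census(short_counts, nc_counts["short_ncRNA"]),
        antisense_targets=_census(target_counts, n_targets),
    )


def alignment_summary(stats: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Per-group and overall means of alignment statistics.

    ``stats`` columns: ``input_read_pairs``, ``uniquely_mapped`` (index =
    sample ids). Mean read-pair counts are rounded to the nearest integer
    and the mean of per-sample mapped percentages to one decimal, both half
    away from zero. The summary percentage is the mean of per-sample
    percentages, not the ratio of summed counts.
    """
    if stats.empty:
        raise ValueError("no samples")
    if (stats["uniquely_mapped"] > stats["input_read_pairs"]).any():
        raise ValueError("uniquely mapped read-pairs exceed input read-pairs")
    df = stats.copy()
    df["percent_mapped"] = df["uniquely_mapped"] / df["input_read_pairs"] * 100.0

    def summarize(sub: pd.DataFrame, label: str, n: int) -> dict:
        return {
            "group": label,
            "n": n,
            "mean_input_read_pairs": round_half_away(sub["input_read_pairs"].mean()),
            "mean_uniquely_mapped": round_half_away(sub["uniquely_mapped"].mean()),
            "mean_percent_mapped": round_half_away(sub["percent_mapped"].mean(), 1),
        }

    rows = []
    if groups is not None:
        for group in pd.unique(groups):
            members = groups[groups == group].index
            rows.append(summarize(df.loc[members], str(group), len(members)))
    rows.append(summarize(df, "overall", len(df)))
    out = pd.DataFrame(rows).set_index("group")
    for col in ("mean_input_read_pairs", "mean_uniquely_mapped"):
        out[col] = out[col].astype(np.int64)
    return out
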