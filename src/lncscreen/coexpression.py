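"""The cis-co-expression screen: lncRNA / nearest-coding-gene pairs tested
against an analytic Pearson critical value, with geometry annotations.

Significance uses a fixed per-test critical value derived from the t
distribution — |r| strictly greater than r_crit(n, alpha) — with no
multiple-testing correction across pairs. This mirrors the fixed-threshold
screening style of exploratory cis-regulation scans (at n = 11 and
alpha = 0.05 the threshold is 0.602) and is deliberately anti-conservative;
see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import stats

from .annotation import (
    AnnotationSet,
    lnc_subclass,
    nearest_coding_partners,
    promoter_window,
)
from .expression import ExpressionMatrix, percent
from .models import GenomicInterval, LNC_SUBCLASSES, SCREENED_LNC_SUBCLASSES

__all__ = [
    "PairCandidate",
    "CoexpressionResult",
    "ScreenSummary",
    "critical_r",
    "pearson_r",
    "build_pairs",
    "screen_pairs",
    "annotate_geometry",
    "enhancer_transcribed",
    "summarize",
]


def critical_r(n: int, alpha: float = 0.05) -> float:
    """Critical |Pearson r| at two-tailed level alpha for n samples.

    r_crit = t / sqrt(t^2 + n - 2) with t the upper alpha/2 quantile of the
    t distribution on n - 2 degrees of freedom.
    """
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    # isf keeps precision for very small alpha where 1 - alpha/2 rounds to 1
    t = stats.t.isf(alpha / 2.0, n - 2)
    if np.isinf(t):
        return 1.0
    return float(t / np.sqrt(t * t + n - 2))


class ZeroVarianceError(ValueError):
    """A correlation operand has zero variance; the pair is skipped."""


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d vectors of length >= 3")
    xm = x - x.mean()
    ym = y - y.mean()
    denom = np.sqrt((xm * xm).sum() * (ym * ym).sum())
    if denom == 0.0:
        raise ZeroVarianceError("zero variance")
    return float(np.clip((xm * ym).sum() / denom, -1.0, 1.0))


@dataclass(frozen=True)
class PairCandidate:
    """One lncRNA / coding-gene pair entering the screen."""

    lnc_id: str
    coding_id: str
    relation: str  # "overlapping" | "adjacent"
    lnc_subclass: str  # lincRNA | antisense | sense_intronic


@dataclass
class CoexpressionResult:
    """Screen output row for one pair."""

    pair: PairCandidate
    r: float
    n: int
    significant: bool
    sign: str | None  # "positive" | "negative", defined only when significant
    gene_overlap: bool | None = None
    promoter_overlap: bool | None = None
    expression_ratio: float | None = None
    ratio_below_30pct: bool | None = None
    enhancer_transcribed: bool | None = None

    def to_row(self) -> dict:
        d = asdict(self.pair)
        d.update(
            r=self.r,
            n=self.n,
            significant=self.significant,
            sign=self.sign or "",
            gene_overlap=self.gene_overlap,
            promoter_overlap=self.promoter_overlap,
            expression_ratio=self.expression_ratio,
            ratio_below_30pct=self.ratio_below_30pct,
            enhancer_transcribed=self.enhancer_transcribed,
        )
        return d


def build_pairs(
    annot: AnnotationSet,
    expressed: set[str],
    expr: ExpressionMatrix | None = None,
) -> tuple[list[PairCandidate], dict]:
    """Pair every expressed lncRNA of the screened subclasses (lincRNA,
    antisense, sense-intronic) with each of its expressed nearest/overlapping
    coding genes.

    lncRNAs whose partners are all unexpressed yield no pair. Returns the
    candidates plus a tally dict (lncRNAs ranked per subclass, lncRNAs
    retained, coding genes involved).
    """
    pairs: list[PairCandidate] = []
    ranked = {c: 0 for c in SCREENED_LNC_SUBCLASSES}
    kept_lnc: set[str] = set()
    kept_coding: set[str] = set()
    for gene in annot:
        if gene.biotype not in LNC_SUBCLASSES or gene.gene_id not in expressed:
            continue
        subclass = lnc_subclass(gene, annot)
        if subclass not in SCREENED_LNC_SUBCLASSES:
            continue
        ranked[subclass] += 1
        partners = nearest_coding_partners(gene, annot)
        for partner in partners:
            if partner.gene_id not in expressed:
                continue
            relation = "overlapping" if gene.span.overlaps(partner.span) else "adjacent"
            pairs.append(
                PairCandidate(gene.gene_id, partner.gene_id, relation, subclass)
            )
            kept_lnc.add(gene.gene_id)
            kept_coding.add(partner.gene_id)
    tallies = {
        "lnc_ranked_by_subclass": ranked,
        "lnc_ranked_total": sum(ranked.values()),
        "lnc_in_pairs": len(kept_lnc),
        "coding_in_pairs": len(kept_coding),
        "pairs": len(pairs),
    }
    return pairs, tallies


def screen_pairs(
    expr: ExpressionMatrix,
    pairs: list[PairCandidate],
    alpha: float = 0.05,
    scale: str = "cpm",
) -> tuple[list[CoexpressionResult], int]:
    """Pearson-test each pair against the analytic critical value.

    ``scale="cpm"`` correlates raw CPM (default); ``scale="log2"``
    correlates log2(CPM + 1). Zero-variance pairs are skipped and counted,
    not errored. Returns (results, n_skipped).
    """
    n = len(expr.sample_ids)
    r_crit = critical_r(n, alpha)
    values = expr.values
    if scale == "log2":
        values = np.log2(values + 1.0)
    elif scale != "cpm":
        raise ValueError("scale must be 'cpm' or 'log2'")
    results: list[CoexpressionResult] = []
    skipped = 0
    for pair in pairs:
        if pair.lnc_id not in values.index or pair.coding_id not in values.index:
            raise KeyError(f"pair member missing from expression matrix: {pair}")
        x = values.loc[pair.lnc_id].to_numpy()
        y = values.loc[pair.coding_id].to_numpy()
        try:
            r = pearson_r(x, y)
        except ZeroVarianceError:
            skipped += 1
            continue
        significant = abs(r) > r_crit
        sign = ("positive" if r > 0 else "negative") if significant else None
        results.append(CoexpressionResult(pair=pair, r=r, n=n, significant=significant, sign=sign))
    return results, skipped


def annotate_geometry(
    res: CoexpressionResult,
    annot: AnnotationSet,
    expr: ExpressionMatrix,
    promoter_width: int = 10_000,
    ratio_cutoff: float = 0.30,
    enhancers: list[GenomicInterval] | None = None,
    enhancer_mode: str = "tss",
) -> CoexpressionResult:
    """Fill the geometry and expression-ratio annotations of a result in
    place (and return it).

    gene_overlap: the two gene spans intersect. promoter_overlap: the lncRNA
    span intersects the coding gene's upstream promoter window.
    expression_ratio: mean lncRNA CPM over mean coding CPM, flagged when
    below the ratio cutoff (default 30 %).
    """
    lnc = annot[res.pair.lnc_id]
    coding = annot[res.pair.coding_id]
    res.gene_overlap = lnc.span.overlaps(coding.span)
    window = promoter_window(coding, promoter_width)
    res.promoter_overlap = window is not None and lnc.span.overlaps(window)
    mean = expr.mean_cpm()
    coding_mean = float(mean[coding.gene_id])
    res.expression_ratio = float(mean[lnc.gene_id]) / coding_mean
    res.ratio_below_30pct = res.expression_ratio < ratio_cutoff
    if enhancers is not None:
        res.enhancer_transcribed = enhancer_transcribed(lnc, enhancers, mode=enhancer_mode)
    return res


def enhancer_transcribed(
    lnc, enhancers: list[GenomicInterval], mode: str = "tss"
) -> bool:
    """Whether a lncRNA is transcribed from an annotated enhancer.

    ``mode="tss"`` (default): the lncRNA TSS lies inside an enhancer
    interval. ``mode="overlap"``: any span overlap qualifies.
    """
    if mode not in ("tss", "overlap"):
        raise ValueError("mode must be 'tss' or 'overlap'")
    for iv in enhancers:
        if iv.chrom != lnc.chrom:
            continue
        if mode == "tss" and iv.contains_point(lnc.tss):
            return True
        if mode == "overlap" and iv.overlaps(lnc.span):
            return True
    return False


@dataclass
class ScreenSummary:
    """Counts and percentages over a screen's results.

    Prose-style percentages are integers (of the significant-pair total);
    one-decimal values are retained alongside in ``percent_detail``.
    """

    pairs_examined: int
    pairs_skipped_zero_variance: int
    examined_by_subclass: dict[str, int]
    significant_total: int
    significant_by_subclass: dict[str, int]
    n_positive: int
    n_negative: int
    percent_positive: int
    percent_negative: int
    n_gene_overlap: int
    percent_gene_overlap: int
    n_promoter_overlap: int
    percent_promoter_overlap: int
    n_enhancer_transcribed: int
    n_ratio_below_30pct: int
    percent_ratio_below_30pct: int
    percent_detail: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


def summarize(results: list[CoexpressionResult], skipped: int = 0) -> ScreenSummary:
    """Aggregate screen results into the standard summary.

    Percentages are of the significant-pair total and rounded to integer
    percent (half away from zero); an empty screen yields zero percentages.
    """
    sig = [r for r in results if r.significant]
    by_sub_all = {c: 0 for c in SCREENED_LNC_SUBCLASSES}
    by_sub_sig = {c: 0 for c in SCREENED_LNC_SUBCLASSES}
    for r in results:
        by_sub_all[r.pair.lnc_subclass] += 1
    for r in sig:
        by_sub_sig[r.pair.lnc_subclass] += 1
    n_sig = len(sig)
    n_pos = sum(1 for r in sig if r.sign == "positive")
    n_neg = n_sig - n_pos
    n_overlap = sum(1 for r in sig if r.gene_overlap)
    n_prom = sum(1 for r in sig if r.promoter_overlap)
    n_enh = sum(1 for r in sig if r.enhancer_transcribed)
    n_ratio = sum(1 for r in sig if r.ratio_below_30pct)

    def pct(k: int) -> int:
        return int(percent(k, n_sig, 0)) if n_sig else 0

    def pct1(k: int) -> float:
        return percent(k, n_sig, 1) if n_sig else 0.0

    return ScreenSummary(
        pairs_examined=len(results),
        pairs_skipped_zero_variance=skipped,
        examined_by_subclass=by_sub_all,
        significant_total=n_sig,
        significant_by_subclass=by_sub_sig,
        n_positive=n_pos,
        n_negative=n_neg,
        percent_positive=pct(n_pos),
        percent_negative=pct(n_neg),
        n_gene_overlap=n_overlap,
        percent_gene_overlap=pct(n_overlap),
        n_promoter_overlap=n_prom,
        percent_promoter_overlap=pct(n_prom),
        n_enhancer_transcribed=n_enh,
        n_ratio_below_30pct=n_ratio,
        percent_ratio_below_30pct=pct(n_ratio),
        percent_detail={
            "positive": pct1(n_pos),
            "negative": pct1(n_neg),
            "gene_overlap": pct1(n_overlap),
            "promoter_overlap": pct1(n_prom),
            "ratio_below_30pct": pct1(n_ratio),
        },
    )
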