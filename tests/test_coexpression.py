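"""The analytic Pearson threshold, pair building, screening, geometry
annotation and summary tallies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from lncscreen.annotation import AnnotationSet
from lncscreen.coexpression import (
    PairCandidate,
    ZeroVarianceError,
    annotate_geometry,
    build_pairs,
    critical_r,
    enhancer_transcribed,
    pearson_r,
    screen_pairs,
    summarize,
)
from lncscreen.datasets import pomc_screen_counts
from lncscreen.expression import CountMatrix, ExpressionMatrix, cpm_normalize, filter_expressed
from lncscreen.models import GenomicInterval

from conftest import make_gene


class TestCriticalR:
    def test_reference_thresholds(self):
        # frozen from the t-quantile: t(0.975, 9) = 2.2622 -> 0.602;
        # t(0.975, 10) = 2.2281 -> 0.576
        assert round(critical_r(11, 0.05), 3) == 0.602
        assert round(critical_r(12, 0.05), 3) == 0.576

    def test_limits_in_alpha(self):
        assert critical_r(11, 0.9999) < 0.01
        assert critical_r(11, 1e-30) > 0.999

    def test_strictly_decreasing_in_n_and_alpha(self):
        rs = [critical_r(n, 0.05) for n in range(3, 40)]
        assert all(a > b for a, b in zip(rs, rs[1:]))
        alphas = [0.001, 0.01, 0.05, 0.2, 0.5]
        rs = [critical_r(11, a) for a in alphas]
        assert all(a > b for a, b in zip(rs, rs[1:]))

    def test_matches_empirical_null_quantile(self):
        # |r| of independent normal pairs at n = 11: the 95th percentile
        # must agree with the analytic threshold within MC error
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20_000, 11))
        y = rng.normal(size=(20_000, 11))
        xm = x - x.mean(1, keepdims=True)
        ym = y - y.mean(1, keepdims=True)
        r = (xm * ym).sum(1) / np.sqrt((xm * xm).sum(1) * (ym * ym).sum(1))
        assert np.quantile(np.abs(r), 0.95) == pytest.approx(critical_r(11), abs=0.01)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            critical_r(2)


class TestPearson:
    def test_hand_examples(self):
        x = np.arange(1.0, 12.0)
        assert pearson_r(x, x) == pytest.approx(1.0)
        assert pearson_r(x, -2 * x + 7) == pytest.approx(-1.0)
        assert pearson_r([1, 2, 3, 4], [2, 1, 4, 3]) == pytest.approx(0.6)

    def test_zero_variance_raises(self):
        with pytest.raises(ZeroVarianceError):
            pearson_r([1, 1, 1, 1], [1, 2, 3, 4])

    def test_invariant_to_per_gene_positive_affine_maps(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=11)
        y = rng.normal(size=11)
        r = pearson_r(x, y)
        assert pearson_r(3.5 * x + 2.0, y) == pytest.approx(r)
        assert pearson_r(x, 0.1 * y - 7.0) == pytest.approx(r)


def _expr(values: dict[str, list[float]], groups: dict | None = None) -> ExpressionMatrix:
    frame = pd.DataFrame(values).T
    frame.columns = [f"S{i}" for i in range(frame.shape[1])]
    return ExpressionMatrix(
        values=frame,
        group_labels=pd.Series(groups or {s: "g" for s in frame.columns}),
    )


class TestBuildPairs:
    def _annot(self):
        return AnnotationSet(
            [
                make_gene("C1", "chr1", 0, 6_000, "+"),
                make_gene("C2", "chr1", 8_000, 14_000, "+"),
                make_gene("A1", "chr1", 4_000, 9_000, "-", biotype="antisense"),
                make_gene("L1", "chr1", 30_000, 31_000, "+", biotype="lincRNA"),
                make_gene("C3", "chr1", 34_000, 40_000, "+"),
            ]
        )

    def test_antisense_overlapping_two_expressed_coding_gives_two_pairs(self):
        annot = self._annot()
        pairs, tallies = build_pairs(annot, {"C1", "C2", "A1", "C3", "L1"})
        a1 = [p for p in pairs if p.lnc_id == "A1"]
        assert {p.coding_id for p in a1} == {"C1", "C2"}
        assert all(p.relation == "overlapping" for p in a1)
        assert tallies["pairs"] == 3  # A1 x2 + L1 x1

    def test_unexpressed_partner_yields_no_pair(self):
        annot = self._annot()
        pairs, _ = build_pairs(annot, {"L1"})  # C3 unexpressed
        assert pairs == []

    def test_matches_brute_force_enumeration(self, small_bundle):
        _, annot, _, _, matrix = small_bundle
        expr = cpm_normalize(matrix)
        expressed = filter_expressed(expr)
        pairs, _ = build_pairs(annot, expressed)
        # brute force: for each expressed screened lncRNA, overlapped
        # expressed coding genes, else minimal-gap expressed-or-not coding
        from lncscreen.annotation import lnc_subclass, nearest_coding_partners

        expected = set()
        for gene in annot:
            if gene.biotype not in ("lincRNA", "antisense", "sense_intronic"):
                continue
            if gene.gene_id not in expressed:
                continue
            if lnc_subclass(gene, annot) not in ("lincRNA", "antisense", "sense_intronic"):
                continue
            for partner in nearest_coding_partners(gene, annot):
                if partner.gene_id in expressed:
                    expected.add((gene.gene_id, partner.gene_id))
        assert {(p.lnc_id, p.coding_id) for p in pairs} == expected


class TestScreenPairs:
    def test_perfect_and_boundary_correlation(self):
        n = 11
        rc = critical_r(n)
        rng = np.random.default_rng(3)
        x = rng.normal(size=n)
        xs = (x - x.mean()) / np.linalg.norm(x - x.mean())
        e = rng.normal(size=n)
        e -= e.mean() + (e @ xs) * xs  # orthogonal to x, centered
        e /= np.linalg.norm(e)

        def with_r(r):
            return r * xs + np.sqrt(1 - r * r) * e

        expr = _expr(
            {
                "L_hi": list(x),
                "C_hi": list(x),
                "L_lo": list(with_r(rc - 1e-6)),
                "L_up": list(with_r(rc + 1e-6)),
                "C_ref": list(xs),
            }
        )
        pairs = [
            PairCandidate("L_hi", "C_hi", "overlapping", "antisense"),
            PairCandidate("L_lo", "C_ref", "adjacent", "lincRNA"),
            PairCandidate("L_up", "C_ref", "adjacent", "lincRNA"),
        ]
        results, skipped = screen_pairs(expr, pairs)
        assert skipped == 0
        by_id = {r.pair.lnc_id: r for r in results}
        assert by_id["L_hi"].significant and by_id["L_hi"].sign == "positive"
        # strictly-greater rule around the critical value
        assert not by_id["L_lo"].significant and by_id["L_lo"].sign is None
        assert by_id["L_up"].significant

    def test_zero_variance_pair_skipped_and_counted(self):
        expr = _expr({"L": [1.0] * 11, "C": list(range(11))})
        results, skipped = screen_pairs(
            expr, [PairCandidate("L", "C", "adjacent", "lincRNA")]
        )
        assert results == [] and skipped == 1

    def test_null_false_positive_rate_matches_alpha(self):
        # independent pairs at n = 11 should flag at ~ alpha
        rng = np.random.default_rng(11)
        n_pairs = 3_000
        frame = pd.DataFrame(
            rng.normal(size=(2 * n_pairs, 11)),
            index=[f"G{i}" for i in range(2 * n_pairs)],
            columns=[f"S{i}" for i in range(11)],
        )
        expr = ExpressionMatrix(
            values=frame, group_labels=pd.Series("g", index=frame.columns)
        )
        pairs = [
            PairCandidate(f"G{i}", f"G{i + n_pairs}", "adjacent", "lincRNA")
            for i in range(n_pairs)
        ]
        results, _ = screen_pairs(expr, pairs)
        frac = np.mean([r.significant for r in results])
        se = np.sqrt(0.05 * 0.95 / n_pairs)
        assert abs(frac - 0.05) < 3 * se


class TestGeometryAnnotation:
    def test_promoter_overlap_without_gene_overlap(self):
        annot = AnnotationSet(
            [
                make_gene("C", "chr1", 20_000, 26_000, "+"),
                make_gene("L", "chr1", 14_000, 15_500, "+", biotype="lincRNA"),
            ]
        )
        expr = _expr({"L": [2.0] * 11, "C": [10.0] * 11})
        res = _result("L", "C")
        annotate_geometry(res, annot, expr)
        assert res.promoter_overlap and not res.gene_overlap
        assert res.expression_ratio == pytest.approx(0.2)
        assert res.ratio_below_30pct

    def test_overlapping_pair_flags_gene_overlap(self):
        annot = AnnotationSet(
            [
                make_gene("C", "chr1", 0, 10_000, "+"),
                make_gene("L", "chr1", 2_000, 5_000, "-", biotype="antisense"),
            ]
        )
        expr = _expr({"L": [5.0] * 11, "C": [10.0] * 11})
        res = _result("L", "C", subclass="antisense", relation="overlapping")
        annotate_geometry(res, annot, expr)
        assert res.gene_overlap
        assert not res.ratio_below_30pct


def _result(lnc, coding, subclass="lincRNA", relation="adjacent"):
    from lncscreen.coexpression import CoexpressionResult

    return CoexpressionResult(
        pair=PairCandidate(lnc, coding, relation, subclass),
        r=0.9,
        n=11,
        significant=True,
        sign="positive",
    )


class TestEnhancer:
    ENHANCER = GenomicInterval("chr13", 118_713_610, 118_715_012, "+")

    def test_tss_inside_enhancer(self):
        lnc = make_gene("L", "chr13", 118_700_000, 118_714_001, "-", biotype="antisense")
        assert lnc.tss == 118_714_000
        assert enhancer_transcribed(lnc, [self.ENHANCER])

    def test_tss_one_bp_past_interval_end(self):
        lnc = make_gene("L", "chr13", 118_700_000, 118_715_013, "-", biotype="antisense")
        assert lnc.tss == 118_715_012
        assert not enhancer_transcribed(lnc, [self.ENHANCER])

    def test_empty_enhancer_list(self):
        lnc = make_gene("L", "chr13", 118_713_700, 118_714_000, "+", biotype="lincRNA")
        assert not enhancer_transcribed(lnc, [])

    def test_overlap_mode(self):
        # minus-strand TSS past the enhancer end, but span overlapping it
        lnc = make_gene("L", "chr13", 118_714_000, 118_716_000, "-", biotype="lincRNA")
        assert not enhancer_transcribed(lnc, [self.ENHANCER], mode="tss")
        assert enhancer_transcribed(lnc, [self.ENHANCER], mode="overlap")


class TestSummary:
    def test_reference_screen_percentages(self):
        ref = pomc_screen_counts()
        results = []
        n_pos, n_neg = ref["positive"], ref["negative"]
        n_prom = ref["promoter_overlap"]
        for i in range(n_pos + n_neg):
            res = _result(f"L{i}", f"C{i}")
            res.sign = "positive" if i < n_pos else "negative"
            res.r = 0.8 if i < n_pos else -0.8
            res.promoter_overlap = i < n_prom
            results.append(res)
        summary = summarize(results)
        assert summary.significant_total == 82
        assert summary.percent_positive == 72
        assert summary.percent_negative == 28
        assert summary.percent_promoter_overlap == 35

    def test_counts_are_conserved(self, small_bundle):
        _, annot, _, _, matrix = small_bundle
        expr = cpm_normalize(matrix)
        expressed = filter_expressed(expr)
        pairs, _ = build_pairs(annot, expressed)
        results, skipped = screen_pairs(expr, pairs)
        summary = summarize(results, skipped)
        assert summary.n_positive + summary.n_negative == summary.significant_total
        assert sum(summary.examined_by_subclass.values()) == summary.pairs_examined
        assert sum(summary.significant_by_subclass.values()) == summary.significant_total

    def test_empty_results(self):
        summary = summarize([])
        assert summary.significant_total == 0
        assert summary.percent_positive == 0
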