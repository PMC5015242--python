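"""Reference summary tables from an RNA-seq profile of hypothalamic POMC
neurons (11 libraries: 6 prenatally nicotine-exposed offspring N1-N6, 5
control offspring C1-C5).

These are published summary-level values — per-library alignment totals,
the biotype census of the 16,014 expressed genes, the co-expression screen
tallies, and group-mean plasma lipids — usable as worked-example inputs for
the report operations. The underlying per-gene count matrix is not public;
synthetic matrices with the same design come from :mod:`lncscreen.synthetic`.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "pomc_alignment_stats",
    "pomc_composition_counts",
    "pomc_screen_counts",
    "pomc_lipid_means",
]

_ALIGNMENT_ROWS = [
    # sample, input read-pairs, uniquely mapped read-pairs
    ("N1", 39_371_421, 28_694_853),
    ("N2", 33_778_273, 23_411_127),
    ("N3", 37_980_952, 26_573_624),
    ("N4", 43_271_579, 31_630_187),
    ("N5", 98_021_209, 67_023_419),
    ("N6", 25_381_274, 18_901_075),
    ("C1", 43_903_675, 28_076_176),
    ("C2", 31_996_428, 22_462_184),
    ("C3", 39_669_137, 26_617_656),
    ("C4", 31_587_579, 23_443_335),
    ("C5", 46_728_455, 33_418_612),
]


def pomc_alignment_stats() -> tuple[pd.DataFrame, pd.Series]:
    """Per-library alignment statistics and the sample -> group mapping."""
    df = pd.DataFrame(
        _ALIGNMENT_ROWS, columns=["sample_id", "input_read_pairs", "uniquely_mapped"]
    ).set_index("sample_id")
    groups = pd.Series(
        ["nicotine"] * 6 + ["control"] * 5, index=df.index, name="group"
    )
    return df, groups


def pomc_composition_counts() -> dict:
    """Biotype census of the 16,014 genes expressed above 1 mean CPM."""
    return {
        "total": 16_014,
        "top": {"protein_coding": 13_539, "ncRNA": 1_708, "pseudogene": 767},
        "ncRNA": {"lncRNA": 1_124, "short_ncRNA": 265, "processed_transcript": 319},
        "lncRNA": {
            "lincRNA": 509,
            "antisense": 551,
            "sense_intronic": 59,
            "sense_overlapping": 4,
            "three_prime_overlapping": 1,
        },
        "short_ncRNA": {"miRNA": 116, "snoRNA": 81, "snRNA": 20, "rRNA": 10, "miscRNA": 38},
        # gene classes overlapped by expressed antisense lncRNAs
        "antisense_targets": {"protein_coding": 529, "ncRNA": 61, "pseudogene": 15},
    }


def pomc_screen_counts() -> dict:
    """Tallies of the lncRNA / nearest-coding-gene co-expression screen."""
    return {
        "lnc_ranked": 1_119,
        "lnc_examined": 1_053,
        "coding_examined": 991,
        "pairs_examined": 1_096,
        "significant": {"total": 82, "antisense": 41, "lincRNA": 34, "sense_intronic": 7},
        "positive": 59,
        "negative": 23,
        "gene_overlap": 65,
        "promoter_overlap": 29,
        "enhancer_transcribed": 1,
    }


def pomc_lipid_means() -> dict[str, dict[str, float]]:
    """Group-mean plasma lipids (mg/dl) of the offspring cohorts after 16
    weeks of standard (STD) or high-fat (HFD) diet."""
    return {
        "nicotine_STD": {"TG": 48.1, "TotChol": 67.5, "HDL": 50.6},
        "control_STD": {"TG": 44.6, "TotChol": 64.7, "HDL": 48.9},
        "nicotine_HFD": {"TG": 61.9, "TotChol": 156.5, "HDL": 124.3},
        "control_HFD": {"TG": 67.0, "TotChol": 166.8, "HDL": 125.9},
    }
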