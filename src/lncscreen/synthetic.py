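"""Synthetic annotation + count-matrix generator with planted structure.

Emulates an 11-sample (6 exposed vs 5 control) bulk RNA-seq count matrix
over ~16,000 expressed genes whose biotype census follows the composition
of a hypothalamic POMC-neuron transcriptome (84.5 % protein-coding, the
lncRNA mix dominated by antisense and lincRNA genes, etc.), with:

* negative-binomial counts (single global dispersion) around log-normal
  per-gene baselines,
* planted lncRNA/coding pairs whose per-sample rates share a latent
  log-normal factor calibrated so the expected count-level Pearson
  correlation approximates a target r (NB sampling attenuates the rate
  correlation; the calibration inverts that attenuation analytically and
  caps at the achievable maximum),
* one (or more) planted fold-change gene(s) whose exposed-group mean is
  multiplied by the fold,
* enhancer intervals covering designated lncRNA TSSs.

Every gene's geometry is constructed to realize its positional subclass
exactly (antisense genes truly overlap a coding gene on the opposite
strand, sense-intronic genes sit inside a coding intron, and so on), so the
geometric classifier and the interval index can be exercised end to end.
The full bundle is a pure function of the config (seeded determinism).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotationSet
from .expression import CountMatrix
from .gtfio import write_bed, write_gtf
from .models import GeneModel, GenomicInterval

__all__ = [
    "PlantedPair",
    "PlantedDE",
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_annotation",
    "generate_counts",
    "write_fixture_bundle",
    "DEFAULT_BIOTYPE_CENSUS",
]

# Reference biotype census (counts over 16,014 expressed genes) used to set
# default per-leaf gene numbers proportionally.
DEFAULT_BIOTYPE_CENSUS: dict[str, int] = {
    "protein_coding": 13_539,
    "pseudogene": 767,
    "processed_transcript": 319,
    "lincRNA": 509,
    "antisense": 551,
    "sense_intronic": 59,
    "sense_overlapping": 4,
    "three_prime_overlapping": 1,
    "miRNA": 116,
    "snoRNA": 81,
    "snRNA": 20,
    "rRNA": 10,
    "miscRNA": 38,
}

PAIR_GEOMETRIES = (
    "antisense-overlap",
    "adjacent-with-promoter-overlap",
    "adjacent-no-promoter",
    "sense-intronic",
)

_GEOMETRY_SUBCLASS = {
    "antisense-overlap": "antisense",
    "adjacent-with-promoter-overlap": "lincRNA",
    "adjacent-no-promoter": "lincRNA",
    "sense-intronic": "sense_intronic",
}


@dataclass(frozen=True)
class PlantedPair:
    """A batch of planted co-expressed lncRNA/coding pairs of one geometry."""

    geometry: str
    target_r: float
    count: int
    baseline_cpm: float = 50.0

    def __post_init__(self) -> None:
        if self.geometry not in PAIR_GEOMETRIES:
            raise ValueError(f"unknown pair geometry {self.geometry!r}")
        if not -1 < self.target_r < 1:
            raise ValueError("|target r| must be < 1")
        if self.count < 0 or self.baseline_cpm <= 0:
            raise ValueError("count must be >= 0 and baseline CPM positive")

    @property
    def subclass(self) -> str:
        return _GEOMETRY_SUBCLASS[self.geometry]


@dataclass(frozen=True)
class PlantedDE:
    """A planted fold-change gene; ``baseline_cpm`` is the all-sample mean
    CPM it should attain (the control mean is derived from the fold)."""

    fold: float
    biotype: str = "antisense"
    baseline_cpm: float = 4.5

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")


def _default_planted_pairs() -> list[PlantedPair]:
    return [
        PlantedPair("antisense-overlap", 0.9, 7),
        PlantedPair("adjacent-with-promoter-overlap", 0.9, 7),
        PlantedPair("sense-intronic", 0.9, 6),
    ]


def _default_planted_de() -> list[PlantedDE]:
    return [PlantedDE(fold=80.0, biotype="antisense", baseline_cpm=4.5)]


@dataclass
class SyntheticConfig:
    """Everything the generator needs; the bundle is a pure function of it."""

    seed: int = 0
    n_exposed: int = 6
    n_control: int = 5
    n_genes: int = 16_000
    depth: int = 1_000_000  # read-pairs per sample
    log2_cpm_mean: float = 3.0
    log2_cpm_sd: float = 2.0
    dispersion: float = 0.1  # NB: var = mu + dispersion * mu^2
    pair_sigma: float = 1.0  # lognormal latent sd (natural-log scale)
    planted_pairs: list[PlantedPair] = field(default_factory=_default_planted_pairs)
    planted_de: list[PlantedDE] = field(default_factory=_default_planted_de)
    n_enhancers: int = 1  # enhancers covering the first planted lncRNA TSSs
    biotype_census: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_exposed < 1 or self.n_control < 1:
            raise ValueError("both groups need at least one sample")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not self.biotype_census:
            self.biotype_census = scale_census(DEFAULT_BIOTYPE_CENSUS, self.n_genes)
        if sum(self.biotype_census.values()) != self.n_genes:
            raise ValueError("biotype census must sum to n_genes")

    @property
    def sample_ids(self) -> list[str]:
        return [f"N{i + 1}" for i in range(self.n_exposed)] + [
            f"C{i + 1}" for i in range(self.n_control)
        ]

    @property
    def group_labels(self) -> pd.Series:
        return pd.Series(
            ["nicotine"] * self.n_exposed + ["control"] * self.n_control,
            index=self.sample_ids,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        if "planted_pairs" in d:
            d["planted_pairs"] = [PlantedPair(**p) for p in d["planted_pairs"]]
        if "planted_de" in d:
            d["planted_de"] = [PlantedDE(**p) for p in d["planted_de"]]
        return cls(**d)


def scale_census(census: dict[str, int], n_genes: int) -> dict[str, int]:
    """Scale a reference census to n_genes by largest remainder, keeping
    every non-empty leaf at >= 1 gene where possible."""
    total = sum(census.values())
    raw = {k: v * n_genes / total for k, v in census.items()}
    out = {k: int(np.floor(v)) for k, v in raw.items()}
    remainder = n_genes - sum(out.values())
    for k in sorted(raw, key=lambda k: raw[k] - out[k], reverse=True)[:remainder]:
        out[k] += 1
    return out


@dataclass
class SyntheticTruth:
    """Ledger of the planted structure, for recovery scoring."""

    pairs: pd.DataFrame  # lnc_id, coding_id, geometry, subclass, target_r, baseline_cpm
    de_genes: pd.DataFrame  # gene_id, fold, baseline_cpm
    enhancer_lnc_ids: list[str]

    def validate_against(self, annot: AnnotationSet) -> None:
        ids = set()
        if len(self.pairs):
            ids |= set(self.pairs["lnc_id"]) | set(self.pairs["coding_id"])
        if len(self.de_genes):
            ids |= set(self.de_genes["gene_id"])
        ids |= set(self.enhancer_lnc_ids)
        missing = [g for g in ids if g not in annot]
        if missing:
            raise ValueError(f"truth references unknown genes: {missing[:5]}")


# ---------------------------------------------------------------------------
# annotation layout


class _Layout:
    """Sequential gene placement on synthetic chromosomes."""

    CHROM_CAP = 25_000_000

    def __init__(self, rng: np.random.Generator) -> None:
        self.rng = rng
        self.chrom_idx = 1
        self.pos = 100_000
        self.genes: list[GeneModel] = []
        self._serial = 0

    @property
    def chrom(self) -> str:
        return f"chr{self.chrom_idx}"

    def next_id(self) -> str:
        self._serial += 1
        return f"SYNG{self._serial:05d}"

    def advance(self, unit_span: int) -> int:
        """Reserve a slot of unit_span bp plus an inter-unit gap; returns
        the unit's start coordinate."""
        gap = int(self.rng.integers(12_000, 30_000))
        start = self.pos
        self.pos = start + unit_span + gap
        if self.pos > self.CHROM_CAP:
            self.chrom_idx += 1
            self.pos = 100_000
            start = self.pos
            self.pos = start + unit_span + gap
        return start

    def add_gene(
        self,
        biotype: str,
        start: int,
        end: int,
        strand: str,
        exon_bounds: list[tuple[int, int]],
    ) -> GeneModel:
        gid = self.next_id()
        gene = GeneModel(
            gene_id=gid,
            gene_name=gid,
            biotype=biotype,
            span=GenomicInterval(self.chrom, start, end, strand),
            exons=[GenomicInterval(self.chrom, a, b, strand) for a, b in exon_bounds],
        )
        self.genes.append(gene)
        return gene


def _coding_exons(start: int, length: int) -> list[tuple[int, int]]:
    """Three exons with two introns inside [start, start + length)."""
    e1 = (start, start + length // 10)
    mid = start + length // 2
    e2 = (mid, mid + length // 10)
    e3 = (start + length - length // 10, start + length)
    return [e1, e2, e3]


def _place_coding(layout: _Layout, start: int, length: int = 8_000, strand: str = "+") -> GeneModel:
    return layout.add_gene("protein_coding", start, start + length, strand, _coding_exons(start, length))


def _place_unit(layout: _Layout, kind: str, lnc_biotype: str | None = None):
    """Place one layout unit; returns (lnc, coding) with None where absent.

    Kinds mirror the pair geometries plus standalone genes; each realizes
    its positional subclass by construction.
    """
    if kind == "standalone_coding":
        start = layout.advance(8_000)
        return None, _place_coding(layout, start)
    if kind == "standalone_small":
        start = layout.advance(1_500)
        strand = "+" if layout.rng.integers(2) == 0 else "-"
        end = start + 1_500
        lnc = layout.add_gene(lnc_biotype, start, end, strand, [(start, start + 600), (end - 600, end)])
        return lnc, None
    if kind == "antisense-overlap":
        start = layout.advance(8_000)
        coding = _place_coding(layout, start, strand="+")
        # opposite strand, overlapping exonic/intronic sequence
        ls, le = start + 1_500, start + 5_500
        lnc = layout.add_gene("antisense", ls, le, "-", [(ls, ls + 700), (le - 700, le)])
        return lnc, coding
    if kind == "sense-intronic":
        start = layout.advance(8_000)
        coding = _place_coding(layout, start, strand="+")
        # inside intron 1 ([start+800, start+4000) for length 8000), same strand
        ls, le = start + 1_200, start + 3_200
        lnc = layout.add_gene("sense_intronic", ls, le, "+", [(ls, le)])
        return lnc, coding
    if kind == "sense-overlapping":
        start = layout.advance(14_000)
        end = start + 14_000
        lnc = layout.add_gene(
            "sense_overlapping", start, end, "+", [(start, start + 400), (end - 400, end)]
        )
        coding = _place_coding(layout, start + 2_000, length=6_000, strand="+")
        return lnc, coding
    if kind == "three-prime-overlap":
        start = layout.advance(10_000)
        coding = _place_coding(layout, start, length=8_000, strand="+")
        # overlap confined to the coding 3'-most exon region [start+7200, start+8000)
        ls, le = start + 7_400, start + 9_400
        lnc = layout.add_gene("three_prime_overlapping", ls, le, "+", [(ls, le)])
        return lnc, coding
    if kind == "adjacent-with-promoter-overlap":
        # lncRNA inside the coding 10-kb upstream window, no span overlap
        start = layout.advance(16_000)
        ls, le = start, start + 4_000
        lnc = layout.add_gene("lincRNA", ls, le, "+", [(ls, ls + 800), (le - 800, le)])
        coding = _place_coding(layout, start + 7_000, strand="+")
        return lnc, coding
    if kind == "adjacent-no-promoter":
        # lncRNA downstream of the coding 3' end: adjacent but outside the
        # upstream promoter window
        start = layout.advance(14_000)
        coding = _place_coding(layout, start, length=8_000, strand="+")
        ls, le = start + 11_000, start + 12_500
        lnc = layout.add_gene("lincRNA", ls, le, "+", [(ls, le)])
        return lnc, coding
    raise ValueError(f"unknown unit kind {kind!r}")


def generate_annotation(
    config: SyntheticConfig,
) -> tuple[AnnotationSet, SyntheticTruth, list[GenomicInterval]]:
    """Lay out the configured gene census on synthetic chromosomes.

    Returns the annotation, the truth ledger (planted pair/DE/enhancer gene
    ids filled in) and the enhancer intervals.
    """
    rng = np.random.default_rng(config.seed)
    census = dict(config.biotype_census)

    def take(leaf: str, n: int = 1) -> None:
        if census.get(leaf, 0) < n:
            raise ValueError(
                f"census exhausted for {leaf!r}: planted structure needs more genes"
            )
        census[leaf] -= n

    layout = _Layout(rng)
    pair_rows = []
    de_rows = []

    # planted pairs first (they consume census slots for both members)
    for batch in config.planted_pairs:
        for _ in range(batch.count):
            take(batch.subclass)
            take("protein_coding")
            lnc, coding = _place_unit(layout, batch.geometry)
            pair_rows.append(
                {
                    "lnc_id": lnc.gene_id,
                    "coding_id": coding.gene_id,
                    "geometry": batch.geometry,
                    "subclass": batch.subclass,
                    "target_r": batch.target_r,
                    "baseline_cpm": batch.baseline_cpm,
                }
            )
    # planted DE genes (lncRNAs hosted like their subclass demands)
    for planted in config.planted_de:
        take(planted.biotype)
        if planted.biotype == "antisense":
            take("protein_coding")
            gene, _coding = _place_unit(layout, "antisense-overlap")
        elif planted.biotype in ("lincRNA", "protein_coding", "pseudogene"):
            kind = "standalone_coding" if planted.biotype == "protein_coding" else "standalone_small"
            gene, coding = _place_unit(layout, kind, lnc_biotype=planted.biotype)
            gene = gene or coding
        else:
            gene, _ = _place_unit(layout, "standalone_small", lnc_biotype=planted.biotype)
        de_rows.append(
            {"gene_id": gene.gene_id, "fold": planted.fold, "baseline_cpm": planted.baseline_cpm}
        )

    # background genes: geometry-realizing units for every remaining leaf
    hosted = {
        "antisense": "antisense-overlap",
        "sense_intronic": "sense-intronic",
        "sense_overlapping": "sense-overlapping",
        "three_prime_overlapping": "three-prime-overlap",
    }
    unit_plan: list[tuple[str, str | None]] = []
    for leaf, kind in hosted.items():
        n = census.get(leaf, 0)
        take("protein_coding", n)
        unit_plan.extend([(kind, None)] * n)
        census[leaf] = 0
    for leaf in ("lincRNA", "pseudogene", "processed_transcript", "miRNA", "snoRNA", "snRNA", "rRNA", "miscRNA"):
        unit_plan.extend([("standalone_small", leaf)] * census.get(leaf, 0))
        census[leaf] = 0
    unit_plan.extend([("standalone_coding", None)] * census.get("protein_coding", 0))
    census["protein_coding"] = 0
    rng.shuffle(unit_plan)  # interleave biotypes along the chromosomes
    for kind, leaf in unit_plan:
        _place_unit(layout, kind, lnc_biotype=leaf)

    annot = AnnotationSet(layout.genes)
    pairs = pd.DataFrame(
        pair_rows,
        columns=["lnc_id", "coding_id", "geometry", "subclass", "target_r", "baseline_cpm"],
    )
    de_genes = pd.DataFrame(de_rows, columns=["gene_id", "fold", "baseline_cpm"])

    # enhancers cover the TSSs of the first planted-pair lncRNAs (falling
    # back to planted DE genes when there are no pairs)
    enhancer_ids = list(pairs["lnc_id"][: config.n_enhancers])
    if len(enhancer_ids) < config.n_enhancers:
        enhancer_ids += list(de_genes["gene_id"][: config.n_enhancers - len(enhancer_ids)])
    enhancers = []
    for gid in enhancer_ids:
        gene = annot[gid]
        enhancers.append(
            GenomicInterval(gene.chrom, max(gene.tss - 700, 0), gene.tss + 701, "+")
        )
    truth = SyntheticTruth(pairs=pairs, de_genes=de_genes, enhancer_lnc_ids=enhancer_ids)
    truth.validate_against(annot)
    return annot, truth, enhancers


# ---------------------------------------------------------------------------
# counts


def latent_correlation(
    target_r: float, baseline_cpm: float, depth: float, dispersion: float, sigma: float
) -> float:
    """Latent-factor correlation needed so the count-level Pearson
    correlation of a planted pair approximates ``target_r``.

    The per-sample rate is lognormal (sd ``sigma`` on the natural-log
    scale); NB sampling attenuates the rate correlation by
    v_rate / (v_rate + v_nb). The required rate correlation is capped at
    the achievable range, so high targets at low expression realize the
    attenuation ceiling rather than the target itself.
    """
    mu = baseline_cpm * depth / 1e6
    ev = np.exp(sigma**2)
    v_rate = mu**2 * (ev - 1.0)
    v_nb = mu + dispersion * mu**2 * ev
    attenuation = v_rate / (v_rate + v_nb)
    rho_rate = target_r / attenuation
    lo = (np.exp(-(sigma**2)) - 1.0) / (ev - 1.0)  # most negative reachable
    rho_rate = float(np.clip(rho_rate, lo + 1e-9, 1.0))
    return float(np.log1p(rho_rate * (ev - 1.0)) / sigma**2)


def generate_counts(
    config: SyntheticConfig, annot: AnnotationSet, truth: SyntheticTruth
) -> CountMatrix:
    """Draw the NB count matrix with the planted structure applied."""
    rng = np.random.default_rng(config.seed + 1)  # independent of the layout stream
    gene_ids = [g.gene_id for g in annot]
    index = {gid: i for i, gid in enumerate(gene_ids)}
    n_genes = len(gene_ids)
    n = config.n_exposed + config.n_control

    cpm = 2.0 ** rng.normal(config.log2_cpm_mean, config.log2_cpm_sd, size=n_genes)
    # planted overrides
    for row in truth.pairs.itertuples():
        cpm[index[row.lnc_id]] = row.baseline_cpm
        cpm[index[row.coding_id]] = row.baseline_cpm
    fold_mult = np.ones((n_genes, n))
    for row in truth.de_genes.itertuples():
        # control-group CPM chosen so the all-sample mean CPM equals baseline
        control_cpm = row.baseline_cpm * n / (config.n_exposed * row.fold + config.n_control)
        cpm[index[row.gene_id]] = control_cpm
        fold_mult[index[row.gene_id], : config.n_exposed] = row.fold
    # safety net: keep expected column sums well below the library size
    total = cpm.sum()
    if total > 0.9e6:
        planted = np.zeros(n_genes, dtype=bool)
        for row in truth.pairs.itertuples():
            planted[index[row.lnc_id]] = planted[index[row.coding_id]] = True
        for row in truth.de_genes.itertuples():
            planted[index[row.gene_id]] = True
        excess = total - cpm[planted].sum()
        cpm[~planted] *= (0.9e6 - cpm[planted].sum()) / excess

    mu = cpm[:, None] * np.ones((1, n)) * (config.depth / 1e6)
    mu *= fold_mult

    # shared latent lognormal factor for planted pairs
    sigma = config.pair_sigma
    for row in truth.pairs.itertuples():
        rho_z = latent_correlation(
            row.target_r, row.baseline_cpm, config.depth, config.dispersion, sigma
        )
        a = np.sqrt(abs(rho_z))
        b = np.sqrt(max(1.0 - abs(rho_z), 0.0))
        f = rng.normal(size=n)
        z1 = a * f + b * rng.normal(size=n)
        z2 = np.sign(rho_z) * a * f + b * rng.normal(size=n)
        mu[index[row.lnc_id]] *= np.exp(sigma * z1 - sigma**2 / 2.0)
        mu[index[row.coding_id]] *= np.exp(sigma * z2 - sigma**2 / 2.0)

    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)

    frame = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=config.sample_ids)
    colsums = frame.sum(axis=0)
    if (colsums > config.depth).any():
        raise ValueError(
            "generated exonic counts exceed the configured depth; lower the "
            "baseline expression or raise the depth"
        )
    return CountMatrix(
        counts=frame,
        group_labels=config.group_labels,
        library_sizes=pd.Series(config.depth, index=config.sample_ids),
    )


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full fixture bundle; byte-reproducible given
    the config. Returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annot, truth, enhancers = generate_annotation(config)
    matrix = generate_counts(config, annot, truth)
    paths = {
        "gtf": outdir / "annotation.gtf",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "bed": outdir / "enhancers.bed",
        "truth_pairs": outdir / "truth_pairs.tsv",
        "truth_de": outdir / "truth_de.tsv",
        "config": outdir / "config.json",
    }
    write_gtf(annot, paths["gtf"])
    matrix.counts.to_csv(paths["counts"], sep="\t")
    meta = pd.DataFrame(
        {
            "sample_id": matrix.sample_ids,
            "group": matrix.group_labels.values,
            "library_size": matrix.library_sizes.values,
        }
    )
    meta.to_csv(paths["samples"], sep="\t", index=False)
    write_bed(enhancers, paths["bed"])
    truth.pairs.to_csv(paths["truth_pairs"], sep="\t", index=False)
    truth.de_genes.to_csv(paths["truth_de"], sep="\t", index=False)
    with open(paths["config"], "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
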