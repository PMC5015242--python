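# Methods

## Scope and data model

`lncscreen` operates at gene level. A gene is a stranded span with sorted,
non-overlapping exons and a biotype; transcript isoforms are deliberately
out of scope (the analysis design it reproduces quantified genes, not
transcript variants). Coordinates are 0-based half-open internally; GTF I/O
converts to and from the 1-based inclusive convention at the boundary, and
a write/read round trip reproduces models exactly. Strands other than `+`
and `-` are rejected.

## Expression and filtering

CPM divides a gene's exonic read-pair count by the *genome-mapped*
read-pair total of its sample (supplied as the library size in the sample
metadata), times 10⁶ — not by the column sum of exonic counts. The two can
differ materially when many reads map outside annotated exons; a
`column_sum` mode exists for generic reuse. The expression filter keeps
genes whose unweighted mean CPM across all samples is strictly greater
than 1 (the boundary case mean = 1.0 is excluded). Group sizes are not
rebalanced in the mean.

Report rounding is half away from zero: percentages to one decimal,
read-pair means to the nearest integer. The summary mapped percentage is
the mean of per-sample percentages, not the ratio of summed counts; the
two differ (70.5 vs ≈70.0 on the reference alignment table) and the
per-sample mean is the convention reproduced.

## The cis-co-expression screen

For each expressed lncRNA of the three screened positional subclasses
(lincRNA, antisense, sense-intronic), candidates are all overlapped
expressed coding genes or, failing any overlap, the coding gene(s) at
minimal span-to-span gap (ties kept — one lncRNA can therefore contribute
several pairs). Distance is span gap, not TSS-to-TSS: "adjacent or
overlapping" is a statement about gene bodies.

Significance uses the analytic two-tailed critical value
r_crit = t₁₋α/₂,ₙ₋₂ / √(t² + n − 2), with |r| strictly greater than r_crit
required. There is **no multiple-testing correction across pairs**: the
screen reproduces a fixed per-test threshold design, so at α = 0.05 roughly
5 % of independent pairs flag by chance. This is an exploratory screen, not
an inference procedure; treat the pair list accordingly.

Correlation is computed on raw CPM by default (`log2` mode optional). The
choice matters little for strongly co-expressed pairs but raw CPM is the
more literal reading of "linear co-expression" with CPM thresholds.
Zero-variance genes skip their pairs (tallied, not errored). Geometry
annotations: gene overlap is span intersection; promoter overlap intersects
the lncRNA span with the coding gene's 10-kb strand-aware upstream window,
clipped at the chromosome origin; the expression ratio is mean lncRNA CPM
over mean coding CPM, flagged below 0.30; enhancer transcription is
TSS-containment in a BED interval by default (`overlap` mode optional,
since the one documented precedent — an enhancer straddling a coding
promoter and the antisense TSS — is consistent with either reading).

Positional classification: a GTF subclass tag always wins; geometry is
used for untagged or synthetic genes with precedence antisense >
sense-intronic > sense-overlapping > 3′-overlapping > lincRNA. The
3′-overlapping rule (overlap confined to the coding gene's 3′-most exon
region) is a gene-level approximation: UTRs are not encoded in gene-level
models. A same-strand overlap matching no specific geometry falls back to
sense-overlapping.

## Differential expression

The final DE list is the intersection of callers: genes with BH-adjusted
q ≤ 0.05 in *every* supplied call set. The operator is caller-agnostic;
three native callers are built in.

1. **Exact conditional-binomial test.** Counts and library sizes are summed
   within groups; conditional on the total k = k_A + k_B, k_A is
   Binomial(k, L_A/(L_A+L_B)) under equal expression rates. The two-sided p
   sums all outcome probabilities no larger than the observed one
   (minimum-likelihood rule, ties included at a 10⁻⁷ relative tolerance),
   capped at 1; k = 0 gives p = 1. The implementation enumerates outcomes
   with a vectorized log-space pmf and matches brute-force enumeration to
   ~10⁻¹³ for all totals ≤ 200.
2. **Rate likelihood-ratio (G) test** on the same aggregates,
   χ²₁-asymptotic. A second count-based caller with different small-sample
   behaviour.
3. **Exhaustive label-permutation caller**: all 462 relabelings of the
   6-vs-5 design, statistic = moderated t on log2(CPM+1) (group-mean
   difference over pooled SE plus s₀, the median SE across genes). By
   default the permutation null is pooled across genes, refining p-value
   granularity from 1/462 to 1/(462·genes); a per-gene exhaustive mode
   exists.

**Why the default intersection uses callers 1+2 and not the permutation
caller.** Per-gene exhaustive permutation p-values have granularity
1/462 ≈ 0.0022; with ~15,000 tested genes, BH requires ~690 genes at the
minimum p before any q reaches 0.05, while only ~30 null genes tie there —
so a per-gene permutation caller can never enter a q ≤ 0.05 intersection
at this scale. The pooled-null variant resolves the granularity but not
the information deficit: for a gene whose control-group expression is
~0.1 CPM at 10⁶ read-pairs depth, the per-sample log-expression values
carry far less evidence than the aggregated counts, and simulation shows
the pooled caller missing a planted 80-fold gene in ~10 % of seeds where
the count-aggregate callers succeed comfortably. The permutation caller is
therefore reported alongside (its call table is written with the others)
as a distribution-free reference, but the default final list is the
intersection of the two count-aggregate callers — mirroring the practice
of intersecting multiple count-model callers.

**Known limitation, by construction:** aggregation across replicates tests
a *rate* difference, not biological variability. Under biological
(negative-binomial) dispersion both aggregate callers are anti-conservative
— simulated type-I error ≈ 0.2 at nominal 0.05 with dispersion 0.1 — which
is acceptable for recovering a planted large effect but makes the BH q
values optimistic on overdispersed data. The test suite *reports* this
rate rather than asserting it ≤ 0.05.

Fold change is the ratio of group mean CPMs with a 0.01-CPM pseudocount on
both means (configurable). At shallow depth the estimate is unstable for
genes whose lower group mean is far below 1 CPM — with an expected 0.5
control read-pairs, a zero draw drives the ratio to the pseudocount
ceiling — so fold-recovery properties are tested on planted genes whose
both-group means are measurable, while significance-based recovery is
tested at the study scale (4.5 mean CPM, 80-fold).

## Synthetic data generator

The generator emulates the study design so every stage can be exercised
end to end: 11 samples (6 exposed, N1–N6; 5 control, C1–C5), 16,000 genes
with a biotype census proportional to the reference composition (84.5 %
protein-coding; lncRNAs split ≈45/49/5 % lincRNA/antisense/sense-intronic),
and equal per-sample depth. The default depth is 10⁶ read-pairs — a
deliberate desk-scale choice (the real libraries average ~30 × 10⁶); depth
is a config knob and all recovery properties are quoted at the default.

Geometry is constructed, not sampled: every antisense gene truly overlaps
a dedicated coding gene on the opposite strand, sense-intronic genes sit
inside a coding intron, promoter-adjacent planted pairs place the lncRNA
inside the coding gene's 10-kb upstream window without span overlap, and
so on, with 12–30 kb inter-unit gaps guaranteeing unique nearest
neighbours for within-unit pairs. Enhancer intervals are centred on
designated planted lncRNA TSSs.

Counts are negative binomial, var = μ + φμ² with a single global
dispersion φ = 0.1, around per-gene baselines drawn log-normal
(log2 CPM ~ N(3, 2)) — conventional bulk RNA-seq choices; nothing in the
reproduced design specifies distributions. Baselines are rescaled only if
their CPM total would approach the library size.

**Correlation planting.** A planted pair shares a latent standard-normal
factor on the natural-log scale with per-sample rate
μ·exp(σz − σ²/2), σ = 1.0. The latent correlation is calibrated
analytically: rate correlation relates to latent correlation through the
lognormal moment formula, and NB sampling attenuates the count-level
correlation by v_rate/(v_rate + v_NB). The required rate correlation is
the target divided by this attenuation, capped at 1 — so high targets
realize the attenuation ceiling (≈0.855 at the default planted baseline of
50 CPM), not the nominal target. Monte-Carlo checks confirm the mean
realized sample r over 200 planted pairs at target 0.9 lands near 0.85,
within the ±0.15 recovery band, with screen power ≈0.94 at n = 11.
Negative targets are representable only down to the lognormal bound
(e^{−σ²}−1)/(e^{σ²}−1) ≈ −0.21 at σ = 1; strongly negative planted
correlations would need a different coupling and are not provided.

**DE planting.** A planted fold-change gene's control-group CPM is derived
from the requested all-sample mean (default 4.5 CPM, fold 80), and the
exposed-group mean is multiplied by the fold before NB sampling.

The full bundle (GTF, counts TSV, sample metadata, BED, truth tables,
config JSON) is a pure function of the config: identical configs produce
byte-identical files.

**What passing synthetic tests does and does not show.** The generator has
no batch effects, no per-gene dispersion variation, no library-size
variation, no isoform structure, and geometry far cleaner than a real
genome. Recovery results demonstrate that the pipeline's machinery is
correct and calibrated under its own assumptions — not that the thresholds
would behave identically on real tissue data.

## Phenotype formulas

Lipids: VLDL-C = TG/5 and LDL-C = TotChol − HDL-C − VLDL-C, applied
unconditionally; a negative derived LDL-C is flagged, never clipped.
Applying the formulas to group means is exact for the VLDL row (the
derivation is linear) but does not reproduce every published LDL group
mean, consistent with per-animal derivation before averaging; the
control-HFD group is the worked example used. Tolerance-test AUC is the
composite trapezoidal rule over the sampled timepoints, total area above
zero by default with an optional baseline-subtracted mode (clipped at the
baseline). ΔΔCt relative expression is 2^(−ΔΔCt). Daily dose is fluid
volume × concentration (default 200 µg/mL), reported as mass of the
dissolved salt; no free-base conversion is applied.

## Problem sizes and numerical choices

Test and acceptance runs use: null calibration on ~2,300 independent
expressed NB gene pairs; planted-pair recovery on 200 pairs in a
2,500-gene layout; DE recovery on 20 seeds of the full 16,000-gene design;
exact-test verification on all 20,300 (total ≤ 200) outcomes at three
library ratios. The exact test compares pmf values with a 10⁻⁷ relative
tolerance so probability ties survive floating-point roundoff; the
permutation caller clips negative variances arising from catastrophic
cancellation; `critical_r` uses the inverse survival function to keep
precision at extreme α, and returns 1 in the α → 0 limit.
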