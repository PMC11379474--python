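# Methods

This note records the models, conventions, and numerical choices behind
`refeedkit`, what the synthetic data does and does not emulate, and the
design decisions taken where several reasonable options existed.

## Study design and data model

The package targets a five-state feeding time course — `Adlib`, `Fasted`,
`Refed_3h`, `Refed_10h`, `Refed_24h` — with three biological replicates
per state, profiled as gene-level RNA-seq counts and peak-level ATAC-seq
counts, plus per-base transposase cut-count tracks for footprinting. All
genomic coordinates are 0-based half-open (BED convention); synthetic
data lives on a single 10 Mb contig `chrS` (footprinting fixtures on a
separate contig `chrF` so motif windows never collide with gene peaks).

## Negative-binomial differential testing

Counts are modeled as NB with Var(Y) = μ + αμ², a single dispersion α per
feature.

**Size factors** are the median-of-ratios: the median over features with
nonzero counts in every sample of count / geometric mean, rescaled to
geometric mean 1. Rescaling makes factors unique; all downstream
quantities depend only on factor ratios.

**Dispersion.** The per-feature estimate is method-of-moments,
max(0, (s² − μ̄)/μ̄²), with the within-condition variance pooled across
conditions by residual degrees of freedom, then averaged 50/50 with a
trend over log mean and floored at 1e−8. The trend is fitted locally in
20 log-mean quantile bins by moment matching,

    α_bin = (Σ s² − Σ μ̄) / Σ(μ̄² − s²/n),

whose denominator is an unbiased estimate of Σμ². This binned fit is
used instead of a lowess of the per-feature ratios because at n = 3
replicates those ratios are biased low by the correlation between the
sample mean and variance (≈ −13% at α = 0.05), which propagates into
anticonservative Wald tests; the binned fit removes the bias by summing
moments before taking the ratio. With 3v3 replication the resulting
test's null p ≤ 0.05 rate is ≈ 0.06 — the residual inflation is the
price of plugging an estimated dispersion into a Wald test at this
sample size, and is shared by standard count-based DE tools.

**Wald contrast.** Per group the log mean β = log q is fitted by Newton
iteration on the NB score equation with sample size factors as offsets;
the expected information is I = Σ μ/(1 + αμ). The statistic is
(β_B − β_A)/√(1/I_A + 1/I_B) against a standard normal. Features with a
zero-count group get the half-count continuity value q = 0.5/Σs so the
statistic stays finite. The *reported* fold change is the ratio of mean
normalized counts with pseudocount 0.5 added to both means (bounded for
zero-count features); the pseudocount does not enter the likelihood.
BH adjustment runs per contrast over features with baseMean ≥ 1
(independent filtering); features that are all-zero across all samples
are dropped before testing. Regulation calls use FC ≥ 1.5 and adjusted
p ≤ 0.05 with inclusive boundaries.

## Kinetic patterns

The fasting-regulated universes collect genes significantly higher
(induced) or lower (repressed) in `Fasted` than in *at least one* fed
state. Discovery clustering is k-means (k = 3, ≤ 1,000 iterations, best
of 10 seeded restarts by total within-cluster distance, ties to the
lowest restart index) on z-scored condition means with distance
1 − Pearson r; centroids are re-standardized each iteration so the
metric stays correlation-like. Features with zero variance across
conditions carry no shape information under this metric and are
excluded with a log entry. Clusters for the early patterns A–C are named
by the schematic template their centroid best correlates with; A–C are
deliberately *not* given hard cutoffs.

The refeeding patterns are pure functions of the regulation-call tables
for five contrasts (Fasted, Refed_3h, Refed_10h, Refed_24h each vs
Adlib, plus Fasted vs Refed_24h):

- **E (overshoot)**: repressed in fasting vs ad lib AND induced at 24 h
  vs ad lib.
- **D (recovered)**: repressed in fasting vs both ad lib and 24 h
  refeeding, and not induced at 24 h vs ad lib.
- **G (early-induced)**: induced at 3 h vs ad lib and in no other
  condition.
- **F (late-induced)**: induced at 10 h or 24 h vs ad lib, not induced
  in fasting or at 3 h.

The rule texts overlap: a gene repressed in fasting and induced late
satisfies both E and F (F's "not induced in fasting" does not exclude
repression), and one can construct D∩G and D∩F cases. The classifier
resolves them with the fixed precedence **E > D > G > F**, which makes
the taxonomy a partition; the fasting-repression requirement is what
separates an overshoot gene from a merely late-induced one, so E wins
over F, and the recovery rule (two repression calls) is more specific
than the induction-only rules, so D precedes G and F. The test suite
checks the classifier against an independent enumeration of all 3⁵
status combinations.

## Lipid-pathway gene groups

User-supplied gene groups (LIPO, CHOL, AID or custom; non-overlapping by
contract) pass two independent filters: expressed in liver
(max across condition-mean RPKM ≥ 1, inclusive — the condition is not
specified more precisely, so the maximum is the permissive reading) and
repressed by fasting (membership in the fasting-repressed universe).
Because the predicates are independent, filter order cannot change the
result. Group comparisons of fasting-repression FC (Adlib/Fasted) and
refeeding-induction FC (Refed_24h/Adlib) use a two-sided Mann–Whitney U,
exact when both groups have ≤ 20 genes; a rank test is the conservative
choice for small curated groups with skewed FC distributions.

## Signal-track conventions

Tracks are scaled to a genome-wide total of 1e7 (idempotent). Site
quantification sums scaled per-base signal in [center − 200,
center + 200) with center = floor((start + end)/2); windows crossing a
contig edge are zero-clipped and flagged. Aggregate profiles are 10 bp
bins over ±4 kb; the bin value is the per-site mean of the summed signal
in the bin, so summing the central 40 bins times the site count
reproduces the ±200 bp windowed total exactly. Box-plot style summaries
report the 10th–90th percentile range. Promoter-proximal means the site
center lies within −1 kb…+0.1 kb of a TSS in transcription orientation
(the genomic window flips for minus-strand genes); unknown strands are
treated as '+' and logged.

## Enhancer classes and gene linkage

Peak contrasts use the identical NB machinery and cutoffs as genes.
Overshoot and recovered enhancers follow the E and D rules;
refeeding-activated means induced at Refed_24h vs Adlib (a superset of
overshoot); genotype classes (increased/decreased) come from a
WT-vs-knockout contrast. Each peak is linked to the gene with minimal
|peak center − TSS|, ties broken by smaller distance then
lexicographically smaller gene id; no distance cap is applied by
default ("proximal" = "is the nearest gene of"), since any cap value
would be arbitrary — a configurable maximum distance can be layered on
by filtering the link table. Fraction comparisons between gene sets use
Fisher's exact test on the 2×2 has/has-not table.

## Bivariate footprinting

Per motif, cut counts are pooled over occurrences inside accessible
sites on a fixed −200…+199 bp offset grid around the occurrence center
(minus-strand occurrences reversed). Per-bp density is
(counts + 0.5)/n_occurrences; the pseudocount bounds the logs for
sparse motifs and is negligible at realistic coverage. FA is the log2
mean density over the flank band 35 < |offset| ≤ 200 bp; FPD is FA
minus the log2 mean density over the interior |offset| ≤ ⌈w/2⌉. The
flank band and interior definition are this package's normative
reconstruction of the bivariate footprinting statistic — the 35 bp
inner exclusion keeps shoulder effects at motif edges out of the flank,
and motifs ≥ 70 bp wide are refused because their interior would reach
the band. Multiplying a track by c shifts FA by log2 c and leaves FPD
fixed, so condition deltas are insensitive to sequencing depth after
scaling.

Condition deltas (ΔFA, ΔFPD) over all motifs are summarized as a bag
plot: Tukey halfspace depth is computed exactly by an angular sweep
(O(n log n) per point; coincident points share every halfplane); the
bag is the convex hull of the smallest depth region holding ≥ 50% of
points; the fence inflates the bag ×3 about the depth median (the
centroid of maximal-depth points); points outside the fence are
outliers, and the jointly-increased quadrant (ΔFA > 0, ΔFPD > 0) is
reported separately. Fewer than 10 motifs make depth contours
degenerate and are refused; a collinear bag falls back to a radial
fence. Motif enrichment of a site subset uses a one-sided
hypergeometric test against the full accessible landscape with BH
across motifs.

## Synthetic data: what it emulates, and what it does not

The generator draws NB counts (gamma–Poisson, shared α, default 0.05)
with log-uniform base means on [20, 2000], log-normal(0, 0.1) library
size factors, and per-pattern mean-multiplier templates, e.g. pattern E
= (1, 0.25, 0.5, 2.5, 3) over the five conditions. Default effect sizes
put the planted contrasts at ≥ 2× the FC cutoff so power at n = 3 is
near 1; a hard mode halves every effect on the log scale for power
studies. Enhancer peaks are placed so a planted peak's center is nearer
its target TSS than any neighbour's (verified against the nearest-gene
mapper at generation time), with the count of linked peaks equal to
floor(fraction × n) of the target genes. Cut tracks set the expected
per-base rate to flank_rate within ±200 bp of an occurrence and
flank_rate × interior_fraction inside the motif, optionally Poisson
noised; per-motif, per-condition overrides of both the interior
fraction and the flank rate plant condition-specific footprint
deepening and accessibility gain.

Not emulated: read-level artefacts (GC and transposase sequence bias,
PCR duplicates, mappability), genuine gene-gene correlation,
overdispersion heterogeneity across features, overlapping/nested peaks
near planted links, and multi-contig genomes. Passing tests therefore
demonstrate the correctness and calibration of the statistical chain
under the stated model, not robustness to alignment- or library-level
artefacts in real data.

## Problem sizes and determinism

The demo runs 5,000 genes (300 each of A–C, 200 each of D–G, 3,300
flat), 3,000 peaks, and 50 motifs × 50 occurrences — sizes chosen so a
full run finishes in seconds while leaving hundreds of features per
planted class for stable precision/recall estimates. Every stochastic
step takes an explicit seed (package default 17); identically seeded
runs are byte-identical, and the run manifest records thresholds,
sizes, and an SHA-256 per output file.

## Known limitations

- The Wald test is mildly anticonservative at n = 3 (null p ≤ 0.05 rate
  ≈ 0.06); for designs with ≥ 5 replicates it is nearly exact.
- Fold-change cutoffs apply to raw (pseudocounted) fold changes; no
  shrinkage estimator is provided.
- k-means with correlation distance is a local optimizer; restarts
  mitigate but do not guarantee the global optimum.
- The nearest-TSS linkage ignores chromatin contact data; "proximal"
  statements are purely distance-based.
- Halfspace depth is exact but quadratic overall; clouds beyond ~5,000
  motifs would need an approximate depth.
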