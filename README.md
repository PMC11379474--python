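# refeedkit

Kinetic analysis of fasting/refeeding genomic time courses: differential
testing, pattern classification, enhancer–gene linkage, and bivariate
transcription-factor footprinting, with a synthetic-data generator that
plants ground truth for every step.

## The problem

When an animal is refed after a prolonged fast, the liver does not simply
return to its ad libitum state: transcription is reorganized in waves, and
some pathways (notably lipogenesis) *overshoot* — their expression and the
accessibility of their enhancers rise above pre-fasting levels. Analyzing
such a time course (ad libitum → fasted → refed at several time points,
measured by RNA-seq and ATAC-seq with ~3 replicates per state) requires a
chain of statistical steps: pairwise differential tests on count matrices,
classification of each gene's kinetic pattern from the resulting calls,
curation filters for pathway gene groups, linkage of accessibility peaks
to nearby genes, and motif-level footprint statistics that point to the
transcription factors driving the changes. `refeedkit` implements that
chain as a tested, reusable library for people building or evaluating
fasting/refeeding (or any multi-state recovery) analyses.

## Models and statistics

- **Differential testing** (`refeedkit.diffexpr`). Counts for feature *i*
  in sample *j* are modeled as NB(μ_ij, α_i) with Var = μ + αμ²,
  μ_ij = s_j q_ij, where s_j are median-of-ratios size factors. Each
  two-condition contrast is a Wald test on Δβ = log q_B − log q_A with
  standard errors from the expected information, per-contrast
  Benjamini–Hochberg adjustment, and the study's regulation rule:
  induced ⇔ FC ≥ 1.5 and adj. p ≤ 0.05 (inclusive), repressed for the
  mirror case. Dispersions are method-of-moments estimates shrunk 50/50
  toward a binned moment-matching trend over log mean.
- **Kinetic patterns** (`refeedkit.patterns`). Fasting-induced and
  -repressed universes (significant vs ≥ 1 fed state), k-means over
  z-scored condition means with a 1 − Pearson-r distance, and explicit
  rules for the refeeding patterns: D *recovered*, E *overshoot*,
  F *late-induced*, G *early-induced*, resolved by the precedence
  E > D > G > F.
- **Enhancers** (`refeedkit.enhancers`). Peaks are classified with the
  same cutoffs as genes (overshoot / recovered / refeeding-activated),
  linked to the gene with the nearest TSS (deterministic tie-breaks), and
  summarized as proximal-enhancer fractions compared between gene sets by
  Fisher's exact test.
- **Footprinting** (`refeedkit.footprinting`). For each motif, cut counts
  are pooled strand-orientedly over occurrences within accessible sites;
  FA = log2 mean flank density (35 < |offset| ≤ 200 bp) and
  FPD = FA − log2 mean interior density (|offset| ≤ ⌈w/2⌉). Condition
  deltas (ΔFA, ΔFPD) over all motifs are summarized by a bag plot: Tukey
  halfspace depth (exact angular sweep), bag = convex hull of the 50%
  deepest points, fence = bag inflated ×3 about the depth median, points
  outside the fence flagged. Motif enrichment of a site subset uses a
  hypergeometric test against the full accessible landscape.
- **Synthetic data** (`refeedkit.simulate`). NB counts over the default
  design (5 conditions × 3 replicates) with per-pattern mean-multiplier
  templates, enhancer peaks planted so their nearest TSS is a chosen
  target gene, and per-base cut tracks with motif-centered footprints
  whose depth and flanking rate can differ by condition.

## Worked example

Run the self-contained demo: it simulates a full study (5,000 genes,
3,000 peaks, 50 motifs; 200 genes planted per pattern D–G), runs every
stage, and writes contrasts, pattern calls, group reports, enhancer
links, footprint statistics and a truth-vs-called confusion matrix:

```bash
refeedkit demo --seed 17 --outdir demo_out
```

prints

```
demo complete; manifest at demo_out/manifest.json
  n_fasting_induced: 980
  n_fasting_repressed: 890
  pattern_counts: {'none': 4171, 'G': 214, 'D': 208, 'F': 207, 'E': 200}
  proximal_fraction_overshoot: 0.39
  proximal_fraction_recovered: 0.004807692307692308
  proximal_fisher_p: 3.369434699805945e-27
  bagplot_outliers: ['M00', 'M12', 'M18']
  top_enriched_motif: M00
```

Reading the output: of the 5,000 simulated genes, 980 are called
fasting-induced and 890 fasting-repressed (the planted A–C and D–E
universes plus test noise). The four refeeding patterns are recovered at
close to their planted 200 genes each. 39% of overshoot genes have a
proximal refeeding-activated enhancer — the generator planted links for
40% — versus 0.5% of recovered genes (Fisher p ≈ 3e−27). The motif with
a planted condition-specific footprint deepening (`M00`) lands in the
jointly-increased quadrant of the ΔFA/ΔFPD bag plot and is the top
enriched motif in overshoot peaks. Per-pattern precision/recall against
truth is written to `demo_out/patterns/confusion_defg.tsv`.

The same stages run on your own TSV/BED inputs via `refeedkit run
--counts ... --peaks ... --stages diffexpr,patterns,enhancers` (see
`refeedkit --help`); every stage is also a plain library call.

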