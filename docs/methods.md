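# Methods

## Scope and model

`tftargets` implements the downstream half of a TF direct-target study: it
consumes final per-condition ChIP peak calls and per-contrast DE tables
(it does not align reads, call peaks or estimate DE from counts) and
produces direct-target calls, cross-condition reprogramming fates, and the
associated statistics. The experimental design it models is a 2×2 cross of
genotype (control vs. disease) and modifier silencing (scramble vs. modifier
siRNA), with two DE contrasts per condition: TF nuclear induction and TF
knockdown, each against the condition's own baseline.

All genomic coordinates are 0-based half-open (BED convention) and the TSS
annotation is declared 0-based; exactly one TSS row per gene is required —
collapsing multi-isoform genes to a canonical TSS is the annotation
preparation step's responsibility. Gene identity across tables is exact
string matching on `gene_id`.

## Target calling

- **Binding window.** A gene is bound iff a peak `[start, end)` intersects
  the inclusive window `[max(0, tss − W), tss + W]`; equivalently
  `start ≤ tss + W` and `end > tss − W`. `W` defaults to 20,000 bp, the
  distance within which TF binding is commonly associated with regulation of
  the nearest genes, and the window is strand-symmetric. A peak may be
  assigned to several genes; `max_peak_score` per gene is the maximum over
  assigned peaks. Peaks on chromosomes absent from the annotation are
  skipped with a logged count rather than failing the run.
- **Regulation.** Direction is `up` iff `padj ≤ α` and `log2FC ≥ lfc_min`
  (and > 0), `down` symmetrically; `α = 0.05`, `lfc_min = 0` by default,
  both exposed in the config. A `log2FC` of exactly 0 is `none` even at
  `lfc_min = 0` (the up/down rules would otherwise both apply). Genes
  missing from a DE table, or with missing (`NA`) adjusted p, are treated as
  not regulated and counted in the log.
- **Knockdown refinement** promotes an induction-supported target whose
  knockdown contrast passes `α`. Because induction and knockdown can alter
  regulation differently, the knockdown fold-change sign is unconstrained by
  default; `require_kd_anticorrelation` enforces the opposite sign to the
  induction direction. Refinement never promotes non-targets, so the
  knockdown-supported class is always a subset of the induction class.

## Reprogramming classification

Fate is **membership-based**: it compares target membership between the two
scramble conditions only, which makes the partition identities
(`targets(control) = conserved + lost`, `targets(disease) = conserved +
gained`) hold by construction; direction concordance for conserved genes is
reported separately rather than folded into the fate. The control+modifier
condition does not enter fate or dependence — it is summarised as a target
count — because dependence is defined by whether the modifier knockdown in
the *disease* background restores the control status (dependent) or leaves
the disease status unchanged (independent). With `strict_direction` enabled,
a membership match against a member baseline additionally requires the same
regulation direction; mismatches fall into an `unresolved` bucket. Without
it, dependence is always resolved for lost/gained genes, because the two
scramble baselines differ and the knockdown membership equals exactly one
of them.

## Occupancy statistics

Per condition, the "regulated genes" are those with a significant induction
direction; the bound fraction of those genes and the maximal peak score of
the bound ones feed two tests:

- **Pairwise proportions:** the two-sample proportion chi-square with
  continuity correction, with the Yates term clamped at |observed −
  expected| so the statistic is never negative — exactly R's `prop.test` —
  Holm-adjusted across the six condition pairs. The continuity correction
  makes the test mildly conservative (a measured type-I error around 2–4% at
  a few hundred to a few thousand genes per group); that is a property of
  the chosen, R-compatible test, not of its implementation here.
- **Score distributions:** scores are pooled and cut at pooled quantiles
  (deciles by default; duplicated edges from ties are merged), and the
  per-condition bin counts form an R×C table tested by Pearson chi-square
  (no continuity correction, as in R's `chisq.test` for R×C tables). The
  global test uses all conditions; pairwise comparisons re-pool and re-bin
  each pair and are Holm-adjusted. A warning is emitted when any expected
  count falls below 5. Conditions must each contribute at least `n_bins`
  observations.

All tests are two-sided, following the defaults of the R functions they
mirror.

## Set statistics

- **Ortholog mapping** picks one best target per source gene: one-to-one
  relations first, then highest confidence, then the lexicographically
  smallest target id (a deterministic tie-break). Unmapped sources are
  reported, not errors.
- **Overlap significance** is the hypergeometric upper tail P(X ≥ k), which
  equals a one-sided Fisher exact test; the reported percentage uses the
  mapped (query) set as the denominator. The universe defaults to the
  annotated gene set and is overridable — overlap p-values are only
  meaningful relative to an explicit universe.
- **GMT enrichment** reports, per set, the Fisher/hypergeometric p, the
  sample odds ratio with Haldane's 0.5 correction when any 2×2 cell is
  empty, and Benjamini–Hochberg FDR across tested sets. The default
  enrichment universe is the annotated gene set; enrichment services with
  their own backgrounds will give different p-values for the same query.

## Synthetic data generator

The generator emulates the four-condition study: per-gene fates either
sampled from class proportions or planted as exact counts (the default
plants the reference partition of 82 conserved, 137 lost and 190 gained
genes among 10,000, with 111 modifier-dependent genes of the 327
reprogrammed ones — 216 independent); elevated disease occupancy via a
background-binding multiplier (default 1.5) and a peak-score scale shift
(default 1.5); modifier silencing in the control genotype recruiting extra
targets (rate 0.03); and a knockdown-support rate of 0.5 among targets.

**Evidence-label model.** For each gene × condition the generator first
plants the boolean evidence pair (bound, DE-significant) implied by the fate
truth table, flips each label independently with probability ε (default
0.05), then draws the numeric columns *conditional on the labels*:

- Peaks (length 200 bp) are placed uniformly inside the owning gene's TSS
  window. Gene windows are laid out on a non-overlapping grid (TSS spacing
  2W + peak length + jitter + 1 kb), and decoy peaks land in the
  inter-window gaps, so no peak ever strays into another gene's window.
- Significant genes draw |log2FC| from |N(1.5, 0.5)| signed by the planted
  direction, with two-sample z-approximation p-values
  (SE = σ₀·√(2/n_reps), σ₀ = 0.25, n_reps = 3). The z magnitude is floored
  at the Benjamini–Hochberg rejection boundary α·k/m for the contrast, so BH
  recovers exactly the planted significant set.
- Null genes draw p uniformly on (α, 1] (a truncated null) and back out a
  sign-symmetric log2FC consistent with that p. Since BH-adjusted p-values
  never fall below raw p-values, a planted-null gene can never be called
  significant.

Together these choices make the planted labels *exactly* recoverable at
ε = 0 — the flip rate, not sampling accident, is the sole source of
misclassification — which is what lets the test suite assert perfect
noiseless recovery and an analytically predictable accuracy under noise.
The cost is realism at the margins: real DE tables have null p-values below
any threshold, real peaks cluster in shared regulatory regions and real
binding is not confined to one window. Passing tests therefore demonstrate
the correctness of the pipeline logic under a faithful-but-idealised
evidence model, not robustness to correlated artefacts of real data. Also
not emulated: read-level signal, replicate structure, fragment-length/GC
effects, multi-peak genes for members (members get one peak).

Determinism: one seed drives named substreams (one per purpose and
condition) spawned in a fixed order; all per-gene draws are element-indexed
vector draws, so a given seed yields byte-identical output files, and
enlarging `n_genes` leaves earlier genes' draws unchanged.

**Calibration scenario.** Because planted fates are shared across conditions
(a conserved gene is a member everywhere), per-condition bound fractions are
paired, and a two-sample test on them is structurally conservative. Null
calibration of the occupancy tests is therefore measured on a target-free
configuration (`never_target = 1.0`, multiplier = 1, score shift = 1, equal
background binding, ε = 0.1, indirect-regulation rate 0.35 so expected
chi-square cell counts are well above 5), where evidence arises
independently per condition. Under that null the score-distribution test is
essentially exact and the proportion test shows the expected mild Yates
conservatism.

## Problem sizes and runtime

The test suite and the acceptance script run at the design's native scale:
10,000 annotated genes for recovery and partition checks, 5,000 genes ×
100 seeds for calibration, 1,000 genes × 1,000 peaks for the window-assignment
oracle, and exhaustive hypergeometric verification for universes up to 25
plus spot checks at 100,000. A full simulate-and-analyze cycle at 10,000
genes takes about two seconds on one CPU.

## Pipeline configuration

`tftargets run --config config.yaml --outdir out` expects:

```yaml
tss: sim/tss.tsv
window: 20000
alpha: 0.05
lfc_min: 0.0
strict_direction: false
score_column: score          # or signalValue (narrowPeak column 7)
conditions:
  control_scramble: {peaks: ..., induction_de: ..., knockdown_de: ...}
  control_kd:       {peaks: ..., induction_de: ..., knockdown_de: ...}
  disease_scramble: {peaks: ..., induction_de: ..., knockdown_de: ...}
  disease_kd:       {peaks: ..., induction_de: ..., knockdown_de: ...}
overlap:                      # optional
  ortholog_table: orthologs.tsv
  source_genes: mouse_bound_genes.txt
enrichment:                   # optional
  gmt: pathways.gmt
  query_fate: gained_in_disease
```

## Known limitations

- One TSS per gene; no enhancer–promoter interaction model beyond the
  symmetric window, and no peak-reproducibility (IDR) handling — inputs are
  final per-condition peak sets.
- The narrowPeak "score" used for the distribution tests is configurable
  (column 5 or signalValue) because peak callers differ in which column
  carries the meaningful signal.
- The two-gene discrepancy one sees in some published partitions between
  lost+gained and dependent+independent totals is representable here only
  via the strict-direction `unresolved` bucket; the membership-based default
  always resolves dependence.
- Enrichment p-values depend entirely on the chosen universe; results are
  not comparable across universes.
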