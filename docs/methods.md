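# Methods

## Windowed counting

The genome is tiled into consecutive fixed-width windows (default 3000 bp,
0-based half-open); the trailing partial window is kept so the tiling is a
partition and tag counts are conserved. Aligned reads are reduced to their
5'-end coordinate (ChIP-exo tags are 5'-anchored), deduplicated by
(chromosome, 5' position, strand) keeping the first occurrence, filtered at
a configurable mapping quality (default `mapq_min = 10`; the upstream
protocol names no value), and assigned to the unique window containing the
5' end. Tags on chromosomes absent from the tiling are skipped with a
warning and tallied, so `sum(counts) + dropped == input tags` always holds.

## Negative-binomial core

Counts for unit *i*, sample *s* are modelled NB(λ_i·N_s, φ) with a single
dispersion φ shared across units (variance μ + φμ²). No tagwise or trended
shrinkage is attempted: with 3 replicates per group a common φ is the
defensible choice, and the alternative-mode hooks are deliberately absent.

**Equalization.** Library sizes are mapped to the geometric-mean pseudo
size N\*. For each unit the pooled rate λ̂_i = Σ_s y_is / Σ_s N_s sets the
input mean λ̂_i·N_s and output mean λ̂_i·N\* of an NB quantile map. The map
averages the left-continuous and right-continuous percentile inversions,
which makes it the identity when N_s = N\* and keeps pseudo counts
non-negative and monotone in the observed count. φ below 1e-6 switches to
Poisson quantiles. The equalize/estimate cycle runs twice (initial
φ = 0.01), then φ is fixed.

**Dispersion.** φ̂ maximizes the conditional log-likelihood summed over
units and groups, searched with bounded scalar minimization on log φ over
[1e-6, 10] with tolerance 1e-6. Single-replicate groups contribute nothing
(conditioning on the total removes all information); an all-zero matrix is
an error. At φ = 0 the likelihood takes its Poisson/multinomial limit
−z·ln n (terms constant in φ are dropped throughout).

**Exact test.** Conditional on the grand total s = S_A + S_B of
equalized counts, S_A follows a Dirichlet-multinomial (beta-binomial) law
with shapes n_A/φ and n_B/φ — algebraically identical to normalizing
products of two NB pmfs, but computed in closed form via `gammaln` so the
enumeration is exactly normalized. The two-sided p sums all splits whose
probability does not exceed the observed one; ties within 1e-12 relative
(log scale) are included. φ ≤ 1e-6 uses the conditional binomial directly
(the beta-binomial at shape ~1e8 would lose precision to cancellation).
Pseudo-count sums are rounded to the nearest integer before enumeration.
Conventions: s = 0 gives p = 1 and log2FC = 0; fold changes are computed
on per-replicate means with a prior of 0.125 added to each side, so zero
counts give finite, shrunk estimates.

**Differential gating.** Gene-level calls use |fold| > 1.3 with raw
p < 0.05 — the gate is on raw p-values by design; Benjamini–Hochberg is
not applied because the region/gene gates here are defined on raw p.

## Gain-of-6mA calling

Each `ComparisonSpec` carries one hypoxia replicate subset and three
gates evaluated per window:

* exact-test p < α (default 0.05) on hypoxia-vs-normoxia signal counts,
* Δ(H/N) > log2(1.1), where Δ is the difference of input-normalized
  log2 values `log2((signal_cpm + 1) / (input_cpm + 1))`, replicate cpm
  averaged within condition before the ratio,
* Δ(KD/ctrl) < −log2(1.1) for knockdown vs control knockdown under
  hypoxia.

p-values come from raw (equalized) signal counts; input normalization
enters only the fold gates. The sentence-order ambiguity of "normalized
with input … applied the threshold" was resolved this way because the
exact test is defined for counts, not ratios; treating input as an offset
inside the test is a different estimator and is intentionally not the
default. The p gate attaches to the hypoxia-vs-normoxia contrast only;
the knockdown contrast is a directional fold filter.

Windows are hypoxia/WGA positive when `log2((hyp_cpm + 1)/(wga_cpm + 1))
> log2(1.1)`. The final region set is the intersection over comparisons'
passing windows with the WGA-positive set; provenance flags per window
record which filters passed. Regions are reported at window granularity;
merging adjacent windows into maximal runs is available but off by
default. A pseudo-count of 1 cpm bounds every log-ratio at zero coverage.
Raising τ or lowering α can only shrink the region set (monotonicity is
tested).

## Annotation and motifs

Regions are classified by their midpoint — a 3-kb window can span several
features, and a single label per region is the contract — with precedence
proximal promoter > distal promoter > UTR > exon > intron > intergenic.
Promoter windows are strand-aware upstream intervals: proximal covers
TSS-relative −1000..−1, distal −10000..−1001 (both configurable; the
reference analysis used annotation-tool defaults that are not published).
Among genes offering the same label the nearest TSS wins; remaining ties
break on lexicographic gene id, so annotation is deterministic.

TSS-relative coordinates count upstream bases from −1 adjacent to the
TSS; there is no 0, and the TSS base is +1. Motif scanning expands IUPAC
codes (via biopython's table; `N` additionally matches an `N` in the
sequence) into character classes and reports every overlapping exact
match; minus-strand scanning matches the reverse complement on the
forward sequence and reports gene-orientation coordinates. TSS profiles
aggregate strand-oriented tag offsets into bins of `bin_bp` over
±`flank_bp`, as per-bp density averaged over genes; bounds are half-open
in offset space on both strands, which makes the profile exactly
invariant under reflecting the whole world.

## Gene integration

Regions are assigned to every gene whose body or upstream promoter window
(default 10 kb, configurable) they overlap; multi-gene assignments are
retained with a body/promoter rule tag rather than collapsed to a nearest
gene, and unmapped regions are listed. Co-regulated genes are those
flagged up in hypoxia-vs-normoxia and down in knockdown-vs-control in
every provided cell line. Peak classification partitions a gene set by
whether any peak interval overlaps body or promoter; the partition is
exact by construction and tested as such.

## Calibration

Calibration lines are ordinary least squares with a free intercept
(through-origin is a flag); R² is reported. The 6mA/dA ratio is
`(area − intercept)/slope` per analyte, ratioed and scaled to ppm; a
non-positive 6mA amount is clamped to 0 ppm with a below-LOD flag
(baseline levels are genuinely undetectable), while a non-positive dA
amount is an error since it is the denominator. Copies per cell inverts
a Ct-vs-log10(copies) line and divides by the cells extracted
(default 500,000).

## The synthetic world

The generator emulates the *structure* of the assay, not sequence
content: NB window counts with a shared log-normal per-window propensity
b_i (sd 0.5) applied to signal, input and WGA alike — this is what makes
input normalization meaningful — and planted effects on top:

* **Gain windows** (2% of windows, fold 2.0) appear in hypoxic signal
  tracks including the control knockdown, and revert under knockdown.
* **WGA artifacts** (2%, disjoint from gains) get fold 3.0 in the WGA
  track and fold 2.0 in hypoxic signal tracks. Amplification bias is
  modelled as strongest in the fully amplified material and partially
  leaking into amplified ChIP libraries; with equal folds the WGA filter
  would be powerless by construction, contradicting its purpose.
* Default depth is 50 expected tags/window; libraries are triplicate
  except hypoxia signal (five replicates), so the two replicate-subset
  comparisons ({1,2,3} and {1,4,5}) of the study design can be formed.
* Default dispersion is φ = 0.01 (BCV 0.1, the standard figure for
  genetically identical samples such as cell lines). At this depth and
  fold, the exact test has per-comparison power ≈ 0.97, giving
  end-to-end sensitivity 0.93–0.99 with false-discovery fraction ≤ 0.05
  across seeds. Noticeably higher dispersion (φ ≥ 0.05) makes a 2-fold
  effect at depth 50 with 3 replicates undetectable at 90% power — a
  statement about that world, not about the estimator.

Calibration simulation: linear standards with additive Gaussian noise
(1% of true response for MS areas, 0.1 cycles for Ct), standards
bracketing the sample amounts, and sample measurements averaged over
three technical replicates (MIQE-style). Even so, the recovery checks
("10 ppm within 1%", "46 copies/cell within 5%") are roughly 1σ
statements under this noise: they hold at the canonical seed used in the
tests, and fail for a substantial minority of seeds. A green test
therefore establishes correct arithmetic and an honest noise model, not
a universal precision guarantee.

What the generator does **not** emulate: sequence-dependent mappability,
fragment-length structure, replicate-specific quality differences (the
sample sheet is taken as given; replicate QC/selection is out of scope),
copy-number variation, or any real noise structure of 6mA ChIP-exo
beyond NB overdispersion. Green recovery tests establish that the
pipeline's gates and statistics do what they claim on a world matching
their assumptions — not that the assay's real artifact spectrum is fully
handled.

## Determinism

One master seed; every stream (genome, truth, counts, expression, tags,
calibration) is a deterministic spawn. A fixed config reproduces
byte-identical output files; the optimizer and all tie-breaks are
deterministic.

## Known limitations

* Common dispersion only; no tagwise/empirical-Bayes shrinkage, no GLM
  designs.
* The exact test rounds non-integer pseudo-count totals to the nearest
  integer; at very low totals the rounding step is visible in p.
* Windows with zero signal counts everywhere carry p = 1 by convention
  rather than being removed from the returned table.
* Midpoint annotation assigns one label to a 3-kb window even when it
  spans a feature boundary.
* The per-analyte linear MS calibration subsumes response-factor
  normalization; instrument-level workflows are not modelled.
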