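# Methods

## Study design being modelled

Four tissues in fixed axial order — SZ, PNT, CNT, RNT — with three pooled
biological replicates each (12 arrays). The scientific object is the
"differentiation switch" at the PNT → CNT transition: a large, down-biased
change in the transcriptome, sharp enough to fall inside a window of about
three somite-lengths, i.e. 3 × 1.5 h = 4.5 h of development
(`cellcycle.transition_window_hours`).

## Synthetic data

`simulate.SimulationConfig` fixes the study conditions; every generator
consumes one seeded `numpy.random.Generator` stream, so a fixed seed fixes
every emitted byte.

Probe-level intensity is `2**(tissue_mean + probe_affinity + noise)`:

- per-probe-set baselines are Normal(8, 2) in log2 units, the typical
  dynamic range of log-scale array data;
- probe affinities are drawn once per probe, Normal(0, 1) log2 units, and
  shared across samples — exactly the additive probe effect that median
  polish assumes;
- noise is i.i.d. Normal(0, `noise_sd`) in log2 space with `noise_sd = 0.25`
  by default, a realistic replicate scatter for pooled-tissue arrays; there
  are no array-scale effects by default (quantile normalization is still
  exercised, and `background_correct(mode="shift_log")` is available for
  real scanner-derived matrices).

Planted structure:

- a **switch cohort** (`switch_fraction = 0.2` of probe-sets) whose tissue
  means differ *only* between PNT and CNT, by exactly `effect_size = 1`
  log2 unit, downregulated with probability `down_fraction = 0.64`;
- a **marker cohort** (`marker_fraction = 0.1`) with one tissue elevated by
  `effect_size`, giving every tissue pair its own signature. Real adjacent
  tissues differ pairwise; without markers, SZ and PNT replicates would be
  statistically identical and replicate clustering would be meaningless.

Annotation layer: `annotation_gap = 0.35` of probe-sets lack a vendor gene
id; enough carry consistent EST chains that chaining closes the gap to
`residual_gap = 0.16`. The ortholog table mixes ~80% 1:1 rows with 1:many
and many:many blocks; toy chromosomes (50 genes each, conserved order
between the two species) make the true candidate share ordered neighbours
with its source while decoys sit on a separate chromosome and share none.
A handful of protein-similarity hits rescue otherwise dead probe-sets.

DRS layer: toy genes are 9 kb with 15 kb spacing, alternating strands. A
planted subset has its annotated 3′ end pulled back by up to 7 kb (the
annotation is truncated; the reads are not). Per-gene read mass is linear
in expression and 3′-biased — it occupies the window from 1 kb inside the
annotated body to the *true* 3′ end — and a deterministic tile drawn from
the same read budget guarantees coverage contiguous to exactly the true
end, so the planted extension is identifiable. Read-sequence content and
alignment artefacts are not modelled; alignments are emitted directly as
BED intervals.

EdU layer: per-section counts are Binomial(cells_per_section, L(t)) with
L(t) = (S + t)/T, five embryos × five sections per exposure (1 h and 4 h),
200 cells per section. Zero-noise mode emits the exact expected
(fractional) counts so analytic round-trip tests are exact.

What passing tests therefore show: the pipeline's statistics are correct
for data whose noise is i.i.d. Gaussian in log2 space with additive probe
effects, and whose reads/counts follow the stated forward models. They do
not certify behaviour under spatial chip artefacts, probe-sequence (GC)
bias, pooling-induced correlation between replicates, or DRS basecalling
error — none of which the generator emulates.

## Normalization

Full RMA convolution background (normal + exponential deconvolution) is
deliberately not implemented: the analysis surface is the downstream
statistics, and background choice is isolated behind the
`background_correct` flag (`none` default, `shift_log` optional).

Quantile normalization maps each column onto the vector of row-wise means
of column-sorted values; tied values receive the mean of the reference
quantiles they span (average-rank convention). This makes the transform
idempotent and column-permutation-equivariant; exact equality of column
means holds for tie-free columns.

Median polish is row-sweep-first, tolerance 1e-6 on the relative change in
total absolute residual, at most 20 sweeps — polish output depends on sweep
order, so the order is fixed and documented. Probe-sets with equal probe
counts are polished as one vectorized stack (identical arithmetic,
per-probe-set results). Probe-set expression is overall + sample effects.

Replicate QC: average-linkage clustering on 1 − Pearson; a sample whose
nearest neighbour belongs to another tissue is flagged.

## Differential expression

Cell-means OLS per probe-set over an arbitrary grouping factor (tissues by
default; 4 × 3 design → residual df = 8). Variance moderation follows the
scaled-F empirical-Bayes scheme: with s² ~ s₀²·χ²_d/d given a χ²_{d₀}
prior, log s² has digamma/trigamma moments; matching the sample mean and
variance of log s² yields (d₀, s₀²) (trigamma inverted by Newton). If the
observed dispersion of log s² does not exceed the χ² sampling noise, d₀ is
infinite and every posterior variance equals s₀². One boundary case is
special-cased: when the s² are literally identical there is no sampling
scatter to deconvolve, and the prior is taken to be that common value (the
moment formula would otherwise inflate it by the χ² log-scale correction).
`d0_override=0` turns moderation off, reducing the machinery to classical
t-tests — used as an oracle equivalence in the tests.

Contrast t = c′μ̂ / (s̃·√(Σc_g²/n_g)), two-sided p on d₀ + d degrees of
freedom. The pooled switch contrast is the 6-vs-6 comparison
mean(CNT,RNT) − mean(SZ,PNT); the interaction reading
(CNT−PNT) − (PNT−SZ) is available behind `include_interaction=True`.
BH-FDR is applied per contrast (per-comparison gene lists), and the
significance call is strictly q < 0.046; the equivalent "2σ" phrasing is
not applied as an extra filter. Zero residual variances (possible on
zero-noise data) are floored at machine epsilon with a warning.

Gene-level calls: a gene is significant if any of its probe-sets is;
direction comes from the probe-set with the smallest q, ties broken by
larger |logFC|.

CASI screen: the statistic is the mean absolute inter-replicate log2 ratio
over CASI-gene probe-sets (averaged over tissues and replicate pairs); the
null redraws equal-size random probe-set groups, p = (b+1)/(B+1). Pooling
should average sex composition out; a replicate-linked shift concentrated
in sex-identity genes inflates the statistic.

## Enrichment

Gene-level, not probe-set-level: probe-sets are collapsed to genes before
counting so probe-set redundancy cannot inflate overlaps — a deliberate
tightening relative to annotation-package probe-set tests. The universe is
the set of genes with ≥1 annotated probe-set on the array (the standard
gene-universe convention), not the genome. Flat term tests only; no GO
graph decorrelation.

## Re-annotation and synteny

Evidence precedence is total: vendor > EST chain > synteny ortholog >
similarity. EST chains assign only when all of a probe-set's mapped ESTs
agree (conflicts are flagged, not guessed). Similarity assignment takes the
best hit passing identity/e-value thresholds; equal-best hits to different
genes stay unresolved.

The synteny score of candidate B for source gene A is the number of genes
within ±`window` of A whose already-accepted orthologs lie within ±`window`
of B. The window (±5 genes) and `min_margin` (1) are config keys — the
field uses conserved gene order for this purpose but no canonical scoring
function exists, so this formalization is the package's own, chosen for
determinism and testability. Ambiguity is resolved greedily: the globally
highest-margin pair is fixed (ties broken lexicographically), its genes are
removed from other candidate lists, and scores are recomputed so later
resolutions can lean on earlier ones. A best candidate must beat the
runner-up by ≥ `min_margin`; symmetric ties are never guessed. A
sequence-similarity search is consumed as a precomputed hits table, never
run.

## Conservation test

"Significant in at least one tissue comparison" means the union over the
three pairwise transition contrasts at q < 0.046 (the pooled contrast is
excluded by default and toggleable). The null draws B uniform subsets of
the gene universe of the mapped-cohort size; p = (b+1)/(B+1) (floor
1/(B+1); 0.001 at B = 999, default B = 9999). Because a uniform draw is an
assumption rather than a derivation, the exact hypergeometric tail is
always reported alongside.

## Cell-cycle estimation

The displayed simultaneous equations of the original protocol are adopted
in their standard cumulative-labeling form, L(t) = (S + t)/T: this is the
unique linear model in which subtracting the two exposure equations yields
T = (t₂−t₁)/(L₂−L₁) and back-substitution yields S = L₁T − t₁, and it
reproduces the 1 h/4 h design. This reconstruction is flagged here
deliberately: if the original equations carried a different scaling (e.g.
percentages), only the inversion in `cellcycle._invert` needs adjusting.
No growth-fraction or cell-death correction is applied (all cells assumed
cycling). Labeled fractions are pooled count-weighted within exposure;
with more than two exposure times the least-squares line generalizes the
two-point formula. Uncertainty is a leave-one-embryo-out jackknife, since
the design reports mean ± s.e.m. over five embryos. Degenerate inputs
(non-increasing labeling) are errors; S outside (0, T) is returned but
flagged. Region comparisons use Welch's t by default (Student's pooled
variance behind a flag).

## DRS integration

Coordinates are 0-based half-open internally (BED convention); GFF3 is
converted on read and write. Counting is strand-aware by default (3′-end
sequencing is stranded). The UTR walk moves base-by-base downstream of the
annotated 3′ end, extending through coverage ≥ `min_cov` (default 1) and
bridging uncovered runs ≤ `max_gap` (default 50 bp); it stops at the first
longer gap, the nearest same-strand downstream gene, or `max_extension`
(default 10 000 bp — above the 7 kb the data motivate, so that case is
reachable). Counts are compared across platforms as log2(count + 1) versus
log2 array expression; the log-transform choice is an assumption of this
package.

## Problem sizes and numerical choices

Defaults: 1000 probe-sets × 11 probes for general use; the test suite and
null-calibration runs use 5000 probe-sets × 4 probes and 20 seeds for the
FDR property, 40-gene toy genomes for the DRS round trips, and B = 10⁵ for
the permutation-calibration check — sizes at which every property is
measurable with comfortable Monte-Carlo margins. Median polish tolerance
1e-6/20 sweeps; variance floor at machine epsilon; trigamma inversion by
Newton to 1e-10 relative.

## Known limitations

- No CEL parsing, PM/MM handling or probe-sequence correction; intensity
  matrices arrive as TSV.
- The FDR property is demonstrated under the generator's i.i.d. Gaussian
  noise; correlated probes or array effects would need duplicate-correlation
  or array-weight models, which are out of scope.
- The synteny scheme resolves what conserved order can resolve; paralog-rich
  neighbourhoods with symmetric context stay unresolved by design.
- The conservation null treats genes as exchangeable within the universe;
  expression-matched nulls are not implemented.
- Replicates are simulated i.i.d.; the pooling of ≥5 explants per replicate
  in the real protocol may induce noise structure the generator does not
  characterize.
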