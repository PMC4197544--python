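# axiswitch

Analysis pipeline for transcriptome change along an ordered embryonic neural
axis. In the elongating amniote embryo, temporal steps of neural
differentiation are laid out in space: the caudal **stem zone (SZ)** holds
multi-potent neuro-mesodermal progenitors, the **preneural tube (PNT)** an
early, still-revertible neural progenitor state, and the closed **caudal**
and **rostral neural tube (CNT, RNT)** progressively committed and
differentiating neuroepithelium. Comparing bulk microarray transcriptomes of
these four adjacent tissues localises a sharp "differentiation switch" — a
large, down-biased transcriptome re-organisation — to the PNT → CNT
transition, and predicts accompanying changes in cell-cycle kinetics that
cumulative EdU labeling can test directly.

The package provides every computational step of that analysis as a tested
library, exercised end-to-end on a synthetic-data generator with known
ground truth:

- **`axiswitch.simulate`** — generates all pipeline inputs (probe-level
  intensities with a planted switch cohort, annotation tables with gaps,
  ortholog tables on toy ordered chromosomes, GMT term sets, GFF3/BED
  gene models and 3′-biased reads, EdU count tables) in the exact external
  formats the pipeline reads.
- **`axiswitch.rma`** — RMA-style processing: background handling, quantile
  normalization, Tukey median-polish summarization to probe-set expression,
  replicate QC by correlation-distance clustering, and the mean-scaled
  relative profile log₁₀(I_{p,t}/⟨I_p⟩).
- **`axiswitch.de`** — per-probe-set cell-means linear models over the four
  tissues; transition contrasts PNT−SZ, CNT−PNT, RNT−CNT and the pooled
  switch contrast mean(CNT,RNT) − mean(SZ,PNT); empirical-Bayes variance
  moderation with a scaled-F prior, s̃² = (d₀s₀² + d·s²)/(d₀ + d), estimated
  by method of moments on log s²; Benjamini–Hochberg q-values with
  significance called strictly at q < 0.046; a permutation screen for
  sex-linked (CASI-gene) bias.
- **`axiswitch.enrich`** — exact hypergeometric over-representation of
  GMT term sets, P(X ≥ k) with X ~ Hypergeom(N, K, n), gene-level against
  the annotated-array universe.
- **`axiswitch.annotation`** — probe-set re-annotation via an evidence
  cascade (vendor > EST chain > synteny ortholog > protein similarity) and
  conserved-gene-order resolution of 1:many / many:many ortholog ambiguity.
- **`axiswitch.conservation`** — cross-species conserved-cohort test:
  ortholog mapping plus a permutation null with p = (b+1)/(B+1), reported
  alongside the exact hypergeometric tail.
- **`axiswitch.cellcycle`** — dual-exposure cumulative-labeling estimation:
  under L(t) = (S + t)/T, T = (t₂−t₁)/(L₂−L₁) and S = L₁T − t₁, with
  leave-one-embryo-out jackknife errors, mitotic index and pairwise
  region t-tests.
- **`axiswitch.drs`** — 3′-end sequencing integration: stranded per-gene
  read counting, coverage-walk 3′UTR extension (bridging gaps ≤ `max_gap`,
  stopping at the next same-strand gene or `max_extension`), and Pearson
  correlation between platforms on the log scale.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (each writes its tables under `results/`):

```bash
python analysis/01_simulate.py
python analysis/02_normalize.py
python analysis/03_differential_expression.py
```

which prints, for 2000 simulated probe-sets (seed 1):

```
               n_significant  n_up  n_down  pct_down
contrast
PNT_vs_SZ                100    61      39      39.0
CNT_vs_PNT               575   252     323      56.2
RNT_vs_CNT               109    52      57      52.3
switch_pooled            690   330     360      52.2

pooled switch contrast: 690.0 probe-sets at q<0.046, 52% down; the switch
region spans 4.5 h of development
planted switch cohort: 399/400 recovered (66% down, planted 66%)
CASI sex-bias screen: no strong sex-linked bias (p=0.637, 13 genes)
```

The CNT-vs-PNT transition carries by far the most regulated probe-sets and a
clear excess of downregulation — the planted differentiation switch — and
the pooled contrast recovers essentially the whole planted cohort with its
planted down-bias. Continuing the pipeline:

```bash
python analysis/07_cell_cycle.py     # T ≈ 8 h (SZ) doubling to ≈ 16 h (RNT)
python analysis/08_drs_integration.py
```

the last of which reports

```
extended 10/30 genes, max 7000 bp; planted extensions recovered exactly: True
platform correlation over 30 genes: R=0.46 before re-annotation -> R=0.96 after
```

i.e. the coverage walk recovers every planted 3′UTR truncation (up to 7 kb)
and re-annotation markedly improves the array/DRS agreement.

Every step is also available as a CLI (`axiswitch simulate|normalize|de|
enrich|annotate|conserve|cellcycle|drs --help`).

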