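# Methods

This note documents the statistical procedures implemented in `methnet`,
the defaults they ship with, the synthetic-data conditions under which the
test suite evaluates them, and the design choices made where the analysis
admits more than one reasonable construction.

## Coordinates and genomic anchors

All coordinates are 0-based half-open (BED convention) throughout; any
1-based input positions must be converted on ingestion. Gene anchors are
strand-aware: the promoter spans 1500 bp upstream to 2500 bp downstream of
the TSS in transcription orientation (4000 bp); the "gene body excluding
the first 5 kb" removes the 5 kb downstream of the TSS in transcription
orientation and is empty for genes shorter than 5 kb; the analysis domain
is the TSS ± 1 Mb (2 Mb total, clipped at chromosome bounds when sizes are
supplied).

Variable regulatory regions — poised chromatin whose activity differs
between tumors — are the bases covered by H3K4me1 in **every** sample and
by H3K27ac in a fraction of samples between `min_frac` (default 0.25) and
`1 − min_frac`. Selection is computed at base-pair resolution by sweep-line
coverage counting and then merged into maximal intervals. Base-level logic
was chosen over peak-level logic because it is deterministic, invariant to
how callers fragment peaks, and invariant to sample relabelling (all three
properties are tested). With a single sample the acetylation fraction can
only be 0 or 1, so the result is empty by construction; the function warns.

Windows tile each region from its start in `size`-bp windows advancing by
`step` (defaults 500/250, i.e. 50% overlap); the final window is clipped at
the region end. Tiling is restricted to targeted regions: only they carry
reads, so genome-wide tiling would add empty windows without changing any
result.

## Reporter activity scoring

The transcriptional activity score of a window is the log2 ratio of its
RNA:DNA read ratio to the library-wide ratio. Segments with at least one
RNA read and one DNA read are retained; library totals are sums over
retained segments of the same condition. A window receives the **full**
counts of every overlapping segment — a segment spanning two overlapping
windows contributes to both. Pro-rating by overlap length was considered
and rejected: counts are not uniform along a segment, and full assignment
keeps window scores interpretable as "activity of material overlapping
this window".

Significance is a Pearson chi-square (1 df, no continuity correction;
counts are large — a Yates flag exists for small libraries) on the 2×2
table of the window's RNA/DNA split against the remainder of the library.
Windows with zero aggregated RNA or DNA are flagged unscored rather than
dropped. BH correction is applied across all scored windows of one
condition in one run. Elements require q < 0.05 and ≥ 100 RNA reads; class
follows the TAS sign (an exact zero is unclassifiable and excluded).

Methylation response compares matched unmethylated/methylated window
scores. Sensitivity demands |ΔTAS| ≥ log2(1.5): the 1.5-fold threshold is
applied on the activity **ratio** scale, since TAS is already a log2
ratio. Groups: I — enhancer whose activity drops (or switches sign) upon
methylation; II — enhancer strengthened; III — silencer strengthened
(more negative); IV — silencer weakened or switched. Insensitive elements
and elements unscored in the methylated condition remain `unclassified`
and keep their rows, so the audit trail survives every classification
step.

## Circuit inference

For every gene × CpG-site pair with the site inside the gene's ±1 Mb
domain, we compute Spearman's rank correlation (average ranks for ties)
over pairwise-complete samples; sites need ≥ 8 non-missing values and
cohorts ≥ 12 shared samples. p-values use the t-approximation on n − 2 df,
adequate at cohort sizes around 24. BH correction is applied globally over
all tested pairs in the run (a per-gene family is available by flag; the
global family is the stricter and simpler default when the correction
family is not dictated by the data). A circuit is retained when q < 0.05,
ρ² > 0.3, and no filter has flagged it.

Filters add boolean flags and recompute `retained`; the unfiltered table
is always recoverable:

* **Blood contamination** — sites whose methylation tracks expression of
  the pan-leukocyte marker PTPRC (CD45) with ρ² > 0.1 likely report
  leukocyte admixture, not tumor-cell regulation.
* **Secondary effects** — a site inside another gene's promoter or
  5-kb-trimmed gene body is flagged only when the two genes' expressions
  correlate (ρ² > 0.1). The conditional version is the default; a strict
  mode flags such sites outright. Testing precedes flagging, so both the
  pre- and post-filter counts are reported.
* **Canonical mismatch** — each circuit's site is matched to the nearest
  called reporter element within 500 bp. A negative circuit (expression
  falls as methylation rises) canonically corresponds to a
  methylation-weakened enhancer (group I); a positive circuit to a
  methylation-weakened silencer (group IV). A methylation-sensitive
  matched element outside the expected group flags the circuit. The
  {negative→I, positive→IV} map is the default and is configurable; it is
  the assignment consistent with the group semantics above, and the map is
  exposed because alternative group conventions exist.

Copy-number association follows the same pattern on pre-computed 5-kb
sliding blocks (50% overlap): Pearson and Spearman correlation of total
copy number against gene expression for blocks in the gene domain, with
≥ 6 samples of available copy number, constant blocks skipped, BH within
each correlation family.

## Units

Retained circuits of one gene, sorted by position, are merged greedily:
a site joins the open cluster when it has the same association sign and
lies within `max_gap` (default 1000 bp) of the previous member; a sign
change or a larger gap closes the cluster. Clusters below `min_sites`
(default 2) are emitted as singletons flagged `sub_unit` and excluded
from unit statistics — multi-site averages are reported alongside
singleton-inclusive averages because the convention differs between
studies. The 1000-bp gap default comfortably merges the planted unit
architecture (~900-bp spans, ~5 sites) while separating units placed tens
of kilobases apart. Unit size is the genomic distance from the first to
the last member site. Methylation–methylation correlation maps use the
same Spearman primitive as circuit inference, pairwise-complete, with
under-observed pairs rendered as missing.

## Expression models

Candidate sites are a gene's retained (and canonically consistent)
circuits. All subsets of 1–4 sites with jointly complete data in ≥ 12
samples are fitted by OLS on complete cases. Model strength `r_model` is
the Pearson correlation of fitted vs observed (equal to the multiple
correlation √(1 − SSE/SST) for OLS with an intercept); significance is
the overall F-test, BH-corrected **within the gene** over its candidate
models (the per-gene family matches correcting "for the number of possible
models per gene"). Among significant models the highest r² wins; ties go
to fewer sites, then lexicographic site order. The winner is *synergic*
when its r² strictly exceeds every member site's single-site Pearson r²
computed on the same complete-case samples — Pearson on both sides keeps
the comparison like-for-like inside the modelling stage even though
circuit discovery uses Spearman. Rank-deficient designs (e.g. duplicate
sites from a tightly coupled unit) are rejected outright rather than
fitted with a pseudoinverse.

The LASSO variant places no cap on site count: predictors are
standardised, the penalty path is cross-validated (10-fold, fixed seed)
and the **one-standard-error rule** picks the strongest penalty within
one SE of the minimum CV error. The minimum-MSE penalty was evaluated
first and retained roughly seven sites for a planted four-site model at
n = 24 — the well-known over-selection of CV-min lasso at small n — while
the 1-SE rule recovers site counts close to the planted model and matches
the parsimony convention of glmnet's reporting defaults.

Leave-one-out validation re-runs the whole inference chain — circuit
mapping, optional canonical filtering, exhaustive model search — on each
N−1 training cohort; the held-out sample never informs training. A
prediction within 2-fold of the observation (|log2 error| ≤ 1, boundary
inclusive) is a success; a round with no model or with missing
methylation at the model's sites in the held-out sample is a failure. A
gene is verified when it succeeds in ≥ ceil(20/24·N) rounds, which
preserves the 20-of-24 ratio for other cohort sizes. "Irregular"
observations deviate from the gene's cohort mean by more than one cohort
SD, computed over all N samples (not the training 23; configurable) so
the flag is identical across rounds of the same gene.

## Synthetic cohorts and reporter libraries

The generator emulates the cohort structure the analysis assumes. Per
gene: positive and negative regulatory units (counts 1 + Bernoulli(0.1)
and 1 + Bernoulli(0.4), mean 1.1 and 1.4); sites per unit 2 + Poisson(2.9)
(mean ≈ 4.9) spread evenly over 900-bp spans, units 20 kb apart;
per-sample unit activities Uniform(0, 1) (a Beta option exists because
real beta-value distributions are bimodal; Uniform keeps full dynamic
range and is the default); site betas are the unit activity plus
N(0, 0.05) clipped to [0, 1]; expression is a baseline (Uniform(6, 10)
log2 units) plus the signed weighted sum of unit activities (weights
Uniform(0.8, 1.6)) plus N(0, 0.25) log2 noise; background null sites are
independent Uniform(0, 1); 5% of methylation calls are masked. Default
cohort size is 24 samples. Ground truth records every planted circuit,
unit, and coefficient; each circuit's `rho_true` is the Spearman
correlation measured on an independent 20 000-sample reference draw of
the same gene, i.e. the population association implied by the settings.

`unit_coupling` mixes each unit's activity with a shared per-gene latent
factor (opposite loadings for opposite signs). At coupling 1 positive and
negative units are perfectly anticorrelated — the fixture for
correlation-map sign structure — and every planted site approaches
|ρ| = 1. This matters for test design: with **independent** units, a
site's population correlation with expression is capped near 1/√(2·#units)
(each other unit acts as irreducible noise), so at n = 24 the ρ² > 0.3
retention floor intermittently drops whole units. Recovery fixtures that
require deterministic retention (unit membership ARI, noiseless
leave-one-out) therefore use coupled units; calibration and power
fixtures use independent units.

Reporter libraries plant per-window activities by response group with
fractions I/II/III/IV/null = 0.2/0.1/0.4/0.2/0.1. Because TAS is defined
relative to the library mean, only activity plans whose depth-weighted
mean of 2^activity equals 1 are self-consistent; this mix satisfies that
balance in both conditions exactly, so planted scores of ±1 are recovered
on their own scale instead of shifted by a library-composition offset.
Per window and condition, three segment sub-intervals receive
negative-binomial DNA counts (mean 500/window, dispersion 10) and Poisson
RNA counts with mean DNA · 2^activity. Windows sit in disjoint regions so
planted effects do not bleed across overlapping windows. Peak sets cover
all regions with H3K4me1 except a planted tenth that misses one sample,
and sweep H3K27ac presence across the full fraction range.

What the generator does **not** emulate: bimodal beta-value distributions
(unless the Beta option is enabled), spatial autocorrelation of
methylation beyond unit structure, copy-number confounding of expression,
batch effects, cell-type admixture other than the PTPRC construction used
in filter tests, and sequence-level read noise. Passing tests demonstrate
correctness of the statistical machinery under the stated model, not
robustness to these real-data features.

## Problem sizes and numerical choices

The test suite and the acceptance script run at reduced problem sizes
chosen to exercise each property with adequate Monte-Carlo resolution:
2000-window null libraries and 500-window planted libraries; null-cohort
calibration over ≥ 1000 gene × site pairs; power at planted ρ ≈ 0.85 over
60 circuits (expression noise 0.185 with unit weight 1 and site noise
0.02 plants that population correlation); 100 replicate cohorts for
coefficient recovery; leave-one-out cohorts of 24 samples × 4 genes with
2–3 sites per unit (the exhaustive ≤ 4-site search grows binomially in
candidate count, and the validation properties do not depend on unit
width).

Numerical conventions: BH is computed by statsmodels with NaN
passthrough; Spearman by scipy with average ranks; OLS by least squares
with explicit rank checking (rank-deficient designs rejected, never
pseudo-inverted); a perfect fit (SSE ≤ 10⁻¹⁴·SST) reports p = 0; the
F survival function is evaluated through the direct C routine for speed.
Degenerate inputs — constant vectors, zero-read windows, empty segment
lists, missing PTPRC — are flagged or skipped with warnings rather than
silently scored. All generator randomness derives from one seed through
spawned child generators, making every fixture bundle and pipeline run
byte-reproducible; run manifests record SHA-256 checksums of all outputs.

## Known limitations

* Spearman p-values rely on the t-approximation; below n ≈ 10 an exact
  permutation test would be preferable (the mapping stage requires ≥ 12
  shared samples, which keeps the approximation adequate).
* The exhaustive model search is combinatorial in the candidate count;
  genes with many dozens of retained sites make the ≤ 4-site sweep
  expensive, and the LASSO route is the practical alternative there.
* The canonical-mismatch filter depends on the reporter assay's group
  calls; windows misclassified by the assay propagate into circuit
  filtering.
* Verification thresholds scale as ceil(20/24·N), which is conservative
  for very small cohorts.
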