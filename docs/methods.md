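# Methods

## The classification model

The cascade is a fixed-threshold decision procedure, not a fitted model.
Its inputs are a genes × samples table of non-negative counts (or TPMs),
per-gene transcript lengths, and a design mapping the samples onto the four
layered-culture groups (`N_self`, `T_self`, `T_vs_N`, `T_vs_KO`), each with
at least two replicates (three in the study design). Its output partitions
genes into five mutually exclusive, nested layers.

Counts are length-normalized and scaled per sample to TPM (columns sum to
10⁶ within a relative 10⁻⁶). Because TPM is compositional, a strong
perturbation concentrated in few genes rescales every other gene in that
sample; this is a property of the unit, not an artifact of the
implementation, and it is why validation datasets keep the perturbed mass
at a realistic fraction of the transcriptome (see below).

Every significance call uses the same two-tailed pooled-variance Student
t-test (df = n₁ + n₂ − 2) on raw TPM replicate values. Fold-type statistics
use group means with an additive pseudocount:

* expression filter: mean TPM ≥ `min_tpm` (default 1, inclusive) in ≥ 1 group;
* Src effect: `(T̄_self + pc)/(N̄_self + pc)` ≥ `src_fold` (3) or ≤ its
  reciprocal, p < `src_alpha` (0.05);
* reversal: signed relative change `(T̄_vs_N − T̄_self)/(T̄_self + pc)`,
  opposite in sign to the Src effect, magnitude ≥ `reversal_fraction`
  (0.40), p < `reversal_alpha` (0.08 — deliberately looser than the other
  stages, kept verbatim as the analysis's stated cut-off);
* cadherin dependence: `(T̄_vs_KO + pc)/(T̄_vs_N + pc)` ≥ `cdh_fold` (2) for
  Src-up genes or ≤ 1/`cdh_fold` for Src-down genes, p < `cdh_alpha` (0.05).

`pc` is `pseudocount`, default 1 TPM. The source analysis never defines its
ratio or zero handling; 1 TPM matches the expression-filter scale and
bounds ratios for near-zero genes. All threshold comparisons are inclusive
("at least"); alphas of exactly 0 are accepted as degenerate cut-offs that
pass nothing.

### Interpretation choices (config switches)

Several steps of the published analysis are underdetermined; each default
is an explicit choice with the alternative kept selectable:

* **Filter granularity** (`filter_scope`): "expressed in any sample group"
  is read as *group mean* ≥ threshold (groups are the unit of comparison
  throughout the cascade); `any_sample` keeps a gene when any single
  replicate reaches the threshold.
* **Reversal definition** (`reversal_mode`): the default (`relative`)
  measures the change against the transformed-self level. The plausible
  alternative (`restoration`) measures the fraction of the gap back to the
  normal-self baseline that the coculture closes.
* **Test scale** (`log_scale_tests`): t-tests on raw TPM by default
  ("Student's" names the classical equal-variance test on the reported
  values); log2(TPM + 1) testing is available.
* **Multiple testing** (`bh_correct`): off by default — the analysis
  reports raw per-gene t-test cut-offs; Benjamini–Hochberg adjustment
  within each stage is available.
* **Dependence scope**: the dependence test is applied to *all* reversed
  genes (both directions). The published counts are ambiguous about whether
  one direction or both entered this stage; applying it to the full
  reversed set is the symmetric reading.
* **Direction consistency**: a knockout-vs-competent differential only
  counts as cadherin dependence when it moves expression back toward the
  transformed-self level; an equally large differential the other way is
  not loss of normalization.

### Degenerate inputs

Zero pooled variance with equal means yields t = 0, p = 1; with unequal
means, p = 0 and an infinite t with a logged warning (reachable only on
noise-free synthetic data). A sample with all-zero counts has undefined TPM
and is rejected. Fold changes with a zero denominator and zero pseudocount
are infinite; the all-zero case is rejected.

## Synthetic data generator

The generator emulates the statistical structure the cascade assumes: four
groups × R replicates (default 3), ~10²–10⁴ genes with planted classes, and
gamma–Poisson (negative-binomial) counts, variance μ + φμ² with a per-gene
dispersion φ shared across groups. No distributional description of the
original data is available; the NB model is the standard bulk RNA-seq
choice and is a stand-in, not an inference from the study.

Planted classes fix each gene's expected TPM per group: a base level in
`N_self`; ×/÷ `src_fold` in `T_self`; ∓ `reversal_fraction` of the
transformed-self level in `T_vs_N` for reversed classes (a multiplicative
`1 + reversal_fraction` increase for Src-down genes); and ×/÷ `cdh_fold` in
`T_vs_KO` for dependent classes. Expected counts are obtained through
per-gene lengths (uniform on [500, 5000] bases unless supplied) and
per-sample library sizes jittered ±10% around `library_size`, anchored to
the normal-self group's read mass by a single global constant so planted
within-gene ratios are exact on the count scale; TPM results are unaffected
by per-sample depth, so this choice is invisible to the cascade.
`library_size` defaults to 2 × 10⁷ reads, the order implied by sequencing
twelve libraries on one HiSeq lane; at much lower depths single stray reads
in short genes approach 1 TPM and the expression filter becomes
quantization-limited.

Randomness comes from one root seed with dedicated substreams (sample-level
jitter, per-gene counts, lengths), so identical seed + specification gives
bit-identical counts and appending genes never alters the random draws of
earlier genes. Dispersion exactly 0 produces deterministic rounded expected
counts.

Two stock mixes set study conditions:

* `study_mix(scale)` — the study's nested proportions (49,315 detected;
  21,738 expressed; 2,240/1,151 Src up/down; 328/326 reversed; 16/68
  dependent at `scale=1`), with effect sizes at twice each threshold.
* `recovery_benchmark_mix()` — 1,000 genes with every class well
  represented (200 sub-threshold, 640 unaffected, 80 + 80 Src-affected,
  40 + 40 reversed, 20 + 20 dependent), effects again at twice each
  threshold (fold 8, reversal 0.6, differential 4) and dispersion 0.01.

Both auto-scale the base expression so planted normal-self TPMs total one
million, making planted values realized TPMs. What the generator does *not*
emulate: batch effects, length/GC biases, isoform structure, correlated
genes, outlier replicates, or spatial structure within the membrane.
Passing recovery benchmarks therefore demonstrates correctness of the
decision procedure under its own assumptions, not robustness to real-data
pathologies.

Recovery is scored per stage over the genes that truly reach that stage
(expression over all genes; Src effect over truly expressed; reversal over
truly Src-affected; dependence over truly reversed), plus a 5 × 5 confusion
matrix over layers.

## Annotation and network summaries

Cellular locations and interaction edges are consumed from flat TSV exports
rather than live services, keeping runs reproducible and offline. Genes are
binned into five mutually exclusive categories: noncoding biotype first,
then coding genes by the fixed precedence extracellular > plasma membrane >
cytoplasm > nucleus (the precedence is this package's choice; multi-location
binning was not specified in the source analysis), with unannotated genes
`unclassified` so contingency rows always sum to layer sizes. Neighborhoods
threshold undirected edge confidences in [0, 1], with the conventional
score tiers 0.400 / 0.700 / 0.900 exposed as presets; duplicate edges keep
the highest score.

## Assay statistics

Growth assays (transformed cells per 0.242 mm² field) and densitometry
(band signal over loading control) are summarized as percent of a control
condition's mean, with SEM computed as the n−1 sample standard deviation
over √n. t-tests compare raw measurements, not percents, so the control's
scaling noise is not applied twice; percent values are presentation-layer.
Both percent and fold outputs are invariant under common rescaling of all
measurements.

## Validation problem sizes

The test suite and the acceptance script use: 100 random matrices for TPM
conservation; 100 random replicate pairs for t-test reference agreement;
50 random 200-gene datasets (randomized effect sizes spanning the
thresholds, dispersions 0.02–0.3) for exact equivalence with a
straight-line per-gene oracle; the 1,000-gene recovery benchmark at
dispersion 0.01 and its near-noiseless variant at 10⁻⁴; and a 0.1-scale
study-proportion simulation (4,932 genes). These sizes give stable
statistics while keeping a full run inside a couple of minutes on one CPU.

## Known limitations

* The cascade is threshold-based by design; it performs no shrinkage,
  dispersion estimation, or hierarchical modeling, and raw p-value cut-offs
  at n = 3 have limited power and uncalibrated error rates.
* TPM compositionality couples genes within a sample; planted effect sizes
  are recovered exactly on the count scale but only approximately on the
  TPM scale when perturbed genes carry substantial mass.
* The published transcriptome counts derive from the study's deposited raw
  sequencing data processed with an unnamed quantifier and are not
  reproducible from summary tables; the study-proportion simulation
  reproduces the *structure* of those results, not the gene lists.
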