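# Methods

## Analysis model

### Pseudobulk X:A ratios

Cells are summed within each annotated spermatogenesis stage ("pseudobulk"),
genes with fewer than 5 aggregated reads in every stage are removed, and each
gene's expression is divided by the stage median over the autosomal reference
arms (Muller B and E). Muller F is excluded from the reference because it is
a former X chromosome; the neo-Y is excluded because it is male-limited and
degenerating. Raw pseudobulk counts are a valid input unit: any per-stage
scale factor (sequencing depth, cell number, global transcriptional
amplification) cancels between numerator and the within-stage reference
median. Chromosome-level trajectories are per-stage medians of the per-gene
ratios; uncertainty comes from a seeded bootstrap over genes (resampling the
chromosome's gene set with replacement, percentile intervals; default 1,000
replicates at 95%).

The gene filter phrase "fewer than 5 total reads across any cell types" is
interpreted as *no stage reaches 5 aggregated reads* (keep iff the per-stage
maximum is >= 5); the alternative global-sum reading is available as
`filter_genes(mode="total")`.

### Regime classification

No quantitative decision rule exists in the field for "consistent with DC
shutdown"; `regime_classify` is this package's explicit operationalization
of the qualitative trajectory predictions, and every verdict records the
statistics and thresholds that produced it.

* **MSCI** iff any X arm's final-meiotic-stage bootstrap CI upper bound is
  below `0.5 * (1 - delta)` (default `delta = 0.1`), or the youngest arm's
  first-to-last germline log2 median change exceeds the oldest arm's by more
  than `tau = 0.5` while the oldest arm ends below half.
* **DC_SHUTDOWN** iff no arm is flagged below half, the spread of the X-arm
  medians at the final stage is less than half the spread at the first
  germline stage (`convergence_index < 0.5`), and the first-germline-stage
  medians are age-ordered (oldest >= middle >= youngest). The ordering
  comparison allows a slack of 0.02 on the medians: chromosome medians over
  finite gene panels carry sampling noise of roughly this size at the
  default panel sizes, and a strict inequality would turn that noise into
  spurious `AMBIGUOUS` calls.
* **AMBIGUOUS** otherwise (e.g., flat trajectories, which exhibit neither
  signature; a degenerate initial spread below 1e-9 sets the convergence
  index to 1 so that it cannot certify convergence).

### Modified (autosome-anchored) TPM

Because sex chromosomes contribute very differently to male and female
transcriptomes, bulk samples are normalized as

`tpm(g) = (c_g / L_g) / sum_{a in autosomes} (c_a / L_a) * 1e6`

with `L` the CDS length (counting in this workflow is CDS-based), so the
*autosomal* mass is exactly 10^6 in every sample. The published rendering of
this formula carries unbalanced parentheses and stray `10e-6` factors; the
form above is the standard TPM with an autosome-restricted denominator,
which is the stated intent of the normalization.

### MSL proximity

Distances from gene bodies to the nearest MSL ChIP peak follow
`bedtools closest -d` semantics on 0-based half-open intervals: overlapping
*and bookended* pairs get distance 0, otherwise the edge-to-edge gap; strand
is ignored. The five-level scheme uses inclusive upper bounds (overlap /
<=1 kb / <=5 kb / <=20 kb / >20 kb); the binary scheme calls a gene proximal
iff its distance is strictly below 2 kb (so exactly 2,000 bp is distal).
Genes on chromosomes without any peak are flagged rather than given a
distance. Whether gene bodies or TSSs anchor the distance is not specified
upstream; gene bodies are used, matching `closest` run on gene features.

### Gametolog calling

One CDS per gene (the longest; ties broken by smallest record id), then
masked reciprocal best hits: the ingroup CDS set is duplicated with neo-X
genes removed from one copy and neo-Y genes from the other, and each
outgroup gene is aligned against both. "Best hit" is the highest
Smith-Waterman local-alignment score (match +1, mismatch -2, gap open -5,
gap extend -2, affine; the first base of a gap costs the open score), with
ties broken by the longest aligned length and then the smallest subject id
for determinism. The description of best hits as having the "highest
e-value" upstream is read as a typo for best (lowest); since alignments are
scored directly here, best simply means highest score. A pair is kept iff
mutual; a partner on an unexpected chromosome (a moved gene) is not recorded
as a gametolog. Local alignment is computed by Biopython's `PairwiseAligner`
(an exact dynamic-programming implementation standing in for a seeded
aligner at these scales).

A neo-Y CDS is counted truncated iff strictly shorter than 80% of its neo-X
partner. Y-biased genes are called per trio with a one-sided exact binomial
test of the pooled neo-Y count against half of the X+Y total,
Benjamini-Hochberg corrected (flag iff q <= 0.05 and Y > X); pooled counts
rather than replicate-level testing is an assumption recorded here. Combined
dosage is `log2((E_X + E_Y + eps) / (E_out + eps))`; ribosome occupancy is
`(ribo + eps) / (rna + eps)`. The pseudocount `eps` is 0 whenever both sides
are positive and 0.01 TPM otherwise.

### Cross-species comparison

Per-ortholog `log2((E_outgroup + eps) / (E_ingroup + eps))` on
modified-TPM tables, with per-chromosome medians and two-sided Wilcoxon
rank-sum tests of each chromosome class against the rest; pairs at zero in
both species are dropped. Gene movement is tabulated as a 2x2
(moved/retained x focal/contrast source chromosome) with a two-sided Fisher
exact test; the table itself is returned so users control the margins. Raw
p-values are reported throughout (matching how rank-test thresholds are
conventionally quoted for these comparisons), with Benjamini-Hochberg
q-values as an additional column.

## The synthetic-data generator

The generator emulates the study design, not any particular dataset.
Expression of gene *g* in a cell of stage *t* has expectation

```
mu[g, t] = B_g * A_t * (CN_g / 2) * D[g, t] * S[g, t] * gamma_g
D[g, t]  = min(1 + (boost_chrom - 1) * profile_t * exp(-d_g / lambda), boost_chrom)
```

* `B_g` — lognormal per-gene baseline (defaults log-mean 1, log-sd 1, the
  broad spread typical of expressed testis genes).
* `A_t` — global stage amplification, peaking in late spermatocytes
  (default 1, 1, 1, 1.3, 2, 4, 4, 3 across hub, cyst, GSC, SG, SC_early,
  SC_late1, SC_late2, ST_early). It cancels in every X:A ratio.
* `CN_g` — copy number (1 on X arms and the neo-Y in males, 2 on autosomes).
* `D` — dosage-compensation boost, decaying with the gene's distance `d_g`
  to the nearest MSL peak (`lambda` = 10 kb). Default per-arm maxima: 2.0
  (ancestral X, full compensation), 1.6 (fused arm), 1.2 (young neo-X,
  partial); 1.0 elsewhere. `profile_t` in [0, 1] scales compensation by
  stage: when unset it is derived from the simulated regime — a linear
  decline to 0 across the meiotic stages under `DC_SHUTDOWN`, all ones
  otherwise.
* `S` — meiotic silencing: `msci_factor` (default 0.4) on X-linked genes in
  meiotic stages under the `MSCI` regime, else 1.
* `gamma_g` — neo-Y retention, logit-normal per gene (default mean 0.5),
  1 elsewhere. Neo-Y genes share their neo-X partner's baseline (common
  ancestry), so Y expression tracks the ancestral allele level.

Counts are negative binomial (gamma-Poisson, shared dispersion 0.1) around
`mu` times a lognormal per-cell library-size factor. Genes are laid out
without overlap on linear chromosomes (lengths 1-3 kb, exponential
intergenic spacing); MSL peaks are fixed 500 bp intervals placed on X arms
at 50 per Mb, preferentially near high-baseline genes when `peak_bias > 0`
(high-expression neighborhoods attract entry sites). Default panel sizes are
realistic Muller-element gene counts (2,500-2,800 genes per arm, 1,100
expressed neo-Y genes, 80 on the dot) with 300 cells per stage; at these
sizes chromosome-median estimates are stable to roughly +-0.02.

Bulk two-species tables give the outgroup every gene at its diploid baseline
`B_g`; the ingroup expresses the neo-X at `B * 0.5 * D` (with a per-tissue
compensation profile, default 0.5 in testis and 1 elsewhere) and the neo-Y
at `B * 0.5 * gamma`. Pre-ZGA embryo samples carry the identical maternal
pool `B_g` in both species (zero for the male-limited neo-Y, which is also
absent from female tissues). Measurement noise is multiplicative lognormal
(log-sd 0.2).

CDS trios draw a random ancestral CDS (150-600 bp by default), spawn neo-X
and neo-Y descendants with independent per-site substitutions (default 5%),
lose each descendant with configurable probability, and 3'-truncate a
fraction of neo-Y copies; the truth table records pairings, losses and
truncation fractions.

**Ground truth.** The generator records `mu` and defines the true X:A of a
chromosome at a stage as the median of `mu` over its genes divided by the
median over the reference-arm genes — the same estimand the pipeline
targets. With finite random baselines this median-based truth fluctuates
around the analytic composition value (exactly 1 for diploid arms, exactly
0.5 for an uncompensated single-copy arm, only when baselines are held
equal, i.e. `baseline_logsd = 0`); recovery tests therefore compare the
pipeline against the recorded truth, and exact-composition tests use
equal baselines.

**What the generator does not emulate:** ambient RNA, doublets, replicate
batch effects, sperm-morph heterogeneity, ampliconic copy-number expansion,
small-RNA production, and any clustering/cell-type-assignment error (labels
are taken as given). Passing tests therefore certify the inference machinery
under the stated generative assumptions, not robustness to these real-data
artifacts.

## Numerical choices and degenerate inputs

* Fold changes between stages use a pseudocount of 1 count (stage-restricted
  genes would otherwise hit log of zero); ratio operations on normalized
  units use the 0-or-0.01 rule above.
* A zero reference median at any stage is an error naming the stage, not a
  silent NaN; an empty gene filter result is allowed with a warning.
* Categories with fewer than 3 genes keep their median but leave rank tests
  undefined, with a warning.
* Bootstrap, simulation and alignment tie-breaks are fully deterministic
  given the recorded seeds; identical configurations produce bit-identical
  outputs.
* Single-cell matrices are kept dense: simulated testis counts run at ~85%
  nonzero, where dense storage is both smaller and faster than CSR.

## Problem sizes used in the checks

The test suite runs the regime classifier over 20 seeded shutdown and 20
seeded MSCI simulations at the default scale; the copy-number-floor check
uses a ~2,800-gene x 300-cell cohort with a moderate baseline spread
(log-sd 0.5), sized so the finite-panel median noise sits well inside the
+-0.03 tolerance; gametolog recovery runs 200 trios at 0% and 5% divergence;
the maternal-pool null uses 1,500 ortholog pairs. `scripts/acceptance.py`
re-runs the maternal-pool analysis from scratch at the same scale.

## Known limitations

* The regime thresholds are calibrated to separate the two generative
  regimes at the default simulation scale; on real data with different
  noise structure they are starting points, and the recorded-statistics
  report exists precisely so users can apply their own rule.
* Reciprocal best hits use full local alignment, adequate at hundreds of
  trios; genome-scale CDS sets would need a seeded pre-filter.
* The eight default stage labels are treated as opaque ordered stages;
  nothing in the package depends on their biological names.
* The exact contingency-table margins behind published gene-movement tests
  are not recoverable from text, so the movement operation exposes its 2x2
  for the user to supply margins rather than asserting a specific p-value.
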