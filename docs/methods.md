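# Methods

## Overview

`ricenet` implements a conditional transcription-factor (TF) to biological-
process association analysis for plant expression compendia, of the kind
used to nominate regulators of photosynthetic carbon metabolism (PCM) in
rice, together with the surrounding microarray differential-expression and
enrichment machinery and the physiological measurement formulas used in
drought phenotyping.  Because the original multi-hundred-sample GEO
compendium and the AgBase annotation snapshot are external resources, the
package is exercised and validated on a synthetic test-bench with planted
structure; every recovery claim below is therefore a statement about the
generator's conditions, not about real rice data.

## Association-network model

Input is a genes x samples expression matrix per condition (control,
stress), pooled from several datasets/stages and assumed RMA-normalized
upstream.  The stages are:

1. **Replicate averaging and stage scaling.** Replicate columns are
   averaged; then the pooled distribution of all expression values within a
   dataset/stage block is centred and scaled to mean 0, s.d. 1 (population
   s.d., so the post-condition is exact).  The text this follows speaks of
   scaling "the distribution of gene expression values within a
   developmental stage", singular, which we read as one mean/s.d. per stage
   block; per-gene scaling within the stage is available via
   `scale_within_stage(..., per_gene=True)` for users who prefer the other
   reading.
2. **Correlation and normalization.** Pearson correlations between every
   gene and every TF across all samples; Fisher Z-transform
   (z = arctanh r, |r| clipped to 1 - 1e-6); standardization of the pooled
   Z values to N(0,1) by subtracting the empirical mean and dividing by the
   empirical (population) s.d. over all gene-TF entries, excluding
   self-pairs (a TF with its own gene).  Empirical standardization is the
   default because a compendium mixes datasets with different sample sizes;
   the analytic null scaling z * sqrt(n - 3) is a switch
   (`analytic_standardization=True`).
3. **CLR-style specific scores.** Each normalized correlation C_ij is
   re-expressed relative to the background of correlations involving either
   gene i (its row, over TFs) or TF j (its column, over genes):
   z_row = (C_ij - mean_i)/sd_i, z_col = (C_ij - mean_j)/sd_j, combined by
   Stouffer's method, S_ij = (z_row + z_col)/sqrt(2).  Backgrounds use
   sample s.d. (divisor n-1) and exclude self-pairs.  Unlike the original
   CLR formulation the background z-scores are **not** clamped at zero:
   negative (anti-correlated) associations are meaningful here and must
   survive into the process level.
4. **Process summarization.** For a gene set G_k (a GO biological process
   after propagation/filtering/pruning, see below), the TF-process
   association is a Stouffer combination over member genes:
   A(j,k) = sum_{i in G_k, i != gene(j)} S_ij / sqrt(|G_k ∩ genes(S) \ {j}|).
   The TF's own gene is excluded from its sets.  Processes with fewer than
   `min_size` (default 5) scorable members are dropped.  A mean-based
   summary is not offered separately since it differs from the Stouffer sum
   only by the sqrt(|G_k|) scale shared within each process column.
5. **Contrast and screening.** The composition is run independently per
   condition.  Each (TF, process) pair is categorized from
   (a_control, a_stress) with two thresholds, tau_pos = 2 and tau_zero = 1
   on the z-like association scale: `maintained` (both above tau_pos),
   `attenuated_to_none` (positive association collapsing into
   [-tau_zero, tau_zero]), `flipped` (positive to below -tau_zero), `gained`
   (the symmetric rule: stress association above tau_pos from a control
   value at or below tau_zero) and `other`.  Candidate regulators of a set
   of query processes are the TFs whose control association exceeds tau_pos
   on **all** queries, ranked by their minimum association over the queries;
   candidates are first intersected with a TF subset and, when supplied, a
   list of differentially regulated TFs, mirroring a screen restricted to a
   drought-regulated TF family.

### Null behavior of process scores (why screening needs the TF restriction)

Process-level Stouffer scores are *not* N(0,1) under the null.  With n
samples, the sampling correlation between the driver TF of a module and
any other TF has s.d. ~ 1/sqrt(n); that error propagates coherently into
all module members (they share the driver's profile), so the Stouffer sum
amplifies it by sqrt(|G_k|) instead of averaging it away.  At the default
study conditions (n = 120, |G_k| = 20) null process scores have s.d. ≈ 3.
Consequently tau_pos = 2 separates planted from null associations only in
rank terms (AUROC ≈ 1), not as an absolute significance cut; a screen over
all TFs at tau_pos = 2 admits chance passers.  The screen is therefore
meant to be run, as in the motivating analysis, on a pre-selected candidate
subset (a TF family intersected with differentially regulated TFs); the
test-bench uses the planted stress-responsive TFs as that subset.  This is
a property of the summarization statistic worth keeping in mind with real
compendia as well: association magnitudes grow with set size and member
redundancy.

## Gene-set construction

Ontology handling follows the standard closure semantics: a gene annotated
to a term is annotated to all its ancestors along `is_a` and `part_of`
edges (OBO parsing via `obonet`; obsolete terms excluded; cycles rejected).
Gene sets are optionally intersected with the expression universe (default
in the pipeline, since only array genes can be scored), then filtered to
`min_size <= |genes| < 1500` — the upper bound strict, the lower bound
(default 5) our addition since hypergeometric tests on near-empty sets are
uninformative.  Redundancy pruning walks the terms sorted by set size
(descending, ties by term id; descending so the larger, more general
representative survives) and removes a later term B relative to an earlier
retained term A iff ||A| - |B|| < 5 **and** Jaccard(A, B) >= 0.9 — both
bounds read strictly/inclusively as stated, conditions conjunctive.
Removed terms never trigger removals; a second pass is a no-op.

## Differential expression and enrichment

Genes whose interquartile range across samples is strictly below the
median IQR are removed first (quartiles by linear interpolation, the
type-7 convention; IQR filters are sensitive to the quantile definition,
so this is pinned).  The two-group test is the empirical-Bayes moderated
t: per-gene pooled variances s² on d = n1 + n2 - 2 df are shrunk toward a
prior, s̃² = (d0 s0² + d s²)/(d0 + d), with (d0, s0²) fitted by moment
matching on log s² (digamma/trigamma moments of the scaled-F model;
trigamma inverted by Newton iteration).  When the observed log-variance
dispersion does not exceed chi-square sampling noise the prior df is
infinite and the pooled mean variance is used as the scale.  The statistic
is referred to a t distribution on d0 + d degrees of freedom, capped at the
pooled residual df across genes.  A plain pooled t is available with
`moderated=False`.  The implementation is cross-checked in the test suite
against the R/limma workflow on a shared fixture (agreement to ~1e-6 in t).

P-values become q-values by Benjamini-Hochberg step-up with pi0 = 1
(Storey-type pi0 estimation is deliberately not applied; with it, calls
could only become more liberal).  Genes with q < 0.01 (strict) are called
differentially expressed.  Enrichment per gene set is the upper-tail
hypergeometric probability P(X >= k), BH-adjusted across sets, significant
at q < 0.01; significant sets are connected into an overlap graph with an
edge where the Jaccard coefficient of their DE-overlap gene sets is at
least 0.25 (the "significant overlap" cut is not externally specified;
0.25 is our default and configurable).

## Phenotype metrics

All formulas are direct: RWC% = (FW-DW)/(RW-DW) x 100; WUEi = Pn/E;
WUEg = (BIO45-BIO31)/WUc with WUc the sum of daily water additions;
Fv/Fm = (Fm-Fo)/Fm; qPCR relative expression 2^-ddCt with
dCt = Ct(target) - Ct(reference) per sample and ddCt relative to the
calibrator; ChIP fold enrichment with dCt = Ct(specific Ab) -
Ct(nonspecific Ab); spikelet fertility, single-grain weight and harvest
index as the usual ratios.  Ct-based quantities are invariant to adding a
constant to every cycle value, and RWC is invariant to rescaling all
weights; both invariances are property-tested.  Percent grain-yield
increase over wild type is rounded half-to-even to one decimal.
Recomputing the bundled yield-trial percent-increase column from the
printed 1-2 decimal GY means reproduces 5 of the 10 published cells
exactly and all 10 within 0.1 percentage points; the discrepant cells stem
from the original computation using unrounded means, so 0.1 is the honest
reproduction tolerance (`ricenet.datasets` records which cells are
arithmetically consistent).

## Synthetic test-bench

`ricenet.simulate` generates every input from a single seeded
configuration (NumPy `default_rng` with per-artifact streams; identical
config implies bit-identical output):

- **Compendia.** TF profiles i.i.d. standard normal per sample; each
  module member of TF t is coupling·x_t + sqrt(1 - coupling²)·eps with
  eps ~ N(0, noise_sd), so at noise_sd = 1 the population correlation with
  the TF equals the coupling exactly, making recovery bounds analytic.
  Background genes are i.i.d. noise.  Samples are assigned to datasets
  round-robin, exercising per-stage scaling without extra configuration.
- **Ontology.** A rooted DAG (is_a/part_of only): one term per planted
  module annotated exactly to its members; planted redundant pairs built
  as a term A of ~40 genes and a child B = A minus two genes, so after
  propagation the pair meets both pruning conditions by construction; the
  remaining terms form chains up to `max_depth` with random annotations.
- **Two-group experiment.** A wild-type vs transgenic design with
  `n_de_genes` genes shifted by `effect_size` in the transgenic group.

The default study configuration — 600 genes, 30 TFs, 5 modules of 20
genes at control coupling 0.8, stress couplings alternating {0, -0.6},
120 samples per condition in 4 datasets, noise s.d. 1, a 40-term ontology
with 3 redundant pairs, and a DE experiment of 50 genes shifted by 3 s.d.
at 10 samples/group (seed 17) — is deliberately desk-scale with high
statistical power.  The TF assignment is: TF g0000 drives two modules
(the screening queries; stress couplings 0 and -0.6) and g0001-g0003 one
module each, so the bench plants an all-positive candidate, attenuations
and sign flips simultaneously.

What the generator does *not* emulate: probe-level signal, RMA, batch and
dataset-specific covariance structure, missing values, correlated
backgrounds, realistic GO topology, or heavy-tailed expression noise.
Passing recovery tests therefore demonstrates correctness of the
computations and their behavior under the stated sampling model, not
performance on real microarray compendia.

## Numerical choices and degenerate inputs

- |r| clipped to 1 - 1e-6 before arctanh; zero-variance genes correlate 0
  with a warning; zero-s.d. CLR backgrounds contribute a 0 z-component
  with a warning; constant stage blocks and single-sample stages are
  errors, as are constant correlation matrices.
- Population s.d. wherever an exact mean-0/s.d.-1 post-condition is
  asserted (stage scaling, global standardization); sample s.d. (n-1) for
  CLR backgrounds.
- Gene harmonization across datasets by intersection (no imputation);
  sorted gene order for determinism; all list-valued outputs use explicit
  (score, id) tie-breaks.
- p-values clipped into (0, 1] before BH; the hypergeometric tail uses
  `scipy.stats.hypergeom.sf(k-1, ...)` which the suite checks against
  exhaustive enumeration for every universe size up to 25.

## Problem sizes used in the checks

The bundled checks run the full network pipeline at the 600 x 120 x 2
study scale (seconds on one core), the CLR oracle on 100 random 10 x 5
matrices, the DE null calibration on 50 simulated 200-gene experiments,
and the hypergeometric enumeration up to N = 25.  These sizes are chosen
so the whole bench stays interactive while keeping every estimate's
Monte-Carlo error far below the asserted margins.

## Known limitations

- Association scores scale with gene-set size; comparisons across
  processes of very different sizes should rely on ranks or on explicit
  null calibration (see the null-behavior note above).
- The moderated t assumes exchangeable per-gene variances around a single
  scaled-F prior; strong variance clustering (e.g. intensity-dependent
  noise) violates the moment-matching fit.
- BH with pi0 = 1 is conservative when many genes are truly affected.
- The contrast categories depend on (tau_pos, tau_zero); they are labels
  for reporting, not hypothesis tests.
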