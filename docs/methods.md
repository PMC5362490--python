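# Methods

## Problem and overall design

`epioutlier` implements an integrative discovery-and-validation workflow
for heterogeneous carcinoma cohorts profiled on paired expression and
promoter-methylation platforms.  Solid tumors often alter a driver gene in
only a subset of cases, which dilutes cohort-level statistics such as the
t-test.  The workflow therefore (1) scores every gene with a rank-sum
*outlier* statistic against an empirical null built from normal tissues,
(2) intersects high-scoring candidates with promoter methylation via the
sign of the expression–methylation Spearman correlation to nominate
epigenetically silenced genes, (3) provides the confirmatory statistics
used on an independent validation cohort (pooled t-test, 2^−ΔΔCt qPCR
quantification, bisulfite methylation calls, Fisher exact tests), and
(4) provides a pathway arm (marker-gene split, empirical-Bayes moderated
t, BH-FDR, rank-based gene-set test).  A synthetic cohort generator with
full ground truth makes every stage testable without any external data.

## Probe-to-gene summarization

Expression probes mapped to a gene are collapsed either by the per-sample
mean over all probes (`mean_of_probes`, the default) or by keeping the
single probe with the highest across-sample mean (`max_mean_probe`).  Both
conventions exist in practice and can produce different gene-level
estimates; both are therefore first-class options.  Methylation betas
(β = M/(M+U), the fraction of methylated signal at a probe) are collapsed
to the gene's *highest-methylation* representative: the single probe with
the highest across-sample mean beta.  Choosing one coherent probe — rather
than a per-sample maximum that would mix probes — preserves the within-gene
sample ordering, which matters because the downstream integration step is a
rank correlation.  A per-sample-max variant is available behind a flag.
Ties between probes with equal means are broken by the lexicographically
smallest probe id so output is deterministic.

## The rank-sum outlier score

For gene *g* with values x over N samples (T tumors, ≥ 2 normals):

1. The normal samples define the empirical null band: their q_low and
   q_high quantiles (defaults 0.10 / 0.90), computed by linear
   interpolation between closest order statistics (index h = (n−1)q + 1),
   so results are bit-reproducible.
2. A tumor t is a **right-tail outlier** iff x_t > q_high and
   x_t − q_high ≥ δ, where δ ≥ 0 is a minimum-change floor in log2 units
   that suppresses exceedances too small to be biologically meaningful.
3. All N samples are ranked ascending with average ranks for ties;
   the right-tail score is Σ r_t / N over outlier tumors.  The left tail
   is symmetric: x_t < q_low, q_low − x_t ≥ δ, descending ranks
   (N + 1 − r_t).
4. The gene's score is max(left, right); the direction is the winning
   tail (an exact tie goes to "up" and is logged).

Each outlier tumor contributes at most 1, so the score is bounded by the
tumor count and reads roughly as "number of strongly outlying tumors".
Genes are ranked by score (ties broken by gene id) and selected at a score
cutoff (default 2.3) or as a top-k list.  Ranks are normalized by the total
sample count N; normalization by tumor count is available
(`rank_norm="n_tumor"`), and `delta_sweep` reports selection counts over a
grid of δ and both normalizations for sensitivity analysis.

### The minimum-change floor δ

The floor has two natural scales: a "10% expression change" reading
(≈ 0.14 log2 units) and a fold-change reading of several log2 units.  The
constructor default is 0.14, but the **simulation studies in this package
run the discovery scan at δ = 1.0 log2 (a 2-fold change)** — the field's
conventional threshold for a biologically meaningful expression difference.
The choice is not cosmetic: with 44 tumors and 25 normals, per-gene noise
sd of 0.2–0.6 and a 90th-percentile null boundary, a 0.14 floor leaves
each null tumor a few-percent chance of a spurious exceedance, and with 44
tumors the typical *null* gene then collects several high-rank outliers
and scores above 2.3 — a selection at that cutoff would retain most of the
genome.  A screen that yields of order 10² candidates from of order 10⁴
genes at a 2.3 cutoff is only consistent with a floor of roughly this
magnitude, which is why the simulated studies adopt the 2-fold value.  δ
remains fully configurable for data with different noise scales.

## Expression–methylation integration

For each selected candidate with a promoter probe, the Spearman
correlation (Pearson correlation of average-tie ranks) between gene-level
expression and beta is computed over the shared samples — all samples by
default, since silenced tumors versus unmethylated normals are exactly the
signal of interest; a tumor-only mode exists.  Samples missing from either
matrix are dropped pairwise; genes with fewer than 3 usable samples, or a
constant vector, get a missing ρ.  Selection requires **strictly** negative
ρ (ρ = 0 is not negative); no significance test is applied — the filter is
on sign only, and candidates without any promoter probe are carried with
`has_promoter_probe = False` rather than dropped silently.

## Validation statistics

* **t-test** — pooled-variance Student t (default) or Welch, two-sided,
  applied to log-scale expression values and to log2 of qPCR relative
  quantities.  Two degenerate equal groups return p = 1 by convention.
* **2^−ΔΔCt** — ΔCt = mean Ct(target) − mean Ct(reference) over
  triplicates; ΔΔCt subtracts a calibrator ΔCt; RQ = 2^−ΔΔCt.  The default
  calibrator is the normal group's mean ΔCt (the comparator population);
  a named sample can be used instead.
* **Bisulfite calls** — per CpG site the methylated fraction is
  C/(C+T) peak height; the mean over usable sites is thresholded at
  0.25 / 0.75 into unmethylated / hemimethylated / methylated.  The
  thresholds are symmetric defaults (chromatogram reading is traditionally
  manual and no canonical numeric cutoffs exist) and are parameters.
  Zero-height sites are skipped; an all-zero trace is an error.
* **Fisher exact** — two-tailed by the probability-mass convention: the
  sum of hypergeometric probabilities of all tables with the observed
  margins no more probable than the observed table (relative tolerance
  1 + 1e−7).  "Two-tailed" admits several definitions; this one is fixed
  because it is the common software convention.  A zero margin gives
  p = 1.  Frequency comparisons collapse hemimethylated + methylated into
  "any methylated signal".

## Pathway arm

Tumors are sorted by the marker gene's expression (ties broken by sample
id) and halved; with an odd count the median sample joins the low group
(logged).  For a contrast (group1, group2) — reported effects are always
group1 − group2 — each gene gets log_fc (difference of means) and a pooled
residual variance s²_g on d_g = n₁ + n₂ − 2 df.  The empirical-Bayes prior
(d0, s0²) is estimated by closed-form moment matching of log s²_g against
its theoretical scaled-F log-moments (digamma/trigamma identities; the
trigamma inverse is solved by Newton iteration); zero-variance genes are
excluded from estimation and flagged.  The posterior variance
s̃² = (d0·s0² + d_g·s²_g)/(d0 + d_g) replaces s²_g in the t statistic,
which is referred to a t distribution on d0 + d_g df (normal when d0 is
infinite).  d0 → 0 recovers the ordinary pooled t; d0 → ∞ pools every gene
to s0².  BH-FDR is applied within the *stated* gene family — the tested
gene set, passed explicitly — not the whole genome.

The set-level test is a Wilcoxon rank-sum of the set's moderated
t-statistics against all remaining genes: "up"/"down" are one-sided tail
probabilities of the set's rank sum; "either" is two-sided via
min(1, 2·min(p_up, p_down)).  Small instances (|set| ≤ 10, n ≤ 25) are
evaluated by exact enumeration over all subsets of the observed ranks;
larger ones use the normal approximation with tie correction and a 0.5
continuity correction.

## Synthetic cohort generator

Defaults mirror the discovery-study design: 44 tumors, 25 normals, 5,000
genes with 1–4 probes each, 50 silenced + 50 upregulated planted genes,
each altered in 30% of tumors (affected subsets drawn independently per
gene, capturing tumor heterogeneity), expression effect 2.0 log2 units,
promoter betas near 0.10 rising by ≈ 0.5 when silenced, gene-specific
Gaussian noise with sd ~ Uniform(0.2, 0.6), and baselines
μ_g ~ Uniform(4, 12) log2 shared between classes.  For silenced genes the
expression loss and beta gain in an affected tumor are coupled through a
shared per-sample latent intensity (truncated Normal(1, 0.15)), so negative
Spearman correlation is a structural property of affected samples rather
than an artifact of independent shifts; the coupling spread is
configurable.  Upregulated planted genes leave methylation untouched —
methylation-independent alterations that the integration step should *not*
select.  M/U intensities are generated to satisfy β = M/(M+U) exactly;
70% of background genes get promoter probes (silenced genes always do), so
the no-probe path is exercised.  An optional planted "pathway" set is
co-shifted in the lead silenced gene's affected tumors, giving the set test
a true positive tied to the marker split.  Heavy-tailed noise (t with 5 df,
scaled to unit variance) is available to stress the rank statistic.
Bisulfite traces draw 5 CpG sites per promoter with C fractions
~ clipped Normal(β, noise); qPCR uses Ct(reference) ~ Normal(20, σ)
independent of class and Ct(target) = 40 − x so one log2 unit equals one
cycle.  Clinical covariates (HPV status, anatomic site) are generated with
a configurable association odds ratio, default 1.0 (no association).  All
randomness flows from the single config seed; equal seeds give
bit-identical cohorts.

What the generator does **not** emulate: array-level artifacts (batch
effects, probe cross-hybridization, detection p-values, background
correction), correlated gene–gene structure outside the planted pathway
set, copy-number or mutation confounding of expression, and cell-type
admixture.  Recovery results on this generator therefore demonstrate the
statistical machinery under its stated model, not performance on raw array
data, which additionally depends on upstream normalization quality.

## Problem sizes used in the reproduction script

`scripts/acceptance.py` re-measures the headline quantities at the
cohort's native scale: five 5,000-gene planted cohorts for recovery, three
5,000-gene null cohorts for false-positive control, 100 replicates for
gene-set calibration, a 2,000-gene cohort with a 40-gene planted set for
the pathway arm, and 500/200-gene cohorts for the validation arm — sizes
at which every Monte-Carlo fraction is estimated from hundreds of events
while the whole script stays in the seconds range.

## Known limitations

* The rank-sum outlier score has no closed-form null distribution here;
  selection is by score cutoff, not significance level, matching how such
  screens are actually run.  Permutation p-values are deliberately out of
  scope.
* The literature contains several variants of the rank-sum outlier
  statistic (e.g. normalization by tumor count rather than total N); this
  implementation fixes one convention and exposes the alternative
  normalization for sensitivity sweeps rather than guessing intent.
* The integration filter is sign-only: with many candidates, some
  methylation-independent genes will show chance-negative ρ.  This is
  faithful to the screening design, which treats the filter as candidate
  triage, not inference.
* The moderated-t hyperparameter estimator assumes a common residual df
  across genes (true for complete two-group designs, the only design the
  pathway arm builds).
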