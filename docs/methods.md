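# Methods

This note documents the statistical procedures implemented in `loyscan`,
the assumptions behind them, the synthetic cohort generator that the test
suite exercises them on, and the numerical choices made where the design
was genuinely open.

## LOY calling

A male cell is assigned LOY if and only if the summed UMI count over the
genes of the Y male-specific region (MSY) is zero in **both** counting
sources.  The MSY is the fixed GRCh38 interval chrY:2,781,480–56,887,902;
a gene belongs to it only when fully contained (genes straddling a
boundary are excluded — conservative, in keeping with the rule's
specificity-first stance).  The rule is asymmetric by design: ambient RNA
contamination can add stray MSY reads to a true LOY cell (a false
negative) but can never delete reads from a non-LOY cell, so a cell with
any MSY read is never a false-positive LOY call.  Consequences:

* Sensitivity is bounded by the Poisson probability that a normal cell
  yields zero MSY reads in both sources; low-depth cells inflate this, so
  UMI sensitivity filters (drop the lowest 5/10/15% of cells by depth) are
  provided to check robustness of downstream associations.
* Cells with zero total UMIs in both sources are uninformative and are
  excluded from calling (flagged, not silently dropped).  The published
  method does not discuss this degenerate case.
* Female cells are counted but never assigned an LOY flag; their MSY read
  rate is a useful ambient-contamination diagnostic.
* Whether MSY counts are summed across genes or required to be zero gene
  by gene is immaterial — the two formulations give identical calls —
  summation is implemented.

## Donor clonality and age

Per-donor LOY percentage uses all assigned cells; *expanded clonality* is
≥ 10% LOY (the boundary counts as expanded).  The age model regresses the
empirical logit `logit((x + 0.5) / (n + 1))` of the donor's LOY count on
age, sequencing pool (dummy-coded) and ten genotype PCs by OLS.  The
smoothing constant is required because donors with 0% (and occasionally
100%) LOY exist; the source method states only that percentages were
logit-transformed, so the standard empirical-logit rule was adopted.
Collinear or constant covariates are dropped and flagged rather than
allowed to poison the fit.

SNP-array concordance is a Pearson correlation (Fisher-z 95% CI,
Benjamini–Hochberg FDR across cell types).  The mCA–LOY independence test
is a chi-square without Yates continuity correction (stated in the
output); an empty margin triggers a Fisher-exact fallback.

## Trajectories

Pseudotime is the arclength position on a principal curve fitted through a
low-dimensional embedding: initialize on PC1, then alternate lowess
smoothing of each embedding coordinate against the current ordering with
re-projection of cells onto the smoothed polyline; orient so the start
cluster has the lower mean and rescale to [0, 1].  The embedding itself is
pluggable — any 2-D (or low-D) manifold coordinates can be supplied; the
synthetic generator can emit a noisy parametric arc to test ordering
recovery.  Cells are then split into six near-equal quantile bins; ties at
bin boundaries are broken stably by (pseudotime, barcode) order, which
makes equal-count bins well defined.

The LOY-position model is a cell-level logistic regression of LOY status
on either a binary end-vs-start subtype indicator or the quantile as a
single numeric slope (one odds ratio per quantile step — the reported OR
per trajectory is a single number, which is why the numeric coding was
chosen over ordinal dummies).  Three variants: univariate; adjusted for
age, pool and ten PCs; additionally adjusted for rs2887399 dosage
(additive G/G = 0, G/T = 1, T/T = 2).  Because cells are nested in donors
and donor clonality varies over an order of magnitude, naive cell-level
standard errors are far too small; all fits use donor-clustered (sandwich)
covariance.  Perfect separation triggers a Firth-style penalized fit
(Jeffreys-prior adjusted Newton scoring), flagged in the results.
Age-stratified refits split donors (not cells) at the median age.
Families of results take Benjamini–Hochberg FDR.

One estimand subtlety: a cell-level logistic model without donor effects
estimates the *population-averaged* odds ratio, which the usual
non-collapsibility of logistic regression attenuates toward 1 relative to
the donor-conditional generative parameter — by roughly
`1/sqrt(1 + 0.346 σ²)` on the log scale for a normal donor offset of sd σ
(≈ 0.77 at the generator's σ = 1.4, so a conditional OR of 0.91 yields a
marginal estimate near 0.93).  Published ORs from the same model form are
marginal in exactly this sense; the clustered confidence intervals account
for the induced intra-donor correlation.

## Differential expression

**Hurdle model.** Per gene, a logistic regression of detection
(count > 0) and a Gaussian regression of log-normalized expression over
expressing cells, both on the group indicator plus the centered per-cell
detection rate (the standard nuisance covariate of hurdle models for
scRNA-seq dropout; it is dropped if degenerate, which can only happen on
toy matrices with fewer than three genes).  The hurdle p-value is the
upper tail of the summed LR statistics against a chi-square with the
combined df; the continuous part is fitted only when both groups have at
least two expressing cells (otherwise df = 1).  Filters: detection ≥ 1% in
each group and |avg log2 FC| ≥ 0.1, where
`avg_log2fc = log2((mean(expm1 x) + 1)_1 / (mean(expm1 x) + 1)_2)`.
Bonferroni correction uses the number of genes actually tested in the run,
recorded in the results.  The same machinery serves the old-vs-young
female contrast (group = age ≥ 67) and the XIST-exclusion replicate.

**Proportion pseudobulk.** For each gene, the proportion of expressing
cells per (donor, LOY-status) pseudobulk sample; only donors contributing
cells to both strata enter; LOY vs non-LOY donor proportions are compared
by a Wilcoxon rank-sum test — full enumeration of rank assignments when
the smaller sample has ≤ 8 donors, a tie-corrected normal approximation
otherwise (no continuity correction; the exact path takes over where it
matters).  The effect filter (minimum 0.1) applies to the proportion
difference, since the statistic is a proportion.

## X-inactivation

X genes are bucketed by locus first — PAR1 (chrX:10,001–2,781,479) and
PAR2 (chrX:155,701,383–156,030,895) membership by coordinates overrides
any curated class, the locus fact beating the tissue-derived label — and
otherwise by curated XCI degree (escape / inactive / variable, else
unclassified).  The direction summary reports, per cell type and class,
the share of tested genes significantly up or down (adjusted p < 0.05
split by log2 FC sign), a rank-sum comparison of the up- and down-shares
across cell types, and a gene-level roll-up (up-only / both / down-only
across cell types).  The *variable* class is summarized but sits outside
the headline up-vs-down comparison, which concerns PAR, escape and
inactive genes.

**Dip statistic and test.** The dip is the minimax distance between the
empirical CDF and the class of unimodal CDFs, computed by the classical
greatest-convex-minorant / least-concave-majorant algorithm on the sorted
sample (ties handled on the raw sample, not a histogram — a unimodal CDF
may carry one atom at its mode, which fits tied data better than any
continuous fit).  The statistic lies in [1/(2n), 1/4] and is invariant
under increasing affine transforms; it is *not* invariant under general
monotone transforms, because the unimodal class is not closed under them —
the test suite asserts the affine version and validates the algorithm
exactly against a linear-programming minimax oracle for n ≤ 8.
Significance uses a uniform(min, max) bootstrap of the same sample size —
the classical calibration; the reference distribution is named in the
result.  Because single-cell data are zero-inflated, the test runs on the
full vector and on the nonzero subset (default report: both).  Note that
the dip applied to heavily tied counts is conservative (atoms fit well);
in practice it is applied to log-normalized expression.

## Dynamics (LOY × pseudotime)

Per gene and lineage, nested linear mixed models with a donor random
intercept, fitted by maximum likelihood so the ANOVA-style comparison is a
valid LRT: the basic model has LOY, quantile (plus quantile² in the
quadratic form), age and ten PCs; the augmented model adds LOY × quantile
(and LOY × quantile²).  df = number of added terms.  The response is
log-normalized expression (a continuous approximation; a count-model
variant is out of scope).  Genes qualify when detected in ≥ 1% of cells in
at least three of the six quantiles ("expressed in a quantile" is not
defined by the source; 1% matches the DE filter).  Non-convergent mixed
fits fall back to donor fixed effects, flagged.  Bonferroni over the tests
run.

## Overrepresentation

Upper-tail hypergeometric test of significant DE genes passing a direction
and log2 FC cutoff (0.25 / 0.5 / 0.75) against each gene set, with the
universe equal to the genes that entered the DE run (the conservative
standard; the alternative whole-genome universe only inflates
significance).  Overlap ratio uses the in-universe set size as the
denominator.  BH-FDR within each (direction, cutoff) family.  The
hypergeometric tail is identical to one-tailed Fisher's exact — asserted
on random tables in the suite.

## QC and preprocessing

QC metrics (total UMIs, genes detected, mitochondrial fraction) map to
normal scores by percentile rank, `Z = Φ⁻¹((rank − 0.5)/n)` with midranks
for ties; cells with any metric below −3 or a mitochondrial score ≥ +2 are
removed.  Under the rank mapping a continuous metric always marks its
extreme ~0.1% at n ≥ ~1500, so the filter is applied once to the input
ranks (repeated application on large continuous data would keep shaving
tails).  Log-normalization is `ln(1 + count/total × 10⁴)` per cell.
Variable genes rank by mean-binned normalized dispersion with a robust
(median/MAD) within-bin z-score so that a single dispersed gene cannot
mask itself by inflating its own bin's spread.  Scaling regresses each
gene on covariates (mitochondrial fraction, pool), scales residuals to
unit variance, clips at ±10, and feeds an exact SVD for PCs.  Graph
clustering is a pluggable contract — any deterministic labeling is
accepted; the bundled helper uses a KNN graph with Leiden community
detection at resolution 1.0 and a fixed seed.  The bespoke, tested layer
is marker validation: each cluster is tested one-vs-rest for each
candidate type's markers (one-sided Wilcoxon rank-sum, Bonferroni within
cluster, log2 FC ≥ 0.25); clusters with no supported type, or enriched for
a contamination marker (e.g. CD3 genes in a monocyte subset), are
excluded.

## The synthetic cohort generator

The generator emulates the statistical structure of a multiplexed PBMC
study of 416 aged male donors, with one master seed and independent child
streams per stage (adding a stage never perturbs earlier draws; same seed
and truth give byte-identical outputs).

* **Donors.** True clonal fraction with `logit f = −3.853 + 0.013·age +
  N(0, 1.4)`; slope 0.013/yr is the study-scale age effect, and the
  intercept and spread are calibrated so the donor distribution matches
  the published cohort shape: mean ≈ 8.5%, expanded-clonality share
  ≈ 26%, per-donor range ≈ 1–55%.  Ages uniform on 19–93.  SNP-array
  fractions add truncated Gaussian noise (sd 0.30, sized so the
  cohort-level Pearson r with the true fraction is ≈ 0.34 — whole-blood
  arrays are a weak readout of PBMC clonality) and are censored below a
  detection floor of 0.02.  rs2887399 dosage ~ Binomial(2, 0.25), mCA
  flags independent Bernoulli(0.0625).
* **Cells.** Five lineages (B-in→B-mem, mono-c→mono-nc, NK→NKr,
  CD8nc→CD8et, CD4nc→Treg) weighted by their observed abundances;
  pseudotime U(0, 1); cell type from the position split.  LOY is Bernoulli
  with `logit p = a_lineage + (logit f_donor − mean) + ln(OR_lin)·(q −
  3.5)`, where the per-quantile odds ratios are 0.92 / 0.91 / 0.93 / 1.08
  / 1.04 for B / mono / NK / CD8 / CD4, and `a_lineage` is solved so the
  realized lineage LOY rate equals the abundance-weighted mean of its cell
  types' published rates.  The gradient is therefore exactly loglinear in
  the quantile, making the per-quantile OR the estimand of the downstream
  logistic model.  A consequence worth knowing: the strong *subtype*
  enrichment of Tregs (12.6% vs 5.8% in the real data) cannot coexist with
  a loglinear 1.04/quantile gradient, and the generator prioritizes the
  gradient — per-type marginal rates emerge from it rather than being
  enforced.  A cell type with baseline rate 0 never yields LOY cells.
* **MSY counts.** Two sources; non-LOY male cells draw Poisson totals with
  a depth-scaled mean (default 5 at median depth; a guaranteed-positive
  option exists for calibration tests); LOY and female cells draw only
  ambient Poisson strays (default rate 0).  Ambient contamination can
  therefore only create false negatives — the generative mirror of the
  calling rule.
* **Expression.** Negative binomial (gamma–Poisson, dispersion 0.5) over a
  compact panel: designated LOY effect genes (IL1B −0.22 log2 FC in
  classical monocytes, with a baseline keeping its detection mid-range so
  the effect also moves the donor-level expressing proportion; LGALS2,
  CD86, MYCL down in mono-c; CD99 down everywhere; escape-X genes +0.3
  everywhere), lineage markers upregulated 8× in their home types,
  mitochondrial genes for QC, and autosomal nulls.  XIST is a
  zero-dominated two-component Poisson mixture active only in LOY cells
  (activity probability 0.05, components at means 2 and 25 with weight
  0.5) — far rarer detection in real data; the rate is scaled up so
  desk-scale cohorts contain enough XIST-positive cells to exercise the
  dip machinery.
* **Dynamics response.** A helper draws a continuous response from the
  exact interaction model (donor random intercept sd 0.2, noise sd 1.0) so
  the mixed-model estimator has a perfectly specified recovery target.

What passing tests on this cohort do **not** show: robustness to doublets,
batch chemistry, realistic transcriptome breadth, non-loglinear gradients,
or the structural (cell-composition-driven) missingness of real SNP-array
calls — the generator's array noise is Gaussian, so the array-detected
share of donors is higher than the published 26%.

## Problem sizes and tolerances

The suite runs everything at desk scale: cohorts of 10–400 donors with
60–1000 cells each, expression panels of ~90 genes, 100–200 replicates for
recovery/calibration properties, dip bootstraps of 100–200 draws, exact
enumeration oracles at n ≤ 8.  Recovery checks assert 95%-CI coverage of
the planted parameter in ≥ 90% of replicates; calibration checks assert
type-I error within two points of nominal; the specificity property is
checked exhaustively on 10⁵ cells.  Logistic and OLS fits converge at
tolerance 1e-8–1e-9; mixed models use ML (Powell, then conjugate-gradient)
with a flagged fixed-effects fallback.
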