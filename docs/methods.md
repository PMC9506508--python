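# Methods

This note documents the models, defaults and numerical choices behind
`admixmet`, and what the synthetic-data generator does and does not
emulate.

## Ancestry estimation

The estimator is the supervised two-population admixture model: each of
an individual's two allele copies at AIM `m` descends from the West
African ancestral population with probability `q`, so the counted-allele
dosage is Binomial(2, π_m(q)) with π_m(q) = q·p_A,m + (1−q)·p_E,m.
Markers are treated as unlinked and reference frequencies as known
(plugged in), the standard supervised convention; panel uncertainty is
not propagated. Missing genotypes drop out of the individual's
likelihood (missing at random).

Reference frequencies use a configurable pseudocount (default 0.5 per
allele, i.e. p = (count + 0.5)/(2n + 1)) so that a genotype impossible
under one ancestry keeps a finite likelihood. AIMs are retained when the
absolute frequency differential is at least `min_diff` (default 0.30,
boundary inclusive).

ℓ(q) is concave (a sum of logs of affine functions), so the maximizer is
unique whenever any marker is informative. The default point estimate
runs EM (allele-level responsibility updates, tolerance |Δq| < 1e-8, cap
500 sweeps; the EM objective is nondecreasing and this is asserted in
tests). EM contracts slowly when the likelihood is flat near the
optimum, so estimates are finished with damped, clipped Newton steps on
the score — a pure numerical choice that leaves the estimand unchanged;
agreement with a 1e-6-resolution grid search is enforced in tests to
1e-4. A flat-prior posterior mean (Simpson integration on a 4097-point
grid, log-sum-exp stabilized) is available as `mode="posterior_mean"`
because Bayesian admixture software reports posterior summaries; at 84
informative markers the two agree to a few hundredths. Individuals with
no observed markers are returned as invalid (q = NaN); panels with
p_A = p_E everywhere set an `identifiable=False` flag.

The dichotomization cutoff is q = 0.45, inclusive on the high side
("GWAA ≥ 45%").

## QC battery

* **Filter**: exclude xenobiotics (exogenous compounds) and metabolites
  with missingness strictly greater than 60%. Exactly 60% survives.
* **Log transform**: natural log. Any base change is monotone and
  alters no downstream decision; natural log keeps effect sizes on the
  same scale as the regression coefficients.
* **KNN imputation** (k = 10): a missing entry is the mean of its
  metabolite over the k nearest samples, Euclidean distance on z-scored
  shared-observed metabolites, neighbours restricted to samples observed
  at that metabolite, median fallback. Imputation feeds **only** the
  PCA-based diagnostics, PLS-DA and cluster PC1; all association models
  run on non-imputed data with casewise deletion.
* **Sample outliers**: PCA |score| > 3 SD on either of the first two
  components, and standardized Euclidean distance (SED) above
  mean + 3 SD. The 3-SD rules are conventions, configurable and echoed
  in the QC report.
* **Bland–Altman**: samples are paired deterministically (consecutive
  pairs after sorting ids within each ancestry subgroup; a seeded random
  pairing mode exists). A pair is an outlier for a metabolite when its
  difference leaves the mean ± 1.96 SD limits of agreement; metabolites
  with > 5% outlying pairs are flagged. On light-tailed (e.g. simulated
  Gaussian) data the outlier fraction hovers at its 5% expectation and
  the flag approaches a coin flip; it is informative on the heavy-tailed
  abundances real LC-MS produces. Metabolites with < 3 complete pairs
  are recorded as unflaggable.
* **CV**: the top 10% of metabolites by coefficient of variation
  (sample SD / mean on raw values; CV is scale-free, so the original
  scale is the conventional choice), ties broken by id.

All flags are advisory: flagged metabolites stay in every analysis;
flagged samples are removed only in the screening sensitivity re-run.

## Screening

Per metabolite: OLS of log abundance on the group indicator plus age,
sex, site, log PRA and batch; categorical covariates are reference-level
indicators with the lexicographically first level as reference
(deterministic across runs). The solver is `numpy.linalg.lstsq` with
classical standard errors; statsmodels OLS is the cross-check in the
test suite. A metabolite constant over the retained samples returns a
coefficient of exactly 0 with p = 1. Metabolites with n ≤ p after
casewise deletion are skipped with a reason and excluded from the BH
family — no p-value exists for them. BH q-values come from
statsmodels' step-up implementation; the exhaustive step-up oracle in
tests guards the rejection set. The screening threshold FDR < 0.2 is
deliberately lenient (type II error matters more at this stage). PLS-DA
(two NIPALS components via scikit-learn on the centred imputed matrix;
separation = centroid distance on component 1 in pooled within-group
SDs) is descriptive and gates nothing.

## Clustering

Weights w_ij = 1/(1 + exp(−s(|r_ij| − τ))) with τ the median
off-diagonal |r| and s swept over {1, 2, 4, 8, 16, 32}; the partition
maximizing weighted Newman modularity over the grid wins, ties toward
smaller s. Unsigned |r| lets anti-correlated metabolites co-cluster;
their signs re-emerge in the PC1 loadings. For n ≤ 8 the optimum is
found by exhaustive enumeration of all set partitions (Bell(8) = 4140);
above that, greedy pairwise agglomeration with deterministic lowest-id
tie-breaking followed by single-move refinement. Degenerate all-equal
weights return one cluster with a warning.

The biology pass assigns every pathway-classified metabolite the label
of its sub-pathway after applying the curated merge map shipped as
package data (diacylglycerol + monoacylglycerol, ceramides +
sphingolipids, plasmalogen + lysoplasmalogen, urea cycle + arginine +
proline, bile acids, tocopherol/nicotinate → cofactors and vitamins,
…). Unknown or unclassified metabolites inherit the best-correlated
biology label among the classified members of their MMC community,
**provided** their mean |r| with that label's members reaches
`min_inherit_r` (default 0.3): community co-membership alone is too weak
a notion of "clustering well", because a modularity partition assigns
every node somewhere, and uncorrelated screening false positives (an
expected consequence of FDR 0.2) would otherwise infiltrate clusters
and dilute the replication concordance denominator. Metabolites failing
the rule are excluded as `unknown-nonclustering` /
`unclassified-nonclustering`; clusters below `min_size` (default 2)
dissolve as `small-orphan`. The refinement is idempotent.

## Cluster tests and replication

PC1 of the z-scored, imputed members (SVD; sign fixed so loadings sum
positive, making results invariant to member order and sign flips);
% variance = first eigenvalue over the trace. The PC1 regression uses
the same covariate-adjusted model as the screen; Bonferroni at α/K with
the display threshold floored to two significant digits (0.05/24 →
0.002, 0.05/13 → 0.0038). Distribution diagnostics: adjusted
Fisher–Pearson skewness G1 (flag |G1| > 1), Sarle's bimodality
coefficient b = (G1² + 1)/(kurt + 3(n−1)²/((n−2)(n−3))) with flag
b > 0.555 (the uniform-distribution benchmark — a deterministic stand-in
for histogram inspection), Shapiro–Wilk p reported as diagnostic only.
Flagged clusters still proceed; replicated flagged clusters get a
Mann–Whitney sensitivity test (exact enumeration when the smaller group
has ≤ 8 observations without ties, else tie-corrected normal
approximation with continuity correction).

Replication recomputes PC1 within the second cohort with its own
loadings, tests at α/K₂ over the clusters actually testable there, and
requires direction concordance ≥ 9/10 computed with exact rationals over
the metabolites assayed and fitted in both cohorts, directions taken
from each cohort's own screen coefficients. Clusters with no available
member are reported untestable; losing more than half the members
triggers a warning. Dose-response regresses each replicated-cluster
metabolite on continuous q (plus covariates) within the q ≥ 0.45 subset,
where q is approximately normal; the per-cluster tally of positive
slopes is reported.

## Synthetic-data generator

Defaults encode the study conditions of a two-trial US hypertensive
setting:

* 84 AIMs, true |p_A − p_E| ≥ 0.30, frequencies uniform on [0.01, 0.99];
  90 reference individuals per ancestral population (binomial genotypes,
  Hardy–Weinberg within panels); no linkage.
* Cohorts of 633 (discovery) and 411 (replication); ancestry mixture
  60.5% Beta(1.3, 60) (median 1.6%, IQR 0.8–2.9%) and 39.5%
  Beta(18, 3.4) (median 85.2%, IQR 79.5–89.9%).
* Covariates: age N(50, 9.5²), 50% female, 3 sites, 4 batches assigned
  independently of ancestry; baseline PRA log-normal with group medians
  0.9 / 0.4 ng/mL/h and σ = 0.81 (matching the interquartile ratio).
* 1223 metabolites: 15.6% xenobiotic, 20.6% chemically unidentified,
  3% known-unclassified, 11.9% with heavy missingness (rate uniform on
  [0.65, 0.95]); baseline log-abundance N(15, 2²), per-batch shifts
  N(0, 0.1²), residual SD 0.6.
* Twelve planted correlation clusters driven by latent factors with
  loading magnitude 1.0 (within-cluster |r| ≈ 0.74 — the within-cluster
  correlation strength of real metabolic modules is a free parameter;
  this value gives clusters that modularity clustering can recover
  without being trivial). The first four clusters, sized 15, 14, 22 and
  12, are differential: the latent factor shifts by 0.8 (log scale) in
  the high-GWAA group, members carry signed loadings (sign splits 15+,
  7+/7−, 16+/6−, 12+), and 1, 1, 2 and 0 members flip sign between
  cohorts — reproducing direction-concordance patterns of 14/15, 13/14,
  20/22 and 12/12. The 0.8 effect is calibrated so that replication
  cluster p-values land in the `< 0.0001` regime and the screen captures
  essentially whole clusters, the regime the study design presumes;
  each differential cluster also contains two unidentified metabolites
  that must be rescued by correlation clustering.
* Missingness for ordinary metabolites (rate 0.15) is 70% left-censoring
  below the per-metabolite detection quantile + 30% uniform dropout —
  low-abundance dropout dominates in untargeted LC-MS and stresses the
  non-imputed regression path. 15% of non-differential metabolites are
  absent from the replication assay (emulating panel drift between
  platforms).

What the generator does **not** emulate: LC-MS peak shapes, retention
times or m/z; linkage disequilibrium or local-ancestry tracts;
run-day normalization (assumed already applied); heavy-tailed abundance
noise; covariate–metabolome confounding beyond the planted ancestry and
batch effects. Passing end-to-end tests therefore demonstrate that the
pipeline recovers planted multivariate structure under realistic sample
sizes, missingness and annotation mixes — not that real plasma
metabolomes behave this way.

The group effect is a step at the 45% cutoff, not a slope in q, so the
within-subset dose-response is genuinely null under the generator — the
dose-response stage is validated separately with planted continuous
slopes.

## Problem sizes and determinism

Every stochastic operation takes an explicit `numpy.random.Generator`;
identical seeds give bit-identical studies, and the analysis layer is
fully deterministic (no RNG anywhere downstream of the generator). The
test suite runs the full default-scale study across 20 seeds for the
recovery check and 20 seeds for the null-configuration check; unit and
oracle tests use reduced sizes (tens to hundreds of samples, ≤ 10
markers for grid-search comparisons, n ≤ 8 for exhaustive partition
enumeration) chosen so each oracle remains exactly computable.

## Known limitations

* The supervised estimator ignores reference-panel sampling error; with
  90 individuals per panel this adds ~0.01–0.02 to the ancestry RMSE.
* Estimated GWAA medians in the low group run slightly above the true
  median (≈2.5–3% vs 1.6%) because estimation noise cannot push
  estimates below 0 — a boundary bias any point estimator shares.
* The Bland–Altman flag is weakly informative on Gaussian data (see
  above).
* Greedy modularity above the exhaustive cap is a heuristic; planted
  well-separated blocks are recovered reliably in tests, but global
  optimality is guaranteed only for n ≤ 8.
* `K₂` counts all clusters carried into replication, including small
  noise clusters formed from screening false positives; this slightly
  tightens the replication threshold relative to a planted-only family.
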