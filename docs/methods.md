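# Methods

## Trait model and scales

All variance-based statistics (T-statistics, nested variance components)
operate on the natural log of LMA, which removes the mean–variance
scaling typical of size-like traits.  Descriptive quantities that
ecologists read in trait units — CWM, CWV, the turnover decomposition of
CWM variance — stay on the raw g·m⁻² scale.  The two scales are never
mixed within one statistic.

## Ingest rules

* **Whole-leaf LMA.**  (lamina + petiole dry mass) / (lamina + petiole
  fresh area) per leaf; the rachis of compound leaves is treated as
  petiole.  A zero total area is an error naming the leaf.
* **Petiole correction.**  Balances with limited precision record zero
  petiole dry masses.  Each plot's fresh:dry petiole mass ratio is
  estimated as a ratio of sums over records with both masses positive —
  robust to tiny masses, unlike a mean of per-leaf ratios — and zero dry
  masses are replaced by `fresh / R_plot`.  Plots with no valid pair keep
  their zeros and the records are flagged.
* **Outlier filter.**  A branch whose leaf-LMA sample variance exceeds
  2000 g²·m⁻⁴ loses the single leaf whose removal minimizes the remaining
  variance; never more than one leaf per branch, and branches still above
  threshold afterwards are flagged rather than truncated further.  The
  rule is deliberately algorithmic (greedy single-leaf removal) so it is
  reproducible and testable.
* **Aggregation order.**  Leaves → tree means → population (species ×
  plot) and plot means, always from tree values; in unbalanced designs a
  plot mean of tree means differs from a pooled leaf mean, and only the
  former is used.  Sun and shade branches are separate records end to end.

## T-statistics and null models

`T_ip.ic` is computed as the within-population sum of squares divided by
the community sum of squares, a bounded [0, 1] fraction (the shared
`n_c − 1` denominator cancels).  `T_ic.ir` uses ddof-1 variances of
individual values; `T_pc.pr` ddof-1 variances of unweighted population
means.  Populations are species × plot cells, never pooled across plots;
the regional pool is every plot of the analyzed transect.

Each statistic gets the permutation scheme that destroys exactly the
structure it measures: values shuffled among individuals within each
community (T_ip.ic); communities rebuilt by sampling n_c individuals
without replacement from the regional pool (T_ic.ir); population means
shuffled across all populations with community sizes preserved
(T_pc.pr).  Observed and null values use the identical estimator, so SES
is invariant to the estimator's normalization.  Significance: the SES
lies outside the central 1 − α quantile box of the SES-transformed null
values (α = 0.05 default, nperm = 999 default, 99 minimum).  Transect
aggregation compares the mean observed SES to the null distribution of
the permutation-wise mean SES across plots.  Ties permute as ordinary
values.  All permutation seeds derive from one master seed through
`numpy.random.SeedSequence` spawning.

## Nested variance components

The intercept-only nested random-effects model is fitted by REML with
statsmodels' MixedLM: the outermost level (plot) is the grouping factor
with a random intercept, inner levels (family / genus / species / tree)
enter as variance components on ancestor-concatenated labels, and the
leaf is the residual.  Labels below the top level must nest (one genus
under two families is an error listing offenders); the top level may
cross the second, since the same family legitimately occurs at many
plots.  Optimization runs two chains (lbfgs and bfgs), each polished by
a tight-tolerance bfgs step accepted only when the restricted likelihood
does not decrease, and keeps the best finite-likelihood solution — a
single lbfgs run can stall at a spurious boundary point on small
designs, and unpolished fits only reach ~1e-4 relative accuracy.
Variances are truncated at zero by the parameterization and proportions
renormalized.  An independent expected-mean-squares (method-of-moments)
solver for perfectly balanced designs serves as the closed-form oracle;
REML matches it to better than 1e-6 relative tolerance on balanced
fixtures.

The turnover decomposition computes, per plot, a specific CWM
(plot-specific species means) and a fixed CWM (region-wide species
means) under the same normalized basal-area weights; the across-plot
ddof-1 variances of fixed, (specific − fixed), and the residual
covariance term reconstruct the specific-CWM variance exactly by
construction.  The covariance is reported signed.

## Beta diversity

Incidence-based Sorensen dissimilarity, `(b + c) / (2a + b + c)` with
presence defined as positive basal area (computed via scipy's `dice`
distance, which is the identical formula).  The Mantel test correlates
lower-triangle entries (Pearson) and permutes one matrix's row/column
order jointly; the one-sided p-value is
`(1 + #{r_perm ≥ r_obs}) / (nperm + 1)` with 999 permutations by default.

## The synthetic gradient generator

The generator emulates the sampling design the ingest stage expects:
dominant species sampled to 80% of plot basal area, 3–5 trees per
species, 3–5 leaves per branch, sun and (optionally) shade branches.
The trait model is Gaussian on log LMA with nested effects — site,
species, population (species × plot), tree, leaf — whose default
standard deviations (0.05, 0.25, 0.10, 0.10, 0.10) make species turnover
the dominant variance source, matching the structure of tropical
gradient datasets.  Species niche optima are uniform over the gradient
(with a one-niche-width margin so edge plots are not species-poor);
membership weight combines a Gaussian niche kernel (default width 400 m
on a 200–3600 m gradient, i.e., strong turnover), a species-level
lognormal abundance (sd 1.0) shared across plots so abundance ranks are
correlated as in real communities, and plot-level lognormal noise
(sd 0.3).  A species is "present" in the census when its relative weight
exceeds 1e-6.  The species trait optimum slope along the gradient
(2.8e-4 log-LMA per m) reproduces a roughly twofold CWM increase over
3400 m, and niche positions are centered on the gradient midpoint so the
configured grand mean (ln 120 g·m⁻²) is the pool's actual grand mean.

Filters are generative knobs, not estimates of any field system:
`gamma_internal` scales σ_pop and σ_tree (shrinking within-population
spread, the quantity T_ip.ic measures), and `gamma_external` shrinks
admitted species means toward the plot trait optimum (reducing community
variance relative to the region, the quantity T_ic.ir measures) — the
simplest mechanisms that act on exactly one statistic each.  Leaf
records carry a mass/area split consistent with the latent LMA: the
petiole holds 5% of fresh area and 8% of dry mass with a fresh:dry mass
ratio of 3.0 — arbitrary but recorded, so the petiole correction is
exactly invertible and testable.  `inject_artifacts` plants zeroed
petioles and single-leaf outliers with a manifest for ingest-filter
tests.

What the generator does *not* emulate: spatial structure within plots,
temporal dynamics, phylogenetic signal beyond nested taxonomy labels
(genus/family labels are deterministic groupings of species with no
variance of their own), measurement error other than the planted
artifacts, and folded-leaf image exclusions.  Passing tests therefore
demonstrate correctness of the statistical machinery under a known
hierarchical model, not robustness to every pathology of field data.

## Validation design and problem sizes

* Oracle identities: T_ip.ic equals the one-way-ANOVA complement
  `1 − SS_between/SS_total` to 1e-12 on every community; the Leps
  identity holds to machine precision on arbitrary inputs.
* Null calibration: under random assembly (the structure a scheme
  permutes removed from the generator), the per-plot rejection rate at
  α = 0.05 is checked against the 99% binomial band over 200 replicate
  four-plot datasets at nperm = 199; the band is computed at the dataset
  count because plots within a dataset share a regional pool and are
  positively correlated.
* Filter recovery: γ_internal = 0.3 must flag ≥ 90% of 100 replicate
  plots with significantly negative SES(T_ip.ic), γ_external = 0.3 ≥ 80%
  for SES(T_ic.ir).
* Generator recovery: with 20 plots × 5 trees × 5 leaves and narrow
  niches (species unique to plots, so the species level carries
  σ²_species + σ²_pop), REML components match the configured variances
  within three analytic standard errors.

Replicate counts and community sizes were chosen so each check has the
statistical resolution its tolerance needs; they are the package's
standing validation conditions, rerun identically by
`scripts/acceptance.py`.

## Known limitations

* REML components come without confidence intervals, and the mixed model
  has no fixed-effect covariates.
* T-statistics are single-trait and unweighted by abundance.
* The Mantel test is the plain one-sided variant (no partial Mantel);
  beta diversity is not partitioned into turnover/nestedness.
* The "significant" flag compares one SES against quantiles of a finite
  null (nperm-limited resolution: with 199 permutations the attainable
  two-sided level near 0.05 is approximate).
* With very small communities (a handful of populations) T_pc.pr rests
  on few population means and its null box is wide; results for such
  plots should be read qualitatively.
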