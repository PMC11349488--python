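# Methods notes

This note records the models behind each stage, the defaults that matter,
and the choices made where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Synthetic data: what it emulates, and what it does not

The generators define the study conditions under which the pipeline is
exercised.

**Scenes.** A scene is a mosaic of spatially coherent patches drawn from a
small set of *class archetypes*. The latent class field is the argmax over
one Gaussian random field per archetype, each smoothed with a Gaussian
kernel of width `patch_scale` (default 100 m at 10 m pixels): a simple,
controllable way to get patches much larger than a pixel without a
radiative-transfer or phenology model. The five default archetypes span a
post-mining successional gradient — dark coal-rich substrate, bright
mineral substrate, sparse pioneer vegetation, dense low herbaceous
vegetation, tall woody vegetation — with surface-reflectance band means in
[0, 1], i.i.d. Gaussian band noise (default SD 0.01, well below the
between-archetype mean separation), vegetation height drawn per pixel from
a truncated normal per archetype, and an optional per-date cloud mask
(nodata) exercising the multi-date averaging path. What passing tests on
these scenes do **not** show: robustness to mixed pixels, atmospheric
artefacts, phenology-driven date differences, or class spectra that drift
in space.

**Phylogenies and traits.** Trees are pure-birth (Yule) with all tips
extended to the present (ultrametric), labelled `sp001…`. Continuous traits
evolve by Brownian motion (root value 0, increment variance
`bm_sigma2 × branch length`, default rate 1); categorical traits threshold
an independent latent Brownian trait at equal quantiles. Missingness is
completely at random (default 15%, a realistic completeness level for
compiled trait databases). Real trait data are neither Brownian nor MCAR —
trait gaps correlate with rarity — so imputation performance here bounds
the idealized, not the field, case.

**Communities.** Plots sit in blocks of 5, blocks in heap × cluster cells.
Each cluster has planted *exclusive indicator species* occurring with
probability `p_inside` (default 0.6) in their cluster and `p_outside`
(default 0) elsewhere; background species occur at a per-cluster rate set
so expected plot richness matches `cluster_richness_means`. The default
means (8, 9, 5, 9, 14) are arch-shaped: richness peaks in mid-succession
and dips in the shaded late-successional cluster — the classic
successional-diversity pattern the analysis stack should resolve. Cover
values are Beta(1, 3) on (0, 1], mimicking many low covers; ordinal
cover-scale recording (e.g. Londo) is deliberately not emulated because
every downstream statistic consumes numeric abundance. Covers are
independent across species, so no abundance compensation or dominance
structure is present.

## Spectral features

Indices are computed **per date and then averaged** over dates; averaging
bands first would differ for every nonlinear index, and the per-date-first
order matches computing indices for each acquisition. The EVI denominator
constant is +1 (the canonical form); the −1 variant that circulates in some
index compilations is available behind `evi_minus_one` but can blow up the
denominator at moderate reflectances. VH is clipped at 0: negative
DSM − DEM values are sensor/registration artefacts, not heights. Inputs
may be unit-scale or integer ×10⁴ reflectance (`reflectance_scale`,
default auto-detect). Zero denominators mask the pixel rather than raise.

## Clustering and the elbow rule

All 13 features are standardized before both k-means and PCA — VH is in
meters and would otherwise dominate Euclidean distances. k-means uses
k-means++ with `n_init = 10` restarts and a surfaced seed; cluster labels
are arbitrary and every downstream statistic is label-permutation
invariant (tested).

The elbow criterion ("stop when the next cluster no longer buys a
meaningful WSS decrease") is operationalized as the k maximizing the
**second difference of log WSS** — the relative drop into k minus the
relative drop out of k. The log scale matters: before the true elbow the
WSS of well-separated clusters decays roughly geometrically, so raw second
differences always peak at the smallest k, while relative curvature peaks
at the planted cluster count (verified on planted-mass data and on
five-archetype scenes). The alternative `relative_drop` rule selects the
smallest k whose WSS decrease, as a share of the starting WSS, falls below
10%; normalizing by the first WSS rather than the current one keeps this
rule scale-free (after the elbow, splitting one of k noise clusters always
removes ≈ 1/(2k) of the remaining WSS however tight the clusters are).
Near-linear curves are flagged low-confidence. For large rasters the k
sweep runs on a seeded subsample (default in the CLI: 20,000 pixels); the
curve shape is stable under subsampling.

## Site selection

"Variance of class number" is computed literally as the population variance
of the integer class labels of the pixels whose centers fall strictly
inside the circle. This is label-ordering dependent — relabelling clusters
changes the statistic (not the 0-variance case) — and is kept because it is
the field workflow's own definition; a label-agnostic impurity
(1 − majority share) is available via `statistic="impurity"`. Population
(not sample) variance is fixed so the 0.2 threshold is unambiguous; with
~113 pixels in a 60 m circle the difference is negligible. Patch area
filtering is strictly greater-than 14,400 m². The candidate grid is
anchored at the raster origin (inclusive of both edges); candidates are
optionally restricted to retained patches (`patch_grid` argument) since the
workflow leaves open whether a circle must also lie in a large patch.
Block quotas use largest-remainder rounding with fractional ties broken
toward the lower class label. The manual aerial-imagery screening step of a
real campaign is replaced by nothing — an exclusion-polygon layer can be
applied upstream by masking the raster.

## Trait imputation

Phylogenetic eigenvectors are the PCoA of the patristic distance matrix
(Gower centering of −D²/2), each retained axis scaled by √eigenvalue;
retention is by count (`n_keep`) or by cumulative share of the positive
eigenvalue mass. The imputer is the iterative chained-forest scheme:
initialize missing numerics at column means and categoricals at modes,
visit traits in increasing-missingness order, fit a random forest of each
trait on all other columns (categoricals one-hot-encoded) plus the
eigenvectors, re-predict the missing cells, and stop when the normalized
change in imputed values first increases, returning the previous iterate.
Forests: 100 trees, `mtry = √p`, minimum leaf size 5 for regression (the
classical regression-forest default; it also keeps out-of-bag error honest
on signal-free traits) and 1 for classification. Error reporting follows
the missForest conventions — NRMSE = √(OOB MSE / trait variance) pooled
over continuous traits (can exceed 1 when a trait carries no signal), PFC =
OOB misclassification share — so the numbers are comparable with published
imputation reports. Observed cells are never altered; everything is seeded.

## Diversity metrics

Faith's PD is the branch-length sum of the minimal *unrooted* spanning
subtree (an edge counts iff its subtree holds between 1 and S−1 of the S
community members); `include_root=True` adds the root path, since both
conventions circulate. MPD is presence-based (unweighted over unordered
pairs), undefined below two species. The functional space is the PCoA of
Gower dissimilarity (numeric: range-normalized absolute difference;
categorical: 0/1 mismatch; equal weights; zero-range traits dropped) with
at most 4 retained axes — convex hulls in higher dimension need more
points than most plots have species. FRic reduces the axes to richness−1
(minimum 1, where it degenerates to a coordinate range) for species-poor
plots and is reported as raw hull volume (no standardization by the global
hull). FDis is the abundance-weighted mean distance to the
abundance-weighted centroid. CWMs renormalize weights over the species
with trait data. Shannon uses natural logs.

The null model is the richness-preserving uniform draw from the species
pool — the analytic null of the phylogenetic-diversity literature — with
SES = (obs − null mean)/null SD and a two-sided Monte Carlo p
(2·min(r+1, n−r+1)/(n+1), default n = 999). Monte Carlo was chosen over
analytic moments for uniformity across metrics; the two agree in
expectation.

## IndVal and NMDS

IndVal is group-equalized: specificity uses per-group *mean* abundances so
group sizes do not bias A. Abundance mode is the default (presence mode is
an option); for a species confined to a single group the two coincide
(A = 1 in both), which is why cluster-exclusive worked examples are exact:
IndVal = √(occupied/group size). Combination search runs up to order K−1.
Permutation p-values use the add-one estimator (r+1)/(n+1) on seeded
permutations of the plot-to-group assignment; small designs can instead
enumerate every distinct relabeling (`exhaustive=True`), which the tests
check against independent enumeration.

NMDS embeds Bray–Curtis dissimilarities of presence/absence data (equal to
Sørensen) in 2-D by alternating the Guttman majorization update with
monotone (pool-adjacent-violators) regression of distances on
dissimilarity ranks, minimizing Kruskal stress-1; best of `n_starts`
random starts, final configuration centered and rotated to principal axes.
Empty and single-species plots are excluded first with a logged reason —
they produce degenerate dissimilarities.

## Mixed models

The Gaussian LMM has fixed cluster effects and independent random
intercepts for heap and block-in-heap. Estimation profiles the REML
deviance over the two variance *ratios* (heap and block variance over
residual), with GLS fixed effects and the residual variance in closed form
at each ratio pair; the two-dimensional optimization (Nelder–Mead on the
log scale, three starts) is handled through the Woodbury identity in the
random-effects space, so each evaluation is O(q³) rather than O(n³).
Ratios below 1e−7 snap to exactly zero (boundary fits are legitimate).

Satterthwaite denominator degrees of freedom are computed analytically:
the variance-component covariance is the inverse *expected* REML
information ½·tr(P Gᵢ P Gⱼ) (P the REML projection matrix, Gᵢ the
per-component covariance derivatives, all traces via low-rank Frobenius
identities), and each contrast's df is 2f²/(gᵀWg) with f the contrast
variance and g its analytic gradient in the components. Components
estimated at zero are excluded from θ, which makes the degenerate
(no-random-variance, balanced) case collapse *exactly* to the classical
one-way ANOVA: F, p, denominator df N−k, and pairwise t statistics (all
tested at 1e−6). Multi-df F tests combine the per-eigencontrast dfs as in
the standard Satterthwaite F construction. Kenward–Roger was not
implemented; Satterthwaite matches the reporting convention of the tables
this pipeline produces.

Tukey comparisons adjust single-step: p̃ᵢ = P(maxⱼ |Tⱼ| ≥ |tᵢ|) under the
joint multivariate t of the contrasts (their estimated correlation matrix;
shared χ scale at the contrasts' mean Satterthwaite df; normal for the
Poisson family), evaluated by seeded Monte Carlo (default 10⁵ draws, so
adjusted p's carry ~0.002 Monte Carlo noise; adjusted p is floored at the
raw p, making the single-contrast case exact). Compact letters use
insert-and-absorb at α = 0.05. AIC comparisons refit full and
intercept-only models by ML (REML likelihoods are not comparable across
fixed structures); the parameter count is fixed effects + 2 variance
components + residual. R²m/R²c follow the variance-partition definitions:
R²m = var(fixed fitted)/(var(fixed fitted) + σ²ₕ + σ²_b + σ²ₑ), R²c adds
the random components to the numerator.

The Poisson GLMM (log link) maximizes the Laplace-approximate marginal
likelihood: inner damped Newton on the joint (β, u) penalized likelihood,
outer Nelder–Mead over the two log random-effect SDs (floored at e⁻⁶;
a fitted SD below 3e−3 is reported as a zero component). Fixed-effect
covariance comes from the joint-Hessian block. The cluster test is Wald
χ²; the table mirrors the Gaussian layout with the statistic as "sum of
squares", χ²/df in the F column, and denominator-df/residual-SD fields NA.
R² uses the lognormal observation-variance approximation ln(1 + 1/λ̄) with
λ̄ the mean observed count. A Pearson χ²/df dispersion statistic is
provided in place of residual-simulation diagnostics (out of scope).
Validation note: the fit agrees with the reference Laplace implementation
to ~10⁻² in the fixed effects and ~10⁻⁴ in the random-effect SDs on the
frozen test fixture; the residual discrepancy comes from profiling β inside
the joint mode rather than inside the Laplace objective.

## Numerical conventions and degenerate inputs

Masked raster pixels are NaN throughout; a pixel missing any feature is
excluded from clustering and classification. Classification ties break to
the lowest label, as do majority-label ties in circles and fractional ties
in quota rounding. Plots with fewer than two species have MPD and FRic
undefined (NaN with the richness recorded); an empty plot has richness 0
and Shannon 0. `sd_null = 0` in the null model flags SES as undefined
rather than dividing by zero. All generators and all stochastic analyses
(k-means, permutations, null draws, Monte Carlo Tukey, forests) are pure
functions of their seed.

## Problem sizes in the test suite

The suite exercises the stages at sizes chosen to make the statistical
checks sharp but quick: 200×200 px scenes over 20 seeds for cluster-count
recovery, 64 species × 6 Brownian traits × 20 seeds for imputation-vs-mean
comparison, 500 simulated null datasets (6 heaps × 5 clusters × 4 plots)
for the F-test size check, and the exhaustive 2⁶-subset oracle fixture for
the diversity metrics. Monte Carlo tolerances in the tests follow from
these sizes (e.g. binomial error on a 500-replicate rejection rate).

## Known limitations

- The Poisson GLMM is Laplace-only (no adaptive quadrature); with very few
  observations per block, variance components are weakly identified.
- NMDS stress-1 is compared across restarts but no Procrustes similarity
  across starts is reported.
- The homogeneity statistic inherits the label-ordering dependence of the
  variance-of-labels definition (see above); use `impurity` when labels
  are not meaningfully ordered.
- Scene synthesis draws band noise i.i.d. across bands and dates; real
  sensor noise is correlated and heteroscedastic.
- FRic of plots whose richness exceeds the retained axes but whose points
  are (near-)degenerate falls back through lower-dimensional hulls, which
  is a convention, not an estimate of the true hypervolume.
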