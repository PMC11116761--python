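# Methods

`sociodep` implements a photo-identification pipeline for a small,
individually catalogued population of killer whales interacting with a
demersal longline fishery: it delineates social units from association
data and quantifies how unevenly those units exploit depredation
opportunities (feeding on hooked fish during hauls), in space and in
frequency.

## Data model and restriction filters

A *sighting* is the observation unit: from shore, a chain of photographs
in one bay with consecutive gaps under 1 h; from a vessel, all
photographs taken during one longline-set haul (one sighting per
vessel × set).  The photographic effort of a sighting is its photo
count, banded as very_low (<25), low (25–49), medium (50–124), high
(125–249), very_high (≥250).  Timestamps are stored in UTC and a "day"
is the UTC calendar date throughout; the representative location of a
multi-photo sighting is the mean of its photo coordinates.

Association analyses restrict the data to individuals photographed in at
least 6 distinct years with a last year after 2019, and to sightings with
at least 42 photographs — enough effort to assume every individual
present was photographed.  `suggest_photo_threshold` reports the
ceiling of 3 × the mean number of individuals identified per sighting,
and the median photo count as a cross-check, but the operative threshold
is configuration, defaulting to 42.  Filters are applied in the order
photo-threshold → individual tenure (recomputed on the retained
sightings) → drop emptied sightings, which makes `restrict_dataset`
idempotent.

## Association indices and null models

Associations use the Simple Ratio Index under the gambit of the group:
SRI = x / (x + y_i + y_j + y_AB).  Two sampling periods are supported.
At the *sighting* period, co-membership of a sighting defines
association and y_AB = 0.  At the *day* period, a dyad is associated on
a date iff it shared at least one sighting that date; both sighted on
the same date in different sightings counts in y_AB.  The day period is
what the permutation null randomises, because the test's constrained
swaps are restricted to groups recorded on the same day — at that
granularity day-presence margins are invariant while shared-group
structure is not.

The preferred/avoided-association test is a data-stream permutation: a
sequential chain of 2×2 checkerboard swaps on the group × individual
incidence matrix, each swap exchanging two individuals between two
groups of the same day, preserving group sizes and individual sighting
frequencies exactly.  The chain starts at the observed data with no
burn-in discard; each recorded permutation applies 10 attempted swaps
(failed attempts count), and the statistic — CV of SRI, SD of SRI, or SD
of nonzero SRI, computed with population (n) denominators over all
dyads (nonzero dyads for the last) — is recorded after each block.  The
p-value is the proportion of recorded values at or above the observed
statistic (one-sided high: preference inflates association spread); a
two-sided mode doubles the smaller tail.  When no day holds two groups
the data are untestable and a degenerate result (p = 1, flagged) is
returned with a warning.  Calibration of this design is checked by
simulation: on data with independent random group membership the
rejection rate at α = 0.05 sits inside [3%, 7%] over 500 replicate
datasets.

The platform comparison (vessel vs shore association matrices) is a
Mantel test: Spearman rank correlation over off-diagonal dyads of the
common individuals, with a null built by simultaneously permuting rows
and columns of one matrix; the p-value is one-sided for positive
correlation with the add-one rule (k+1)/(n+1).

Social differentiation fits a two-parameter beta distribution of true
dyadic association indices by maximising the beta-binomial marginal
likelihood of the observed (x, d) pairs (L-BFGS-B on log a, log b; the
no-true-variation limit a, b → ∞ is handled as a boundary solution and
flagged as degenerate).  S is the CV of the fitted beta,
√(b / (a(a+b+1))).  The estimation power r is the Pearson correlation
between simulated true indices (beta draws) and their binomial
re-estimates at the observed denominators — a posterior-simulation
definition, since r has no closed form here.  Standard errors come from
a nonparametric bootstrap over dyads (200 resamples by default).  H is a
configurable association-count measure — mean dyadic denominator by
default, mean associations per individual as the alternative — and
S²·H indexes the power of the permutation test.  Parameter recovery is
verified on planted Beta(2, 2) truth (CV ≈ 0.447, 500 dyads, d = 100),
recovered within 10%.

## Social units

Units are communities of the weighted SRI graph (every dyad with
SRI > 0 is an edge; no thresholding) found by Leiden optimisation of the
Constant Potts Model, Q = Σ_c [w_c − γ·n_c(n_c−1)/2].  The 20,000
"iterations" budget is treated as a cap: the optimiser runs to
convergence, which these ~80-node networks reach far sooner.  Each
resolution is run with 20 random restarts; the best-quality partition is
kept and stability is the mean pairwise adjusted Rand index across
restarts.  `detect_units` reports a quality value that tests recompute
independently from the partition.  The resolution γ* is chosen by
scanning a grid and taking the midpoint of the widest contiguous plateau
of constant unit count with stability ≥ 0.95 (the published analyses'
stability criterion is qualitative; the plateau rule is this package's
operationalisation, and the fallback when no plateau exists is the most
stable grid point, flagged).  Unit labels are canonical — the smallest
member id, or the two smallest joined by "/" in catalogue style.

Per-unit summaries assume that when at least one member is photographed
during a vessel sighting the whole unit was present: counts of
depredation sightings, distinct years, and the percentage of all vessel
sightings follow from that rule.

## Spatial range

Areas are computed after projecting lon/lat with a spherical Lambert
azimuthal equal-area projection (mean Earth radius 6371.0088 km) centred
on the pooled-data centroid; the projection is exactly area-preserving
on the sphere and its inverse is closed-form (round-trip error < 1e-6°,
1°×1° graticule-cell area within 0.5% of spherical geometry).  Three
range metrics per unit:

* **MCP** — convex-hull area in km² (0 for degenerate hulls), and as a
  percentage of the pooled "fishing area" MCP over all units' sightings.
* **Grid cells** — occupancy of the 0.1° lon/lat graticule
  (floor-convention cell ids, correct at negative coordinates), as a
  count and a percentage of pooled occupied cells.  Grid metrics stay in
  degrees because the grid itself is a graticule.
* **Kernel UD** — isotropic bivariate Gaussian KDE on projected
  coordinates with the ad-hoc reference bandwidth
  h = σ·n^(−1/6), σ² the mean of the coordinate variances; isopleth
  areas (UD50, UD95) accumulate raster cells in decreasing density order
  until the stated mass is enclosed.  The default raster is 200² over
  the data box extended by 3 bandwidths; halving the cell size moves
  areas by < 2%, and on large circular-normal samples the UD95/UD50 area
  ratio approaches the χ²₂ quantile ratio ln 0.05 / ln 0.5 ≈ 4.32.
  Fewer than 5 points, or identical points, raise rather than return
  unreliable areas.

Annual percentage series use *per-year* pooled denominators (an annual
mean of the share of that year's fishing area); cumulative expansion
curves, indexed by years since each unit's first sighting, use the
whole-period denominator, so they are non-decreasing and terminate at
the unit's overall percentage.  Rank correlations between years sighted
and each range metric use Spearman's rho with average ranks; zero
variance is flagged rather than propagated as NaN.

## Occurrence model

Vessel sightings are thinned by the 12-h rule: scanning each vessel's
sightings in time order, a sighting is dropped only when *every* unit
photographed in it was already photographed around that vessel within
the preceding 12 h; the window anchors at each unit's first sighting and
re-anchors once exceeded.  Exclusion is decided at the sighting level
because each retained sighting then yields exactly one record per unit
(present/absent), keeping the record count a multiple of the unit count.

The GLMM is binomial-logit with categorical fixed terms (year, month,
unit; treatment contrasts, first level reference) and independent
categorical random intercepts.  Fitting maximises the
Laplace-approximated marginal likelihood: penalised IRLS finds the joint
(β, u) mode for a given variance configuration (damped Newton, dense
solves up to ~400 coefficients, sparse Cholesky via LU beyond), and the
profiled objective is optimised over log σ² — Brent for one variance
term, Nelder–Mead with a coarse simplex for several (those profiles are
flat near the optimum; the tolerance resolves the log-likelihood to well
under 0.01).  With a single grouping factor the reported log-likelihood
is re-evaluated by adaptive Gauss–Hermite quadrature (15 nodes, group
modes by scalar Newton), which matches dense numerical integration to
better than 1e-3; pinning σ² → 0 reproduces a plain logistic fit to
1e-4.  β covariance is the fixed-effects block of the inverse joint
Hessian.  K counts intercept + (levels − 1) per fixed factor + variance
terms; AICc uses n = number of records.  R²m and R²c are
latent-scale Nakagawa–Schielzeth values with logit residual variance
π²/3.

Model selection is the forward ladder (null, +year, +month, +unit, each
with the effort random intercept), reporting K, LL, AICc, Akaike
weights, and the likelihood-ratio X² = 2·ΔLL with its df against the
previous model; the pseudoreplication check refits the full model with
`(1|sighting) + (1|sighting:unit)` (two extra variance terms).

Diagnostics follow the simulated-residual protocol: 1000 response
vectors are drawn from the fitted model (random effects re-drawn), and
each record's scaled residual is its rank position within its simulated
distribution, ties broken uniformly with the run seed.  Reported checks:
KS uniformity, an outlier binomial test on the extreme ranks, the
dispersion ratio (observed Pearson-residual variance over the simulated
mean, empirical two-sided p), the zero-inflation ratio (observed zeros
over simulated mean), Durbin–Watson on time-ordered residuals (normal
approximation for its p), and generalised VIFs from determinant ratios
of the fixed-design correlation matrix.

Marginal unit probabilities average the linear predictor on the link
scale over a balanced (equal-weight) year × month reference grid with
random effects at zero, then back-transform; CIs are delta-method on the
link scale.  All pairwise unit contrasts are z-tests on log-odds
differences with Holm step-down adjustment.  With few random-effect
levels (five effort bands) the fitted intercept necessarily absorbs the
realised mean of the band intercepts, so these EMMs are conditional
predictions; their frequentist coverage is assessed in the test-suite on
the planted unit log-odds contrasts, which are free of that confounding,
and sits at the nominal 95%.

## Synthetic data

The generator plants: a fixed partition (default 17 units of 1–10
members, 79 individuals); per-unit occurrence probabilities spaced on
the logit scale across 4%–22.5% and shuffled across units; year and
month effects N(0, 0.25²); isotropic bivariate-normal ranges with
centres uniform in an EEZ-like box (45–55°E, 44–48°S) and dispersions
uniform in 40–80 km (chosen so 95% ranges span a large fraction of the
box, as the studied units' do); log-normal photo counts with median 42
and log-SD 1.1 clipped to 1–3299; and saturating detection
1 − exp(−λ·n_photos) with λ = 0.03 per individual (≈0.72 at the median
effort).  Units attend events independently by default; an affinity
matrix can induce correlated co-attendance for power checks of the
permutation test.  Event locations are drawn from a randomly chosen
attending unit's range.  Only events with at least one photographed
individual are emitted, as in real photo-ID data.  A records-level
simulator (`simulate_occurrence_records`) draws occurrence tables
directly from the GLMM for clean parameter-recovery studies.

Because detection is independent across individuals and attendance
independent across units, passing recovery tests demonstrate the
estimators' correctness under the assumed model, not robustness to
misidentification, heterogeneous detection within sightings, or
behavioural vessel-following — all absent from the generator.

## Problem sizes and numerical choices

The test-suite runs the permutation-calibration study on 500 replicate
datasets of 12 individuals × 30 days (400 permutations each), community
recovery on 20 planted 17-block networks, and GLMM coverage on 50
replicates at the study scale (1212 sightings × 17 units); the
acceptance script runs one full end-to-end study at 1475 vessel + 168
shore sightings.  These sizes give binomial/Monte-Carlo error
comfortably inside the asserted tolerances.  Other numerics: PIRLS
converges at relative gradient norm 1e-9 with step halving; variance
components are bounded in log space ([−18, 5]); |β| > 15 raises a
separation warning; beta-binomial parameters are bounded in
log space ([−9, 14]); KDE isopleths interpolate nothing — they count
raster cells, so areas are quantised at the raster resolution.

## Known limitations

* The occurrence model supports independent categorical random
  intercepts only — no crossed correlated structures, alternative links,
  or explicit spatial/temporal autocorrelation (the Durbin–Watson check
  is diagnostic, not corrective).
* Laplace/AGH maximum likelihood, not REML: variance components from few
  grouping levels are noticeably shrunk, a known property shared with
  the standard GLMM tools this mirrors.
* Only the Simple Ratio Index is implemented (half-weight and
  generalised affiliation indices are out of scope), and only
  Gaussian-kernel UDs with the reference bandwidth.
* The Mantel permutation count and the chain length of the association
  test trade precision for time; p-values are granular at 1/n.
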