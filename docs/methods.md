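# Methods

This note documents the models, the synthetic study generator, the
numerical choices, and what the test suite does and does not establish.

## Detection model

For animal *i* at an available camera, the linear predictor is

    η_i = β_Sex,i + β_UD · log(UD_i) [+ covariates] [+ offsets]

with UD_i the utilization density (per m²) at the camera. The capture
rate is λ_i = exp(β_Sex,i)·UD_i^β_UD, so over an exposure of T days the
count response is Poisson with mean λ_i·T (log link) and the binary
response is Pr(detect) = 1 − exp(−λ_i·T), i.e. a complementary log-log
binomial model. The cloglog link is used for binary home-range models
because detection/non-detection is the zero/non-zero split of a spatial
encounter count; the proximity analysis uses the logit link by default
(the binary GLMM convention for that analysis; switchable per
`ModelSpec.link`).

*Offsets.* `offset(log UD)` fixes β_UD = 1 — the *simple model* in which
cameras sample space exactly in proportion to telemetry-measured space
use. By default models also carry `log(exposure_days)` as a second
offset so records with unequal windows are comparable; set
`ModelSpec.exposure_offset=False` for unadjusted fits on roughly equal
windows. The offset-consistency check exploits an exact identity: the
offset model's maximized log-likelihood equals the free-exponent model's
likelihood evaluated at exponent 1 with the remaining coefficients at
the offset fit's values (same linear predictor). The reported gap is a
pure numerical-implementation check and should be ~1e-14.

## Home-range estimation

Fixed-kernel density with an isotropic Gaussian kernel and a single
bandwidth. The reference bandwidth is the bivariate-normal rule
h_ref = sqrt((s_x²+s_y²)/2)·n^(−1/6); because it oversmooths multimodal
ranges, candidate multipliers {0.6, 0.7, 0.8, 0.9} are tried in
ascending order and the first passing two operational criteria wins,
falling back to 1.0:

- *cohesion*: ≤ `max_fragments` (default 3) 4-connected fragments at the
  90th and 95th isopleths;
- *extent*: the 95th isopleth's bounding box overshoots the relocation
  bounding box by ≤ `extent_margin` (default 2) bandwidths per side.

These two thresholds operationalize criteria that are qualitative in
standard practice ("intervals do not break into small polygons",
"isopleths do not extend well beyond the data"); both are exposed as
parameters. Gaussian-tailed data essentially always fragment at
0.6·h_ref (isolated outer fixes form density islands), so selected
multipliers concentrate at 0.7–1.0; compact light-tailed clusters select
0.6.

*Grid.* Cell size defaults to h/4 (a guard rejects cells coarser than
h/2) with a margin of 4 bandwidths around the data — wide enough that
cell-summed mass is within 1e-3 of 1, which the normalization invariant
asserts. Isopleth thresholds come from cumulative cell mass: the p%
threshold is the density of the first cell (descending order) at which
cumulative mass reaches p%, so region mass overshoots p% by at most one
cell (the "1% accuracy" convention at these resolutions). Areas are
cell counts × cell²; fragments use 4-connectivity (conservative).
Point queries interpolate bilinearly; outside the grid the density is 0.
Records are truncated at the 90% isopleth — kernel tails are unreliable
and few relocations fall beyond it — so isopleth percentiles in tables
lie in 1–90 and "outside" cameras are unavailable.

*Seasons.* Fall/Winter = 1 Oct–15 Mar, Summer = 1 Jun–30 Sep, annual =
1 Oct–30 Sep; 16 Mar–31 May (reproductive season) is excluded from
seasonal estimation and from all encounter exposure. Seasonal UDs
require ≥ 25 relocations (annual ≥ 5); both floors configurable.

## Encounter tables

A pair (animal, camera) is *available* when the deployment window
intersects the animal's tracking window outside the excluded season
and — for the home-range analysis — the camera sits inside the 90%
isopleth of the animal's surface for that record's season (grid
membership: density ≥ threshold, consistent with the grid-based isopleth
definition; no polygonization). Proximity-analysis availability is
temporal only, which is why it has more records than the home-range
table built from the same data. Deployments straddling the season
boundary split into per-season records with day-count exposure.
Detection events group images by a ≥ 15-minute gap rule; events outside
available pair-windows are counted and dropped, never silently. NLocs
counts are restricted to the record's season window, keeping covariate
and response contemporaneous (a documented choice; the alternative is
year-cumulative counts). Distances are planar Euclidean on projected
metres. With camera spacing ≥ cell − 2·jitter and radius ≤ half of that,
no relocation can be counted at two cameras;
`SimConfig.check_proximity_spacing` verifies the inequality.

## GLMs, quasi-likelihood, GLMMs

GLMs are fit by iteratively reweighted least squares (statsmodels
backend) with convergence at relative deviance change < 1e-10; the test
suite checks coefficients against independent BFGS maximization of the
same likelihoods to 1e-5. Quasi-binomial/quasi-Poisson fits share the
parent family's point estimates with standard errors scaled by
sqrt(ĉ), ĉ = Pearson χ²/df from the *saturated* fixed-effects model
(`Sex * Isopleth + logUD`), reused for every model in that family; ĉ is
reported as estimated but floored at 1 inside QAICc.

Random-intercept GLMMs (factors: animal, camera, or animal and
animal×camera pair) are fit by Laplace-approximated maximum likelihood:
conditional modes by penalized Fisher scoring, and the variance
parameters (log-SD scale) optimized jointly with the fixed effects on
the Laplace criterion by Nelder–Mead — the same structure lme4 uses at
nAGQ = 1. Because each factor's own block of Z'WZ is diagonal, mode
solves and log-determinants reduce to diagonal operations (one factor)
or a small Schur complement (two factors), keeping observation-level
pair intercepts cheap. An independent adaptive Gauss–Hermite evaluation
(15 nodes) bounds the Laplace error for single-factor fits; agreement
within 0.1 log-units requires in the order of a hundred observations per
group for binary data — with few observations per group the *approximation*
(in any Laplace implementation) is the limiting factor, not this code.
Variance estimates below SD 1e-3 are flagged as boundary fits and
retained. Random-effect selection follows the two-stage protocol: first
compare random structures under saturated fixed effects (by AIC), then
compare fixed effects under the chosen structure.

*Model selection.* AIC = −2ℓ + 2K; AICc adds 2K(K+1)/(n−K−1); QAICc
divides −2ℓ by ĉ and counts ĉ as a parameter (K includes it in both
penalty terms — note the popular shorthand "QAICc = AICc + 2 at ĉ=1"
is only asymptotically exact under this convention). K counts the
intercept, every fixed coefficient and one per random-effect variance.
Akaike weights are exp(−Δ/2) normalized; ties break by smaller K then
label. Conditional R² for mixed fits is
(σ²_fixed + Σσ²_random)/(σ²_fixed + Σσ²_random + σ²_dist) with
σ²_fixed the variance of the fixed-effect predictor (offsets included)
and σ²_dist = π²/3 (logit), π²/6 (cloglog) or ln(1 + 1/λ̄) (Poisson log
link, lognormal approximation with λ̄ the mean fitted count; the
distribution variance convention for the Poisson case is stated here
because more than one circulates). Wald intervals throughout; no profile
likelihood. Mann–Whitney home-range comparisons use the exact null for
groups ≤ 20 and the tie-corrected normal approximation otherwise; the
reported U counts pairs where the first group exceeds the second.

## The synthetic study generator

The generator emulates the study design the analyses assume, not any
particular dataset:

- *Population*: configurable F/M counts (default 20/10). Each animal is
  a stationary 1–3 component Gaussian mixture; after drawing shapes, the
  mixture is rescaled about its centroid so its true 95% isopleth area
  equals the sex target (defaults 2910 ha F, 8915.8 ha M — the ~3×
  dimorphism of the motivating system) times a lognormal individual
  multiplier (SD 0.25). Home ranges are *not* movement paths: the
  analyses consume only marginal space-use frequency, which is what a
  kernel home range measures, so trajectory autocorrelation is out of
  scope — and passing tests therefore say nothing about estimator
  behaviour under strong serial correlation of fixes.
- *Telemetry*: relocation count = rate × window length (default 5/week,
  inside the reported 4–6), dates uniform, positions = mixture draws
  plus isotropic Gaussian error. The error SD (270.4 m) is set so the
  mean radial error is 338.9 m (the aerial-telemetry test-collar value);
  fixes carry dates only (flights at local noon).
- *Cameras*: one per 1×1-km cell at the centre plus uniform jitter
  (default ±200 m, keeping nearest-neighbour spacing ≥ 600 m), ~36-day
  deployments staggered in batches of ≤ 60 across the study year.
- *Detections*: per overlapping pair, count ~ Poisson(λT) with λ from
  the hazard model evaluated at the *true* mixture density — never the
  kernel estimate, so kernel error stays a measurable property of the
  estimator rather than part of the truth. Timestamps uniform in the
  overlap; an optional per-event dropout models unidentifiable photos.
  Default intercepts (β_F = 12.2, β_M = 12.9) give ~10–20% detected
  pairs over 36 days, the order a baited-camera study reports, with the
  0.7 log difference (≈2×) encoding higher male encounter rates at equal
  UD. With an overdispersion target set, each pair's rate is multiplied
  by a unit-mean gamma frailty shared within the pair; the shape is
  calibrated by bisection so the known-mean Pearson dispersion matches
  the target. At near-binary count scales (mean μ well below 1) the
  gamma shape required is tiny and the *fitted*-model dispersion
  estimator is biased downward; the calibration test therefore runs at
  a photo-count scale (mean ≈ 2 events per pair) where the estimator
  is accurate.
- *Determinism*: one global seed; all substreams derive from it (animal
  IDs hash through CRC32, not Python's salted hash), so identical
  configurations give byte-identical CSVs.

## Recovery experiments and problem sizes

`run_recovery_experiment` loops simulate → fit for the exponent test,
reporting bias, RMSE, CI coverage and the offset-vs-free AICc
preference. The acceptance computation uses 100 replicates of 40
animals (20F/20M) on a 12×12-km extent with 60 cameras on an interior
10×6-km jittered grid (~900 available pairs per replicate); home ranges
overhang the camera field as in real grids. `ud_source="kernel"`
replaces the true-density covariate with a kernel estimate from a
simulated telemetry year to quantify attenuation from estimation error.
The default suite keeps single fits at n ≈ 300–900 records and
replicated experiments at 8–100 replicates — sizes chosen so the full
suite runs in minutes while Monte-Carlo error stays well inside the
asserted tolerances.

## Known limitations

- No behavioural trap response (trap-happiness/shyness), bait depletion
  or den-season shifts; the frailty is the only detection heterogeneity
  beyond sex and the optional per-animal intercept SD.
- Stationary ranges: no within-season range drift; seasonal differences
  arise only through which relocations/exposures fall in each season.
- GLMM support is random intercepts only (no random slopes, no crossed
  structures beyond the nested animal/pair case); quasi-likelihood and
  random effects cannot be combined, by construction.
- Planar coordinates with no CRS handling; callers must supply projected
  metres.
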