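# Methods

## Scope and data model

The package analyses central-place foraging from four linked data streams:
GPS fixes (1 per minute, device-on 05:00–21:00 local), tri-axial
acceleration (25 Hz, units g), hourly weather-station records, and breeding
metadata (nest contents by date, nestling masses, adult morphometrics).  The
unit of analysis is the **foraging trip**; the unit of inference is the
**individual**, which enters every mixed model as a random intercept.

## Trip segmentation

A trip is a maximal run of fixes outside a 50-m buffer around the nest (and
optional roosts), extended by its bounding inside-buffer fixes.  Including
the bounding fixes makes the closed-trip invariant exact: when a trip starts
and ends at the central place, length ≥ 2 × max-distance by the triangle
inequality, so tortuosity ≥ 2.  Rules at the day boundary: the first run of
a day with no preceding inside-buffer fix is discarded when its first fix is
more than 2 km from the nest (the device switched on mid-trip); a run cut
off by device-off is flagged incomplete and excluded from the analyses;
runs entirely in `artificial` habitat are not foraging trips.  Distances are
haversine (R = 6371 km) and headings initial great-circle bearings; at trip
scale (≤ ~18 km) this is indistinguishable from an exact geodesic.

Step metrics attribute speed and heading to the step *leaving* each fix;
the turning angle at an interior fix is the absolute heading change between
its incoming and outgoing steps, wrapped to [0, π].

## Behavioural modes

Fixes are clustered in (speed, |turn|) space with a 4-component bivariate
Gaussian mixture fitted by EM, initialized from the quadrants of the
per-axis medians and floored at 1e-8 on covariance diagonals.  After
convergence each axis is split midway between its two low and two high
component means, and components map to modes by the side of the splits their
means fall on: low/low = perch, low/high = intensive search, high/low =
relocation, high/high = extensive search.  Labels are maximum-posterior.
A single smoothing pass replaces a fix's label with the strict majority of
its 5-fix window only when the majority differs and the fix's posterior
margin (top − second) is below 0.5 — confident labels are never overridden.

The mixture is pooled **globally** across individuals by default.
Per-individual fits are available (`PipelineConfig.embc_scope`) but are
unstable below a few hundred fixes per bird and, worse, can assign
incompatible split points across birds, corrupting trip profiles downstream.

## Tactics

Each trip is summarized by its proportions of the four smoothed modes.  The
number of clusters is chosen hierarchically: the two indices able to assess
"no clustering" (gap statistic with a uniform-box reference, B = 10;
Hartigan's rule at threshold 10) first gate k = 1, ties resolving toward no
clustering; given structure, the plurality of all five indices (adding
silhouette, Calinski–Harabasz, Davies–Bouldin) over k ≥ 2 wins, ties toward
smaller k.  K-means (k = 2) then spends a 10,000-iteration budget as 100
random restarts × 100 Lloyd iterations; the cluster whose centroid has the
higher perching proportion is SF, the other DF.  Profiles are commensurate
proportions and are not re-standardized.

## Energetics

Static acceleration per axis is a centred 1-s (25-sample) running mean with
shrinking windows at the edges; dynamic = raw − static, and ODBA_t =
|dx|+|dy|+|dz|.  The trip statistic is the **mean** per-sample ODBA inside
the trip window (units g): the 0.1–0.5 g range it produces is the per-sample
scale, and a mean (unlike a sum) is comparable across trips of different
duration.

## Weather covariates

Hourly records are matched to timestamps by nearest time (ties → earlier;
gaps over 3 h are missing).  Trip direction TD is the bearing from the nest
to the trip's farthest fix.  With WS the mean of departure/return wind
speeds and WD the circular mean of the two directions, TWC = WS·cos(TD−WD)
and CWC = |WS·sin(TD−WD)|.  These formulas require the direction the wind
blows **toward**; station files usually record the *from* convention, so the
reader converts by +180° (`wind_convention="from"`, the default).  Rain is
dichotomized to presence during the trip (any matched hourly record with
rain > 0).  The proportion of non-relocation fixes in arable habitat
("time in arable lands") controls for habitat in the tactic model.

## Mixed models

**Binomial GLMM.**  P(DF trip) is modelled on the logit scale with all
predictors standardized (mean 0, SD 1), year as a treatment-coded factor,
and a per-individual random intercept integrated out by 15-node adaptive
Gauss–Hermite quadrature (per-individual mode + curvature rescaling at every
likelihood evaluation).  Optimization is bounded L-BFGS on (β, σ) with σ ≥ 0,
warm-started at the plain-logistic solution; σ below 1e-8 degrades exactly
to the GLM likelihood, so the boundary is handled without special cases.
Wald 95% CIs come from the numerical Hessian.  Individuals contributing a
single trip are excluded.  The four sex × weather interactions are removed
simultaneously in a single backward step when their CIs cover zero
(interactions that are inestimable — e.g. rain never observed for one sex —
are dropped a priori on rank grounds).  Overdispersion is the Pearson χ² of
the conditional fit over its residual df.

**Repeatability.**  R_adj = σ²_id / (σ²_id + σ²_dist) with the delta-method
observation-level variance σ²_dist = 1/(p̄(1−p̄)), p̄ the mean conditional
fitted probability (a `use="marginal"` switch exists; the choice moves
R_adj by far less than its sampling error).  Significance is a LRT against
the logistic GLM with df = 1; the χ² reference ignores the boundary and is
therefore conservative, which the calibration test quantifies (≤ 7.5%
rejections at nominal 5%).

**Reaction norms.**  One weather variable at a time enters as an
individual-level random slope with intercept covariance, fitted by Laplace
approximation (2-D Newton modes).  Because Laplace is the one-node special
case of the adaptive quadrature, the reduced (intercept-only) model is
refitted with one node so the df = 2 LRT compares like with like.

**Effect sizes and R².**  Marginal/conditional R² use the latent-scale
variance partition (σ²_f = variance of the fixed-effect predictor);
per-covariate effect size is r_j = √(β_j²·var(x_j)/(σ²_f+σ²_id+σ²_dist)),
a variance-partition approximation to semi-partial R² (exact for a single
covariate, where r = √R²_marginal).

**Gaussian LMMs** (trip descriptors and ODBA against tactic) are REML fits
(statsmodels MixedLM, with an internal closed-form REML fallback at the
σ²_id = 0 boundary).  Per-coefficient F tests use **Satterthwaite**
denominator df computed from this package's closed-form REML criterion
(delta-method variance of Var(β̂_j) against the inverse REML information) —
chosen over Kenward–Roger, whose adjustment targets small-sample bias this
synthetic-recovery setting does not probe.

**Conditional modes.**  Individual tendency is the mode of each
individual's conditional latent density at the estimates; its SD is the
standard deviation of 10,000 draws from the Gaussian (Laplace) approximation
at the mode, which is what downstream weighting consumes.

## Fitness correlates

SMI_i = M_i·(L̄/L_i)^b with b the SMA slope (b_OLS/r) of ln mass on ln keel;
DBMI is the brood mean over survivors of each nestling's daily relative mass
gain; residualizing (SMI ~ sex; DBMI ~ year + brood size; feeding frequency
~ year + sex + brood size) is plain OLS.  Associations with tendency use the
weighted Pearson correlation, weights 1/SD(tendency); p-values shuffle y
while (x, w) stay paired — permuting one side is sufficient for
exchangeability under the null — two-sided on |r|, exhaustively for n ≤ 7,
else p = (1 + #{|r*| ≥ |r_obs|})/(B + 1) with B = 9999.  Device-load
correlations run per sex.

## Synthetic-study generator

The generator defines the study conditions: 36 individuals (≈ 36% female),
2–5 tracking days each in June of 2016–2018, negative-binomial intended trip
counts (mean 14, clipped to [1, 45]) scheduled into the 05:00–21:00 window
with 5–40-min nest rests, yielding ≈ 450–550 realized trips per study.
Trip tactic is drawn from logit P(DF) = β₀ + β·z + b_i with β₀ = 0.62
(≈ 65% DF marginally), β = (0.70 solar, −0.12 rain, −0.16 TWC, 0.32 CWC,
0.53 stage) on empirically z-scored covariates, and b_i ~ N(0, 0.773²) —
the SD that implies R_adj = 0.13 at p̄ = 0.5.  Covariates are computed with
the same weather-matching rules the analysis uses, so covariate measurement
error is limited to trip-direction wander (≈ 11° SD), rain-window edge
effects, and return-time slack.

Within a trip, behaviour follows a first-order Markov chain with transition
matrix T = αI + (1−α)1π′ — stationary law exactly the tactic's target
composition (SF: 0.53/0.15/0.04/0.28; DF: 0.07/0.26/0.07/0.60 over
perch/intensive/extensive/relocation) and geometric run lengths set by the
persistence (α = 0.92 SF, 0.85 DF).  Kinematics per mode are truncated
normals (speeds 0.3/2.5/9/10 m/s, low-mode |turns| ≈ 0.2 rad, high-mode
≈ 2.1 rad); movement integrates these step-wise in a planar frame around the
nest with a heading pull toward a goal point (outbound) or the nest
(return), then converts to WGS84.  At-nest fixes sit exactly on the nest
coordinate — GPS error is deliberately not emulated.  Acceleration is
gravity (0, 0, 1) g plus white Gaussian noise with per-mode SD
(0.03/0.15/0.18/0.22 g), generated lazily per trip window to keep memory
flat.  Nestling daily gain is 0.0145 + 0.004·b_i + N(0, 0.004), coupling
growth positively to the parent's DF tendency.

**What recovery on this generator shows — and does not.**  Behavioural
labels are recovered at ≈ 90–95% and tactics at ≈ 80–90%; the residual
tactic misclassification attenuates the full-chain GLMM coefficients by
roughly a third and shrinks the recoverable individual variance — full
pipeline runs therefore often estimate σ̂²_id near zero even though the
estimator itself is unbiased at the model level (the acceptance suite checks
coefficient bias < 0.1 and R̂_adj within 0.05 of 0.13 at 40 × 30 when the
tactic labels are observed directly).  The generator also omits GPS error,
fix loss, spatially structured habitat and weather, diurnal behaviour
rhythms, and prey-driven movement — passing tests demonstrate correctness of
the estimators and rules, not that real kestrel data would yield these
numbers.

## Numerical choices and problem sizes

Convergence: EM |Δ loglik| < 1e-6 (max 200 iterations); GLMM L-BFGS-B ftol
1e-12; group-mode Newton tolerance 1e-10 with step damping at |step| > 10.
Covariance floors: 1e-8 (mixture diagonals), 1e-10 jitter (random-slope Σ).
Ties: weather matching → earlier record; consensus votes → smaller k;
smoothing majority ties → no change.  Degenerate inputs raise (zero-variance
axes, all-relocation habitat profiles, empty trip windows return flagged
NaN).  Test problem sizes are scaled to what the properties need: estimator
recovery at 40 × 30 × 50 replicates, LRT calibration at 200 null/50 power
replicates, end-to-end sign recovery at the study's native 36-individual
scale over 20 seeds, with accelerometry and reaction norms exercised on
single full runs.
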