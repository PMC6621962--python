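# Methods

`bearmove` re-creates, on synthetic data with known ground truth, a full
movement-ecology workflow for GPS-collared American black bears: fix
cleaning, behavioral segmentation, diel selection summaries, multi-scale
step selection functions (SSFs), a housing-density acclimation model,
and spatially weighted predictive surfaces.  This note documents the
models, the choices behind every tunable, and what the synthetic studies
can and cannot show.

## The synthetic study

Because real collar data of this kind are not publicly deposited, every
analysis here runs on simulated studies whose generative parameters are
stored alongside the data.

**Landscape.** A 30 m raster stack on a planar grid.  Mutually exclusive
cover classes (deciduous/coniferous/mixed forest, forested wetland,
agriculture, low-density residential) are carved sequentially from
independent Gaussian-smoothed noise fields: each class claims its target
share of the still-unassigned cells with the highest field values, which
yields contiguous patches and exact class proportions.  Percent
impervious (0–100) is elevated inside residential patches; housing
density (houses/km²) is proportional to impervious with local texture;
roads are narrow level-set bands; slope derives from a synthetic
elevation field.  The default autocorrelation range is 300 m
(smoothing SD of the noise), giving patch sizes of a few hundred meters,
comparable to southern New England land-cover grain.

**Movement.** Each bear is a 3-state switching biased correlated random
walk observed at a 45-minute fix interval.  A latent Markov chain
(encamped / foraging / movement) emits step lengths from state-specific
gamma distributions and turning angles from von Mises distributions;
candidate endpoints are then accepted with probability proportional to
exp(Σβ·x) with covariates read at the endpoint, so realized selection
obeys an SSF with the configured coefficients.  A mild centripetal bias
toward the home center (weight growing with distance, saturating at
2 km) keeps home ranges bounded; it is part of the movement kernel, not
of habitat selection.  Coefficient sets switch by season (calendar) and
by diel period at configured day bounds (06:00–19:00 local in the
simulator).  Between den entry and emergence the bear sits at its den
with 5 m Gaussian jitter, which makes den detection testable.

**Emission defaults.** Gamma means 20 / 120 / 500 m (SDs 15 / 70 / 250),
von Mises concentrations 0.3 / 0.8 / 3.0 with the encamped mean angle at
π (frequent reversals).  These are free parameters of the generator;
they were fixed once so that decoding the simulated chain with the
*true* parameters attains ~94% accuracy — i.e., the states are
discriminable in principle, which any recovery test presupposes — and so
that the movement state produces directed, several-hundred-meter steps
typical of published bear HMM fits.

**Collar imperfections.** Fixes are annotated with a quality class
(unresolved / QFP-uncertain / QFP-certain / 2D / 3D) and a lognormal
PDOP (median 2.5, log-SD 0.8); a small fraction is dropped outright to
create schedule gaps.  Default class rates give an expected
quality-filter loss of ~3.9%, the few-percent scale typical of collar
screens.  The expected loss is available in closed form
(`expected_removal_fraction`) for auditing.

**Acclimation truth.** Each bear's impervious coefficient is the
population logistic evaluated at the housing density of its home pixel —
lower asymptote −1.2, upper −0.1, inflection 75 houses/km², slope
0.08 km²/house — plus N(0, 0.05) individual noise.  Rural bears avoid
impervious strongly; suburban bears only weakly.

## Preprocessing

The quality screen removes unresolved fixes, weakly resolved fixes
(QFP-uncertain or 2D) with PDOP > 5, and strongly resolved fixes
(QFP-certain or 3D) with PDOP > 20; resolved fixes lacking PDOP are
removed and logged.  Removal fractions are reported per bear and pooled.

Steps join successive fixes whose spacing is within ±2 min of the
nominal interval; nothing spans a gap.  Turning angles are changes in
movement heading, wrapped to (−π, π], defined only when the previous
step abuts the current one.

Denning is delineated automatically: the displacement between
consecutive daily mean positions is thresholded at 100 m, and the
longest run of at least 30 stationary days inside an October–May search
window is the den period (entry = day before the run, emergence = first
day movement resumes).  On simulated dens with 5 m jitter this recovers
the configured dates within ±2 days.  The visual-inspection alternative
is not reproducible in software, hence the automated rule.

Diel labels use the half-open convention [sunrise, sunset) = day,
applied to the *step start* in local time.  Sunrise and sunset come from
the standard NOAA solar-geometry algorithm (verified within a few
minutes against published values for Amherst, MA); latitudes beyond
±66° are rejected.  The default season calendar is spring (den emergence
to June 14), summer (June 15 – August 9), fall (August 10 to den entry).

## Behavioral HMM

A 3-state hidden Markov model with gamma step lengths and von Mises
turning angles, fitted per bear by direct maximization of the forward
log-likelihood (L-BFGS-B on unconstrained transforms: log gamma
means/SDs, log concentrations, multinomial-logit transition rows).  The
initial distribution is tied to the stationary distribution of the
transition matrix, saving two free parameters.  Default 10 random
restarts (quantile-based gamma-mean starts, perturbed per restart)
because the likelihood is multimodal; the pipeline uses 4 restarts,
which on the packaged study reaches the same optimum.  Zero step lengths
are replaced by half the minimum positive length (the gamma density is
undefined at 0); the angular term is omitted where the turning angle is
undefined.  States are relabeled in increasing order of gamma mean, so
state 2 is always "movement"; decoding is exact Viterbi.  The forward
recursion matches brute-force path enumeration to 1e-8 on short
sequences (tested for every length ≤ 8).

## Seasons from data

Daily means of speed, |turning angle|, cover-class indicators and
percent impervious at step endpoints are smoothed with a centered 5-day
window and range-standardized to [0, 1] per bear-year (zero-range
features are flagged and zeroed).  k-means (10 restarts) over the pooled
daily table, with k chosen by the gap statistic: B = 20 uniform
reference sets over each feature's observed range, W_k as cluster
inertia, and the one-standard-error rule (smallest k with
gap(k) ≥ gap(k+1) − s_{k+1}).  Daily aggregation stabilizes k-means and
weights days equally.  One statewide calendar is derived by taking the
modal cluster per calendar day across bear-years, smoothing with a 7-day
modal filter, and converting contiguous runs to season start dates; the
pooling rule is this package's construction.

## Diel selection ratios

Availability is each bear's seasonal 95% kernel-density home range: a
binned bivariate KDE (fix counts on the landscape grid smoothed with an
axis-wise Gaussian at the normal-scale bandwidth h = sd·n^(−1/6)), with
the isopleth as the smallest level set holding ≥ 95% of mass.  The
third-order ratio per 45-minute bin is the mean fraction of the step
path inside a category (sampled every 10 m along the bare segment,
configurable) divided by the category's proportion inside the isopleth;
forest, wetland and residential classes are combined into groups before
the ratio.  Confidence intervals resample *bears* (the inferential
unit), not steps.  Under uniform use of the home range the forest-group
ratio is 1 within ±0.05 at 2000 steps; rarer categories carry binomial
noise of sqrt(p(1−p)/n)/p on the ratio scale, which exceeds 0.05 —
calibration checks on rare classes must use that wider band.

## Multi-scale SSF

Used covariates: mean (continuous) or areal proportion (categorical)
over cells whose centers lie within 30 m of the step segment.
Available covariates: Gaussian-kernel weighted means centered on the
step midpoint (configurable: start), kernel truncated at 3σ per axis and
renormalized over in-raster cells; σ ranges over the mean distance moved
in 45 min – 6 h (recomputed from the data by default; any list can be
supplied).  Both extractions match explicit cell-enumeration oracles to
1e-9.  Used and available values are z-scored jointly per bear dataset;
the constants are stored for prediction.

The 1:1 matched conditional likelihood Σ log σ(βᵀ(x_used − x_avail)) is
maximized by damped Newton iteration; complete separation (a one-signed
difference column) is flagged and the variable excluded.  Model building
is the two-stage protocol: univariate AICc per (variable, scale) with
ties to the smaller σ; greedy pruning of pairs with |r| > 0.7 (strict)
keeping the lower-AICc member; bidirectional greedy stepwise from the
null model, stopping when no single add/drop lowers AICc.

**A caution on scale identifiability.** In fully mechanistic
simulations (bears walking a landscape, selection on the endpoint
covariate), the availability scale is only weakly identified through the
used-vs-kernel pairing: univariate AICc rankings drift to adjacent or
extreme scales because kernel means at different σ are highly
correlated and the single-draw noise of the used value dominates.  The
scale-recovery harness therefore generates the used covariate directly
from the matched-pair model at the generating scale, with availability
at all six scales extracted from a real synthetic landscape so the
cross-scale correlation structure is preserved; mismatched scales then
suffer classical errors-in-variables attenuation and the generating
scale is recovered in ≥ 95% of replicates at 1000 strata.  Two
practical corollaries: (i) characteristic scales estimated from short
tracks on small landscapes should be read with care; (ii) sampling
designs must keep kernels far from raster edges — an interior margin
narrower than the largest kernel biases large-σ availabilities toward
the local (not global) mean, which we observed to distort scale
rankings before widening the margin.  For the same reason the pipeline
caps candidate scales so the 3σ kernel truncation fits within half the
smaller landscape extent; on the 6 km packaged landscape this keeps the
two sub-kilometer scales and discards the rest, and measurably improves
both the fitted models and their hold-out validation.

## Housing-density acclimation (HRHD)

HRHD is total houses inside the 95% isopleth divided by isopleth area
(the raster stores houses/km², so this is its mean over the isopleth).
The per-bear standardized impervious coefficient is regressed on HRHD
under three shapes compared by AICc (k = curve parameters + 1 for the
error variance): intercept-only, straight line, and the four-parameter
logistic L₀ + (L₁−L₀)/(1+exp(−s(x−x₀))).  The 4-parameter form can
express "weaker avoidance" (negative to less-negative) without forcing a
sign change.  Logistic start values come from data quantiles with five
perturbed restarts.  The fit requires ≥ 8 bears whose final SSF retains
the impervious variable (configurable); the packaged 5-bear demo is
below that minimum by design and reports the per-bear table only.

## Predictive surfaces and validation

Each bear's surface is ŵ(x) = exp(Σ β_v z_v(x)) with z_v the raster
standardized by the fit-time constants.  The projection uses the *raw*
covariate rasters by default.  An alternative that smooths each raster
at its characteristic scale (mirroring availability extraction) is
available via `smooth_at_scale=True` but is not the default: on the
packaged study the fitted coefficients are good (raw-covariate
log-surfaces correlate 0.78–0.95 with the true linear predictor), yet
scale-smoothing collapses that agreement to ~0.1–0.3 and drives
hold-out calibration to zero, because the selected scales (1–2.4 km) are
a large fraction of the demo landscape.

Per-bear surfaces are min-max rescaled to [0, 1] before combination so
that one bear with a steep linear predictor (the exponential spans
orders of magnitude) cannot dominate the population surface; measured on
the packaged study this raises hold-out Boyce from about −0.2 to ~0.65.
Combination weights are 1/max(d, ε) from each bear's home-range
centroid (ε = half a pixel, avoiding the singularity), normalized per
pixel to sum to one, making the combined surface a pixelwise convex
combination.

The Boyce index partitions the surface's value range into equal-width
classes (default 10) and Spearman-correlates the class rank with the
predicted-to-expected ratio F_i of hold-out points, omitting classes
with no pixels.  Note the Spearman-based index ranges −1 to 1 (not 0 to
1).  Two calibration facts shape its use here: (i) points sampled in
proportion to the surface give Boyce ≥ 0.9 at the default 10 classes;
(ii) under *uniform* (null) sampling the ranks of near-equal F_i are an
almost-random permutation, so the null SD of the index is ≈ 1/√(k−1) —
about 1/3 at 10 classes — and null checks ("index near 0") use 20
classes, where the null SD is 0.23.  Hold-out points come from hold-out
bears simulated on the *same* landscape from the same generative
population (fresh home centers and coefficient noise).

Surface comparisons report the pixelwise Pearson correlation, the
difference raster, and masks of the top 20% most-positive and
most-negative difference pixels (quantiles taken separately over the
positive and the negative side).

## Pipeline and problem sizes

Stages hand off through flat files (CSV, ESRI ASCII grids, YAML/JSON) so
any stage can be rerun and inspected; the manifest records seeds and
output hashes, and reruns with the same config are bit-identical.  The
packaged study — 5 bears, 60 days at 45-minute fixes on a 200×200-cell
(6 km) landscape, 4 HMM restarts, 500 bootstrap draws — runs all eight
stages in well under a minute on one CPU; recovery harnesses use 1000–
5000 strata and 10–50 replicates.  These sizes were chosen so the whole
analysis iterates quickly while every statistical check retains clear
power margins.

## What the synthetic studies do not show

The generator omits GPS positional error (only quality annotation),
male bears, inter-annual food variation, multi-year landscapes, and any
real geography; its selection acts on endpoint covariates rather than
on kernel-summarized neighborhoods.  Passing recovery tests therefore
demonstrates the estimators' correctness under the stated generative
models, not the ecological validity of any particular field inference.
Individual SSFs fitted to ~60 days of data are noisy — occasional
wrong-signed minor coefficients are expected and visible in the demo —
which is precisely why the surface combination and its validation
matter.
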