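# Methods

This note documents the models, the numerical choices, and the synthetic
data generator behind `axokin`, in enough detail to judge what a passing
test suite does — and does not — establish about real feeding videos.

## Kinematic extraction

**Smoothing.** Raw tracker coordinates (x and y separately, per landmark)
are smoothed with a natural cubic smoothing spline, the penalised least
squares fit minimising `Σ(yᵢ − f(tᵢ))² + λ∫f″(u)²du`.  The penalty is not
set directly: the user requests an *effective degrees of freedom* target —
the trace of the smoother matrix S(λ) — and λ is found by a monotone root
search (df falls from n at λ=0 to 2 as λ→∞).  The default target is 80 df
at 1000 frames/s, capped at `n/4` for short series (80 df is meaningless
when n < 80); the realised df is recorded.  The solver is the banded
Reinsch/Green–Silverman construction, O(n) per series with the λ cached per
(series length, spacing, df); fitted values agree with R's
`smooth.spline(..., df=, all.knots=TRUE)` to ~5·10⁻⁶, which the test suite
checks directly against `Rscript`.

**Geometry and derivatives.** All distances are Euclidean, all angles come
from the law of cosines with the arccos argument clamped to [−1, 1], so the
pipeline is exactly invariant to rotation, translation and reflection of
the camera frame (the image y-axis points down; nothing is flipped, because
hyoid depression is defined through the distance to the jaw joint `am`, not
through y).  Speeds are first differences of smoothed signals, assigned to
interval midpoints and linearly re-interpolated onto the frame grid so that
a signal and its derivatives share one time base; accelerations are
differences of differences.  Speeds and accelerations are reported as
magnitudes.

**Events.** Every cycle is delimited on the excursion above a pre-bout
baseline (median of the first 30 frames).  A cycle starts at the last
sample at or below `onset_frac` (default 5%) of its peak excursion before
the peak, and ends at the first sample back at or below a threshold after
the peak — `onset_frac` for the gape (mouth closed), `return_frac` (10%)
for the hyoid ("returned to its initial position").  A hyoid pulse that
plateaus instead of returning ends where its rate stays below 5% of its
peak rate for 10 frames, and the bout is flagged `plateau-ended`.  Ties at
equal maxima take the earliest sample.  All reported times are relative to
the detected mouth-opening onset; the bout ends (PCD) when the last cycle
ends.  The gape-angle vertex is at `am` (the only jaw-joint landmark) and
the head-angle vertex at the eye, with arms to `uj` and `sh`; the maximum
head angle is searched over the whole bout.

These thresholds are operational definitions for clauses that are usually
left qualitative ("when the mouth started to open").  A threshold detector
necessarily reports cycle boundaries *inside* the generating pulse — the
5% crossing of a pulse with rise time D sits about 0.14·D after true
onset — so recovery tests compare detected timings against the analytic
threshold-crossing times, not against pulse onsets.

## Scaling analysis

Peak performance per individual is the maximum across that individual's
bouts for magnitude variables and the **minimum** for timing and duration
variables (the fastest bout is the best performance; the direction is
configurable, since conventions differ).  Ordinary least squares of
log10(peak) on log10(SVL) gives slope, SE, R² and a t-based 95% CI
(df = n−2; this reconstructs the published gape CI 0.79–1.17 from
0.98 ± 0.09 at n = 25).  Angles, already dimensionless, are
log-transformed like everything else.  Geometric similarity predicts
exponents 1 (lengths, timings, durations), 0 (angles, speeds) and −1
(accelerations); classification compares the prediction with the CI,
bounds inclusive.  Timing variables are referenced to bout onset in
seconds; the published timing intercepts (~0.3 log10 s for millisecond
events) imply a different reference point and are not reproduced.

## Mixed-model stage statistics

All inference uses a Gaussian random-intercept model per individual,
`log10(y) ~ log10(SVL) [* stage] + (1 | individual)`, fitted by a dedicated
profile-likelihood routine (the variance ratio is the only free parameter,
making a fit ~1 ms, which the 2000-replicate calibration suites need).
Estimates agree with statsmodels `MixedLM` to ~10⁻⁶ and F/df/p with
`lmerTest` type-II Satterthwaite to 3–4 decimals.

Type II respects marginality: the interaction is tested in the full model,
main effects in the additive refit.  Denominator df use the Satterthwaite
approximation — per 1-df contrast `ν = 2(l′Cl)²/(g′Ag)` with g the
gradient of the contrast variance in the variance components and A their
asymptotic covariance from the observed information; multi-df terms
combine eigencontrast df in the usual way.  Boundary fits (σ²ᵤ → 0) fall
back to the ordinary regression with residual df, where the F statistics
coincide with type-II fixed-effects ANCOVA exactly.

**REML, not ML, for inference.** With 25 individuals, ML variance
estimates are biased low and Satterthwaite F tests built on them reject a
true null about twice too often (measured 0.09–0.12 at α = 0.05, both
here and in `lmerTest` itself).  Estimation therefore defaults to REML,
whose measured type-I error on the study design is 0.043–0.057 for every
term; `method="ml"` is available where ML is wanted (e.g. likelihood
comparisons).  Post-hoc stage contrasts are estimated-marginal-mean
differences at the mean log10 SVL (or on a stage-only model for the
size-ignored follow-up), Tukey-adjusted via the studentized range with the
contrast's Satterthwaite df; with two groups Tukey reduces to the plain t
test.  The immature–adult comparison recodes larvae and juveniles into one
group before fitting.

## The synthetic-data generator

The generator is the package's validation instrument: it produces feeding
bouts whose every derived quantity has a closed-form target.

**Trajectory tier.** A bout is four excursion pulses on a rigid 2-D head
template scaled to SVL: a gape pulse (the lower-jaw tip rotates about the
jaw joint so that `d(uj, lj)` follows rest gape + pulse), two delayed
hyoid-depression pulses (each hyoid point moves radially away from the jaw
joint, so its distance to `am` is rest + pulse exactly), and a small
head-elevation pulse (the shoulder swings about the eye).  Pulses are
beta-density bumps `A·τᵖ(1−τ)^q` with p+q = 8 and the rise:fall ratio
clamped to [0.68, 1.45].  Two properties motivated this family over
raised-cosine windows: it is C² everywhere — a curvature jump at onset or
peak can never be recovered from a smoothed, twice-differenced signal, and
piecewise sin² pulses have exactly such jumps — and within the clamped
asymmetry range its |acceleration| maximum sits on the broad lobe at the
pulse peak rather than in a sharp boundary tail lobe below the smoother's
resolution.  Derivative maxima and threshold crossings are computed from
the exact formula (Brent root solves and refined scans), independent of
the sampling grid and of the pipeline.

Pulse parameters follow log-log laws of SVL: gape amplitude
0.12·SVL^0.98 cm and gape cycle ≈ 60 ms·SVL^0.27 on the published scale;
hyoid amplitudes likewise.  Hyoid *cycle* durations are set near the gape
timescale rather than at the published ~0.3 s values, because those are
dynamically incompatible with the published depression speeds and
accelerations (they imply ~12 ms rise times); dynamic consistency wins, so
simulated depression speeds and accelerations sit well above the
observation-noise floor.  The posterior hyoid starts later and cycles
longer than the anterior one, making the bout end unambiguous (the
compression wave ends posteriorly); an onset floor guarantees each hyoid
crosses its detection threshold at least 3 ms after the gape does, so
detected hyoid onsets are positive and log-transformable.  Random
structure: a per-individual "quality" and per-bout "effort" factor load
positively on amplitudes and negatively on durations (vigorous strikes are
larger and faster), plus idiosyncratic individual and bout noise per
parameter — all on the log10 scale.

Observation noise is 0.3 px of Gaussian landmark jitter with occasional
(1%) low-confidence outlier frames; the cm-per-pixel calibration scales
with SVL (the camera frames the animal), so relative noise is
size-independent — modelling noise as constant in cm across a 3× size
range induces strong artificial allometry of the acceleration variables.
Recording length is the bout plus margins of 0.7×PCD (clipped to
0.12–0.35 s) on each side, keeping the fixed-df smoother's stiffness
commensurate with the movement timescale at every body size.

**Cohorts.** 16 larvae, 4 juveniles, 5 adults with 1–8 bouts each;
stage-conditional lognormal SVL (larva 2.8 cm cv 0.35, juvenile 3.5 cv
0.20, adult 8.4 cv 0.30 — adults three times larger on average, larvae and
juveniles overlapping).  One seed drives every draw; identical seeds give
byte-identical exports.

**Record tier.** The 25 variables of a real bout are functionally coupled
through the pulse shapes, so independent per-variable effects cannot be
imposed on trajectories.  For the statistical suites a second sampler
draws the 25 variables directly from per-variable laws seeded with the
published slopes and intercepts.  The speed/acceleration variables flagged
for interaction get an adult slope deviation of (ratio−1)×slope with the
published three- to seven-fold ratios, *pivoting about the adult mean log
size* so that stage means stay on the common allometry — the realistic
positive control for interaction screening.  The posterior-hyoid onset
time's imposed deviation is qualitative only; its detection power under
the study design is low, as in the published screen where it is marginal.

**Ground truth and recovery targets.** Each bout carries the generating
parameters, the analytic record (true amplitudes, durations, derivative
maxima) and the *expected measurement* record (threshold- and grid-aware
event times, windowed derivative maxima).  Recovery tests compare detected
timings to the expected record (within 2 frames, noise-free) and
amplitudes/speeds/accelerations to the analytic maxima (2/5/10%).  For
scaling recovery, the generating slope of each variable is the regression
of its noise-free expected value — conditional on each individual's
realised random effects — on log SVL over the realised cohort: the imposed
individual-level truth that peak aggregation and OLS should recover.  Every
refitted slope is required to lie within 2 SE of it.

## What the simulator does *not* emulate

Real videos contain perspective and lens distortion (a single global scale
per video is assumed), non-rigid head deformation, prey-dependent and
satiation-dependent kinematics, occlusions and identity swaps in tracking,
and multi-bout sequences (one bout per recording here; multi-bout
segmentation is out of scope).  Landmark noise is Gaussian and mostly
white; real tracker errors are heavy-tailed and temporally correlated.
Passing recovery tests therefore establishes the pipeline's correctness
under the stated observation model, not robustness to all field
conditions.  The published F and p values themselves depend on raw videos
that are not deposited and are not reproduction targets; the statistical
machinery is validated by calibration (type-I error in [0.03, 0.07] over
2000 nulls) and by oracle agreement with `lmerTest`/`emmeans` instead.

## Problem sizes and determinism

Default suites use the study-shaped cohort (25 individuals, ~100 bouts,
300–1000 frames per bout), 100 bouts for noise-free event recovery, and
2000 replicates for calibration and CI-coverage checks.  All randomness
flows from explicit integer seeds through `numpy.random.default_rng`; no
global state is touched.
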