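# Methods

This note documents the models, the synthetic-data generator, the numeric
choices, and the limitations of `tunnelpref`.

## Coordinate and timing conventions

The working-section origin is at the center of the floor; +x downwind, +y
cross-wind, +z up, all in cm.  The two floor stimuli sit symmetrically
about y = 0 (defaults (30, −15) and (30, 15)).  Frames are 0-based and
`t = frame / frame_rate` (60 Hz); period membership uses half-open
intervals `[t_start, t_end)` so a sample is never counted twice at a
boundary.  Points outside the tunnel bounds warn (tracking jitter) unless
strict validation is requested.

## Behavioral metrics

Response volumes are vertical cylinders (default 14 cm diameter × 4 cm
height) with their base on the floor, since the stimuli are floor
projections; the vertical anchoring is this package's choice.  Volume
membership is boundary-inclusive (≤), a deterministic documented
tie-break.  Dwell time is (number of in-volume, in-period samples) /
frame_rate — no sub-frame interpolation, matching the tracker's native
resolution.  A trajectory spanning period boundaries contributes to every
period it overlaps, using only its in-period frames.  Recruitment uses
single-sample entry: one in-volume sample during the period recruits the
trajectory.  Undefined ratios (zero denominators: a trajectory that never
entered either volume, a period with no activity) propagate as NA, never
as 0; they carry no weight downstream.

Occupancy maps bin the top (x, y) or side (x, z) projection into squares
of area 0.3 cm² (side ≈ 0.548 cm; the bin area is configurable and only
rescales the map) and normalize to percent of all occurrences, so any
non-empty map sums to 100%.

## Run-level QC

The three exclusion criteria are qualitative in origin; the numeric
commitments here are the package's own, recorded in every report:
clean-air recruitment > 2%, fewer than 5 recruited trajectories over the
main series, or a recruited-count ratio between series halves > 3.  A
schedule without clean-air phases reports criterion 1 as not-evaluable
rather than passed.  Exclusion is run-wise; no partial salvage.

## Beta-binomial mixed models

For a record with n trials and y successes (preference: frames in the
test volume out of frames in either volume, so time-weighting of
trajectories is exact and trials are integers; recruitment: recruited out
of active trajectories; activation: trajectories out of mosquitos
released), the model is

    logit(mu_i) = x_i' beta + u_{j(i)},   u_j ~ N(0, sigma^2),
    y_i | mu_i ~ BetaBinomial(n_i, alpha = mu_i * phi, beta = (1 - mu_i) * phi).

phi is the beta precision: the intraclass correlation is
rho = 1/(1 + phi) and the binomial limit (`dispersion="binomial"`) is
phi → ∞ / rho = 0.  Preference models use one intercept per run ×
stimulus pair; activation/recruitment one per run.  Records with zero
trials are dropped (they are uninformative); an all-zero-trials data set
is an error.

The marginal likelihood integrates each cluster's intercept with
*adaptive* Gauss–Hermite quadrature (default 20 nodes; 1 node = Laplace):
cluster modes are found by a damped, vectorized 1-D Newton iteration
(analytic first/second derivatives of the beta-binomial log-density with
respect to the linear predictor, converged to |gradient| < 1e-10), and
nodes are centered and scaled by the conditional mode and curvature.
The outer optimization is L-BFGS-B on (beta, log phi, log sigma), with
analytic gradients in the fixed-effects-only path and forward-difference
gradients otherwise (differentiating through the per-cluster modes
analytically is not tractable at this accuracy level); tolerances are
ftol 1e-13 / projected-gradient 1e-8, with log phi bounded in [−4, 15]
and log sigma in [−8, 3] so boundary estimates (sigma ≈ 0) are well
behaved.  Starting values come from a short binomial IRLS pass.  Standard
errors are from a central-difference Hessian at the optimum, computed
lazily.

Fixed effects use treatment-coded factorial designs ("a", "a:b"); the
effective parameter count uses the design-matrix rank so empty factor
cells do not inflate likelihood-ratio degrees of freedom.  No general
formula language is provided — only the factorial designs this pipeline
needs — and there is no Bayesian sampling.

Estimated group means average observed design rows with proportional
(observed-frequency) weighting over the remaining factors; preference
means are rescaled to pi = 2p − 1 and CIs transform endpoint-wise
(monotone).  Šidák families are exactly the set of contrasts requested in
one call; a priori contrasts bypass adjustment.  Per-run predictions are
the empirical-Bayes conditional modes combined with the fixed effects on
the response scale.  Stimulus-order/period covariates are not included in
the preference models by default.

## Log-logistic intensity curves

Estimation is two-stage, mirroring the upstream pipeline: the mixed model
produces run-level preference predictions, and the four-parameter
log-logistic is fitted to those predictions against relative intensity
(measured against the unilluminated black tulle target, hence strictly
positive: with ambient level a, relative intensity of LED level i is
(i + a)/a).  The asymptotes (c, d) come from a full 4-parameter fit to
the widest-range (gray) ramp — refused if max(x)/min(x) < 4 — and are
frozen for every wavelength × odor fit, which then estimates only (b, e)
by nonlinear least squares with e profiled on the log scale, a 5 × 5
multistart grid over (b, e) (b spanning both signs, e at intensity
quantiles), and Levenberg–Marquardt refinement at xtol/ftol 1e-14.
|b| < 1e-3 flags e as unidentifiable.  Per-run (b, e) deviations are a
two-stage approximation to a nonlinear mixed fit: individual run fits
shrunk toward the pooled estimate by precision weighting (both b and e
random, the default since no finer structure is specified).  Relative
potency compares inflection intensities: z = (ln e₁ − ln e₂)/SE with the
delta-method SE from the fit covariances.  The test conditions on the
frozen asymptotes and on the stage-1 predictions: uncertainty in (c, d)
and in the mixed-model stage is not propagated, so potency p-values run
anti-conservative when those stages are themselves noisy — a property of
the inflection-comparison method as practiced, not of this
implementation.  No 3- or 5-parameter variants and no ED10/ED90
comparisons are provided.

## Photometry

Photon flux is the trapezoidal integral of E(λ)·λ/(hc) over a band; the
conversion to photon density happens before band clipping so flux is
exactly additive over disjoint bands.  Irradiance (cosine-corrected) is
assumed for the floor measurement, and PWM duty cycle is assumed
proportional to irradiance, so isoquantal scaling is a single linear
factor; LED non-linearity correction is out of scope.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
per run: Poisson activation per period with a CO₂-dependent rate and a
lognormal run effect; logistic CO₂-gated recruitment (base logit −5.3 ≈
0.5% without CO₂, +2.8 at a 10% CO₂ plume ≈ 7.6%, run intercept SD 0.3),
reproducing the <1% no-CO₂ recruitment regime and a roughly an order of
magnitude CO₂ gain; and, for recruited trajectories, a total in-volume
dwell (1 + Poisson, mean 80 frames) split between test and control
volumes by a beta-binomial draw (precision phi = 8) whose mean follows

    logit(p_test) = base(lambda) + odor_shift + intensity term + run effect.

base(λ) is an inverted Gaussian centered at 525 nm (width 60 nm, edge
logit +0.25, dip depth 1.0), lowest in the green band; floral and
oviposition odors add a green-band boost (+0.6 × the same Gaussian),
host odor a uniform +0.3; the intensity term is the log-logistic effect
relative to the isoquantal level with defaults b = 1.5, c = −0.5,
d = 0.5, e = 6.0 — the inflection sits at the isoquantal level
(relative intensity 6), mid-range of the measurable ramp (x ≥ 1 by
construction, since the tulle target itself reflects ambient light), so
both shoulders of the curve are observable; the run effect is Normal
(SD 0.5) per run × stimulus pair, matching the preference model's random
structure.  Symbolic stimuli: black tulle logit +0.8 (dark targets
strongly preferred), grays 0.

Flight paths are fixed-speed (40 cm s⁻¹ at 60 Hz) correlated random
walks with reflecting walls; cruising flight carries a mild upward bias
below 8 cm so incidental floor-cylinder crossings stay in the <1%
regime observed without CO₂ (wander dwell is therefore *below* the
uniform-occupancy baseline by design).  Recruited tracks steer to the
assigned stimulus, realize their drawn dwell frames inside the cylinder
with a confined walk (counted from first volume entry; exit and
re-entry overhead adds ~3 frames per visited side, a small symmetric
attenuation of realized preference toward 0), and are never censored
below 90 frames; 15% of non-recruited tracks are censored to 30–89
frames to exercise the length filter.  Wind advection, plume tracking
kinematics (casting/surging) and aerodynamics are not modelled: passing
tests shows the *statistical* pipeline recovers what the generator
encodes, not that the flight model is aerodynamically realistic.

Determinism: each run draws from `default_rng(SeedSequence([seed, i]))`,
one substream per run, so cohorts are bit-reproducible and
parallelizable; every cohort written to disk carries a JSON manifest of
all parameters and seeds.

Schedule templates alternate stimulus order between consecutive runs
(controlling responsiveness drift, as in the bioassay) and bracket the
main series with clean-air periods presenting a black tulle target.
Default study conditions are 50 mosquitos per run, 17 channels at 120 s
per period, and a 7-level intensity ramp (0–3× isoquantal).

## Problem sizes used in tests and the acceptance script

Validation suites run at reduced but statistically adequate sizes chosen
once: oracle checks on 100 random tracks; the label-swap pipeline check
on a 5-run, 7-channel cohort; parameter recovery on 200 record-level
runs at (mu = 0.6, phi = 5, sigma = 0.5); LRT type-I calibration on 300
null replicates of 30 runs; end-to-end recovery on 10-run-per-odor
7-channel cohorts plus 20 replicate null cohorts of 6 runs per odor.
The acceptance script uses the bioassay's own cohort scales: 30 + 20
replicate 17-channel sweeps, 12 + 12 CO₂ contrast runs, and two 20-run
intensity ramps.

## Known limitations

- The wavelength LRT and odor-shift estimates inherit a small attenuation
  (order 5%) from symmetric transit frames in the generator, which the
  analysis cannot distinguish from slightly weaker true preference.
- Per-run (b, e) dose-response effects are a precision-weighted two-stage
  approximation, not a full nonlinear mixed likelihood.  When run ids are
  supplied, the (b, log e) covariance used for potency comparisons is
  cluster-robust by run, accounting for the within-run correlation of the
  stage-1 predictions; without run ids it is the iid least-squares one.
- Activation models treat the number released (50) as binomial trials;
  trajectories from re-takeoffs of the same animal are not distinguished,
  which is exactly why run-level random intercepts are essential.
- QC thresholds are calibrated for full-length series; short demo
  schedules need them relaxed via configuration.
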