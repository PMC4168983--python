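# Methods

## The model

Behavior on a speeded two-alternative motion-discrimination task is
modelled as a Wiener diffusion between two absorbing boundaries: evidence
`X(t)` starts at `z`, drifts at rate `v` with within-trial Gaussian noise
of SD `s`, and a response is produced when `X` reaches `a` (correct, with
accuracy coding) or `0` (error) after which a non-decision time is added.
`s` only sets the measurement scale and is fixed at 0.1 by the usual
convention; `z` is fixed at `a/2` (no response bias between left/right,
which are pooled by accuracy).  Two between-trial variability components
are included: drift varies across trials as Normal(`v`, `eta^2`) and
non-decision time as Uniform(`t - st/2`, `t + st/2`).  Starting-point
variability is omitted throughout (it fails to converge in this design and
the source analyses dropped it).

`eta` is the quantity of interest: it produces lower accuracy and slower
errors than corrects (at `z = a/2`), and the package's central claim to
reproduce is that baseline pupil diameter — a tonic-arousal index — tracks
`eta` and nothing else.

### First-passage-time density

The defective density at one boundary factorizes as
`f(tau | u) = exp(-u*w_s - u^2 tau / 2) * g(tau; a, w)` in noise-normalized
units, where `g` is the drift-free series.  Both classical expansions are
implemented — the small-time (image-sum) and large-time (sine-series)
forms — and selected per evaluation by the standard accuracy criterion with
truncation tolerance 1e-8 (term counts capped at 64; never reached for
realistic parameters).  Because drift enters only through a Gaussian
factor, the Normal drift distribution integrates in closed form; the
uniform `st` integral uses 11-node Gauss-Legendre quadrature.  Choice
probabilities use the closed form for `eta = 0` and 15-node Gauss-Hermite
quadrature otherwise.  Per-trial likelihoods are floored at 1e-10 so MCMC
proposals that render an observed RT impossible remain finite (and are
effectively rejected).

### Simulators

Two samplers coexist deliberately:

* An Euler-Maruyama path simulator (default `dt` = 1 ms) with
  Brownian-bridge crossing corrections (`P(cross) = exp(-2 d0 d1 / s^2 dt)`
  between steps) and midpoint-time bookkeeping.  This is the *independent*
  oracle used to validate the density (KS distance below 0.01 at n = 1e5).
  A convergence check against `dt/2` is part of the suite.
* An exact inverse-CDF sampler over the marginal defective distributions
  (8192-point grids, far tail beyond ~1e-8 survival truncated).  Recovery
  and consistency experiments draw their data here: a converged fit to
  Euler-generated data showed the fit absorbing the simulator's residual
  O(dt) distributional error into `eta` (+20%) and `a` (+4%), i.e. the
  experiment was probing the path simulator, not the estimator.

The one-choice (single-boundary) model is sampled exactly for every drift
sign: Wald(`a/u`, `(a/s)^2`) for `u > 0`; for `u <= 0` the absorption event
has probability `exp(2 u a / s^2)` and, conditional on absorbing, the time
is Wald with `|u|` (Levy for `u = 0`).  Non-absorbed or over-cap trials are
censored and excluded from RT summaries with counts reported.

## Hierarchical Bayesian fit

Subject-level parameters are drawn from group-level Normals per pupil bin
(`a`, `t`, `v`, `eta` bin-varying in the primary variant; `st` shared
across bins), with variants constraining `eta` to the group level or
letting only `eta` vary by bin.  Hyperpriors are weakly informative on the
`s = 0.1` scale: group means `v ~ N(0.2, 0.5^2)`, `a ~ N(0.12, 0.1^2) > 0`,
`t ~ N(0.4, 0.3^2) > 0`, `eta, st ~ N(0.15|0.1, 0.2^2) > 0`; group SDs
half-Normal(0.1).  Subject-level truncation to parameter domains is treated
as negligible for the group updates (truncation mass is tiny at the fitted
scales).

Sampling is adaptive random-walk Metropolis within Gibbs.  Design points:

* Subject parameters of one type are proposed simultaneously for all
  subjects and accepted per subject through one vectorized (numba)
  likelihood kernel — the step that makes a laptop-scale fit possible.
* `v` and `eta` form a posterior ridge (more drift variability is partly
  compensated by more drift), so an additional joint proposal moves both
  with correlation 0.7.
* Group means have conjugate truncated-Normal Gibbs updates; group SDs
  log-scale Metropolis steps.
* Step sizes adapt toward 35% acceptance during burn-in only, preserving
  detailed balance afterwards.
* Initialization is method-of-moments (EZ-style) per subject from accuracy
  and RT mean/variance, clamped below each subject's fastest RT; chains
  jitter the start multiplicatively.

Convergence is assessed by the Gelman-Rubin between/within-chain statistic
with the conventional 1.05 bound.  Effect distributions are per-draw
(high - low) differences of a group mean; the mass above zero uses a
half-credit convention for exact ties.  Posterior prediction thins the
pooled draws evenly and regenerates each subject's per-bin trial counts.

Reference protocol is 6 chains x 15,000 iterations with 10,000 burn-in
(30,000 pooled draws); the package's working scale — used by the tests,
the recovery experiments and the acceptance script — is 3 x 4,000 with
2,000 burn-in, which recovers the generating group means of a
26-subject x 196-trials-per-bin dataset within 5% (`v`, `a`, `t`) and 15%
(`eta`, `st`).

## Quantile (non-hierarchical) fit

Per subject, RT quantiles (.1, .3, .5, .7, .9) per bin x accuracy cell feed
a multinomial likelihood whose predicted masses come from the defective
CDFs (8-node Gauss-Legendre per inter-quantile interval); Nelder-Mead from
five 10%-jittered starts minimizes it.  Error cells under 5 trials collapse
to a median split, the standard fallback at ~36 errors per bin.  Quantiles
are Hyndman-Fan type 7 (linear interpolation).

## Pupillometry preprocessing

The chain is: pixel-to-mm scaling (subject-specific factor), linear
interpolation of invalid runs strictly shorter than 1 s (boundary-touching
runs never interpolated), artifact flagging on the interpolated stream
(amplitude < 1 mm, consecutive-sample gradient > 0.02 mm, Euclidean gaze
eccentricity > 5 degrees, residual invalid samples), per-trial baseline as
the mean over `[onset - 1 s, onset)` with any-artifact exclusion, RT-based
trial exclusion (<= 100 ms, > 1,500 ms), and within-subject binning into
the lowest/highest `floor(0.4 n)` baselines (ties broken by stable trial
order; remainder labelled middle and excluded from model fits).  The
baseline window is closed on the left and open at onset; binning happens
after exclusion, so bins are quantiles of retained trials.

## Synthetic data generator

The generator emulates the study's structure, not any particular
subject's physiology:

* Tonic arousal: a sum of three slow sinusoids (periods drawn from
  1-5 min, total amplitude 0.35 mm around a 4.5 mm mean) plus AR(1)
  measurement noise (SD 0.02 mm, 2 s time constant).  This produces slow
  trial-to-trial autocorrelation without any coupling to trial events.
* Coupling: per-trial drift SD `eta_j = max(0, eta0 + slope * z(pupil_j))`
  with `eta0 = 0.123` and slope 0.021, calibrated analytically so the
  low-vs-high-bin `eta` difference is ~0.04 (`E[z | top 2/5] = 0.966` for a
  standard normal).  The linear form follows the approximately linear
  pupil-behavior relation in the source data.
* Behavior: sequential trials with onsets = previous onset + RT +
  Uniform(5, 6.5) s; base parameters default to the fitted group means
  (`v = 0.204`, `a = 0.108`, `t = 0.523`, `st = 0.077`).  Deadline misses
  are resampled (not censored) so trial counts match the design; the
  miss count is reported and >20% raises.
* Stream: a gamma-shaped decision-locked dilation (shape 3, scale 0.5 s;
  peak ~1 s post-response, back to baseline within ~5 s, amplitude
  0.4 mm), Poisson blink dropouts (4/min, 0.1-0.4 s), AR(1) gaze jitter
  (0.5 degrees) with occasional 5.5-8 degree excursions.
* Between-subject dispersion of generating DDM parameters is 15% of each
  mean — a fixture convention, since group-level population SDs are not
  among the published estimates.  In the binned recovery fixture the
  subject deviates come in antithetic (mirrored) pairs: each subject is
  still Normal-dispersed at 15%, but the realized group mean equals the
  nominal value exactly, so recovery error measures the estimator rather
  than the luck of a particular 26-subject draw.  At 196 trials per bin
  the posterior for a group-level `eta` mean is ~10% wide (relative), which
  sets the scale of run-to-run recovery differences.

What the generator does *not* emulate: luminance effects, feedback-colour
effects on the pupil, post-error pupil carry-over (available only as an
explicit injection in tests), non-stationarity over blocks, or any
non-linear pupil-behavior coupling.  Passing tests therefore demonstrate
that the pipeline recovers the assumed coupling structure at the study's
scale and noise level — not that real pupil data obey that structure.

## Simulation studies

Grid experiments compare RT variability (two-choice and one-choice) and
accuracy/error-RT-gap (eta-vs-s) across condition pairs, averaged over 26
mock subjects drawn from the fitted group-level distributions, with
uncorrected per-pixel paired t-tests.  Conditions share random numbers
within subject — in the one-choice case through a dedicated kernel that
reuses each trial's underlying variates across every eta value — which
makes identity pixels exactly null and sharpens paired comparisons without
biasing means.  Desk-scale default is 5,000 trials/condition/subject
(reference scale 50,000 via arguments); the one-choice acceptance check
runs the reference 50,000 with a 10 s censoring cap, which bounds the
contribution of rare near-zero-drift trials whose 10-30 s passage times
otherwise dominate the SD noise.

## Regressions and calibration

Trial-level models are within-subject: logistic accuracy-on-pupil and OLS
z-log-RT on accuracy, pupil and their interaction, plus expanded variants
adding previous-trial accuracy and baseline gaze position (first trials
dropped there only).  Logistic fits flag separation (non-convergence or
exploding coefficients) and are excluded from the group one-sample t-test
with a report.  Tests are two-tailed unless a directional test is
requested.

The difficulty calibration fits the proportional-rate diffusion pair
`P(C) = 1/(1 + exp(-2 a k C))`, `RT(C) = (a/kC) tanh(a k C) + t_r`
(driftless limit `a^2 + t_r`) by joint binomial/Gaussian likelihood
(per-level RT SEMs as weights) and inverts the psychometric at 85%.

## Numerical conventions and limitations

* Series tolerance 1e-8; quadrature orders 11 (st) and 8 (interval
  masses); likelihood floor 1e-10; simplex tolerances 1e-6.
* Degenerate inputs: all-identical baselines bin by stable trial order;
  subjects with one outcome class are rejected by the regression layer;
  bins lacking both outcomes raise a degenerate-likelihood warning in the
  hierarchical fit.
* `eta` and `st` trade off at low information: at 196 trials/bin their
  group means recover within ~±11% while `v`, `a`, `t` recover within
  ~2%.  This mirrors the well-known weak identification of variability
  parameters and is why the group-only `eta` variant exists.
* The exact sampler truncates the extreme survival tail (~1e-8 mass);
  the Euler simulator carries a small O(dt) distributional bias — use the
  exact sampler when the data will be refitted by the analytic likelihood.
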