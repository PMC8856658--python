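# Methods

## Control dynamics and gain calibration

Joystick input u ∈ [−1, 1] drives linear and angular velocity through a
discrete exponentially weighted moving average, `v[t+1] = α v[t] + β u[t]`
with `α = exp(−Δt/τ)`, simulated at 60 Hz (Δt = 1/60 s).  A sustained
maximal input saturates at `vmax = β/(1−α)`.

The input gains are calibrated per trial so that an idealized 1-D bang-bang
controller (maximal forward input until a switch time s, then maximal
braking) covers a nominal displacement in a nominal duration regardless of
τ.  In continuous time the switch time is `s = τ log((1+e^{T/τ})/2)` —
independent of vmax — and the displacement at T is
`2 τ vmax log cosh(T/(2τ))`, giving

    vmax(τ) = x_cal / (2τ log cosh(T/(2τ)))

Defaults: T = 8.5 s, x_cal = 4 m (the mean target distance).  Both
`log cosh` and the switch time are evaluated in log-space forms
(`log1p`/`logaddexp`) because T/τ can reach the hundreds for
velocity-like time constants; the naive expressions overflow.

**Angular calibration.**  The angular channel uses the same formula with a
calibration angle θ_cal.  We set θ_cal = 76° = 2 × 38°, twice the maximum
target bearing: reaching a target at bearing θ along a circular arc requires
a heading change of 2θ, so this is the turn demanded by the most eccentric
target.  Values much below this are geometrically infeasible — the minimum
turning radius `x_cal/θ_cal` then exceeds the target distances themselves
(θ_cal = 19° gives a 12 m radius against 2.5–5.5 m targets) and no
controller can reach the targets in nominal time.  θ_cal is a `SimConfig`
field and can be changed freely; only the angular channel depends on it.

**Pose integration.**  Unicycle kinematics with an explicit Euler step and
midpoint heading (`x += v cos(h + wΔt/2) Δt`), which reproduces closed-form
circular arcs to second order in Δt; validated against the arc solution to
0.1% at 60 Hz.

## Time-constant process

φ = log τ follows a stationary AR(1) across trials,
`φ[t+1] = c φ[t] + η`, with c = exp(−1/τ_φ), τ_φ = 2 trials, and the
innovation moments chosen so the marginal is N(μ_φ, σ_φ²) with
μ_φ = (log τ− + log τ+)/2 and σ_φ = (log τ+ − log τ−)/4 — the bounds sit at
±2σ, so ≈ 95.45% of trials fall inside [τ−, τ+].  Defaults τ− = 0.6 s,
τ+ = 3.0 s span velocity-like to acceleration-like control.  The process is
only probabilistically bounded; a `clamp` flag hard-truncates φ for
sensitivity checks.  The first trial is drawn from the stationary marginal.

## The synthetic participant

Per trial the agent:

1. forms an internal estimate φ̂ = (λ² φ + μ_prior)/(λ² + 1) + jitter,
   τ̂ = exp(φ̂) — the closed-form Gaussian-product posterior plus Gaussian
   belief jitter (default SD 0.1 log-s) standing in for unmeasurable
   trial-to-trial fluctuations of the belief;
2. maintains a believed pose by integrating its own joystick output under
   the dynamics implied by τ̂ (filter coefficient *and* calibrated gains
   recomputed from τ̂ — an agent that believes the dynamics are τ̂ would
   also assume the yoked gain);
3. steers in belief space toward the gain-scaled target (intended gains
   0.85 radial / 0.95 angular, emulating the ubiquitous undershoot):
   - angular channel: proportional control on the believed bearing error
     (gain 2.0) with turn-rate damping scaled to critical damping of the
     linearized heading loop — without it, heading rings badly under
     acceleration-like τ; with fixed damping, velocity-like τ turns are
     needlessly sluggish;
   - linear channel: forward input gated by alignment (zero while the
     bearing error exceeds 0.1 rad far from the goal, cos² of the error
     otherwise), then full braking once the believed distance falls below
     the believed full-brake stopping distance
     `τ̂ (v − vmax̂ log(1 + v/vmax̂))` (the continuous-time rollout in
     closed form), below a 0.05 m arrival radius, or when the believed
     distance starts growing within 0.25 m of the goal (pass-by guard);
     braking holds until the believed speed drops below the 1 cm/s stopping
     threshold;
4. adds i.i.d. Gaussian motor noise (default SD 0.05) to both channels
   before clipping to [−1, 1];
5. the world integrates the same noisy output under the *true* τ; the trial
   ends when the actual speed falls below 1 cm/s after the believed stop,
   or at a hard timeout of 4 T (flagged, not dropped).

Sessions: 15 participants × 480 trials per condition by default, one τ walk
spanning all trials, condition labels randomly interleaved.  Sensory
condition affects only the agent parameters — λ defaults 0.3 (vestibular),
1.0 (visual), 0.8 (combined), μ_prior = μ_φ — matching the regime in which
a narrow prior dominates when only inertial cues are available.  No
stimulus rendering is simulated.

What the generator does *not* emulate: human response noise levels (its
stops are far less variable than real ones — see "known limitations"),
partial or corrective joystick waveforms, within-trial evidence
accumulation (τ inference is one measurement per trial), and any
platform/rendering detail.  Passing tests therefore demonstrate estimator
correctness and qualitative signatures under clean conditions, not
quantitative agreement with human data.

## Behavioral analyses

- Response gains by no-intercept least squares per component; uncentered
  R² (`1 − SSE/Σy²`), the standard choice for regression through the
  origin, with the intercept's ΔR² reported on the same uncentered scale.
- τ tertiles: equal-size groups after sorting by τ, ties broken by trial
  order, remainder to the lower groups.
- Interaction regression on SD-scaled (not centered) variables,
  no intercept: `r̃ = b r + a rτ`; partial correlations of the response
  with target, τ, and target·τ by residualization against the remaining
  predictors (equivalent to the inverse-correlation-matrix formula, which
  the tests verify).
- No-adaptation null: trials with τ within ±0.2 s of the sampling mean are
  re-integrated under τ drawn from the other trials; simulated trajectories
  are grouped by the full dataset's tertile edges and regressed (actual
  tertile gains on null tertile gains): slope 1 = no adaptation,
  0 = perfect adaptation.
- Joystick summaries: trapezoidal |u| areas and cumulative braking (area of
  the negative linear input), correlated with τ per condition.
- p-values for Pearson correlations use the two-sided t approximation; no
  multiple-comparison correction here.  Model validation uses the adjusted
  level 0.0085.

## Model fitting

All internal models are scored by the mean squared Euclidean distance
between the believed stop — the actual joystick trace re-integrated under
the model's τ̂ — and the gain-scaled target in Cartesian coordinates
(radial/angular residuals are reserved for validation).  Optimization is
deterministic: a coarse grid (μ_prior over the observed log-τ range ± 1,
λ log-spaced in [0.01, 10]; τ̂_fixed in [0.1, 30] s; switch distance in
[0.02, 3] m) followed by Nelder–Mead refinement in log-parameters,
objective tolerance 1e−6.  log λ is clamped at ±30 during refinement: the
objective is flat beyond (the observer is numerically veridical), and an
unbounded simplex otherwise wanders into overflow.  A dataset with constant
τ leaves (μ_prior, λ) unidentified; the fit warns and returns the grid
optimum.

The dynamic-prior model updates `μ[i] = (1−k) μ[i−1] + k φ[i]` with
`k = λ²/(λ²+1)`, seeded at the first trial's φ, and estimates
τ̂_i with the updated μ[i] (the literal reading of the update equation; the
measurement of trial i therefore enters both prior and likelihood).  Its
single parameter couples prior tracking and shrinkage, so the family cannot
represent a static prior exactly: on noiseless static-prior data its best
fit retains a small positive subjective-residual correlation (~0.1) that a
static fit removes.  With human-scale response noise this gap is buried;
at the synthetic noise floor it is visible.  The model-comparison paired
t-test operates on the signed per-participant correlations (comparing the
correlations each model produces); the comparison table also reports mean
absolute correlations, where this magnitude gap remains visible.

The switch (sensory-feedback) model keeps each trial's recorded angular
input, drives the linear channel at full forward input and brakes at a
fitted Euclidean distance from the gain-scaled target, integrating under
the trial's true dynamics.  Trials that never approach within the switch
distance stop at their closest approach and are flagged.  The switch-mean
minimizes the stop-position MSE; the reported spread is the standard
deviation of per-trial best switch distances (found by a coarse-to-fine
search over switch samples), since only the mean has a natural global
objective.

Carry-over estimators assign each vestibular trial the τ (or the
static-prior posterior τ̂, with parameters fitted on the visual/combined
trials) of the most recent preceding visual/combined trial; vestibular
trials without a predecessor are dropped from evaluation.

## Validation and statistics

Subjective residual errors substitute believed stops into the residual
definition; their correlation with τ should vanish if the model captures
the belief.  Actual-vs-subjective correlation magnitudes are compared
across participants with a Wilcoxon signed-rank test; model-vs-model
comparisons use a paired t-test; parameter differences use percentile
bootstrap CIs over participants.  The percentile bootstrap is calibrated
for ≳30 samples (93–95% coverage at nominal 95% in Gaussian toy runs); at
n = 15 participants it undercovers (~90%), a known small-sample property
worth remembering when reading CIs over few participants.

## Problem sizes used by the test suite

Unit tests run on sessions of 60–200 trials.  The heavier end-to-end
checks use 20 synthetic participants × 450 trials per prior regime for
parameter recovery (the estimator's median error is stable at that size),
450-trial single-participant sets for the qualitative signatures, and 15
participants for the model-equivalence comparison.  The full suite runs in
a few minutes on one CPU; the numba kernels make the ~10⁵ trial
re-integrations inside each model fit cheap.

## Known limitations

- **Measured-gain coupling in recovery.**  Fitting uses the measured
  response gain to scale targets.  On synthetic data the measured gain
  slightly exceeds the agent's intended gain because shrinkage-induced
  stopping errors are asymmetric over τ (overshoot at large τ outweighs
  undershoot at small τ on the linear scale), which inflates the fitted
  μ_prior by ~0.1 log-s if the measured gain is used as the target scale.
  Parameter-recovery checks therefore supply the generative intended gains
  (ground-truth nuisance parameters); pipeline runs on real-style data
  necessarily use measured gains and inherit this small coupling.
- The steering policy is a minimal two-phase controller; it reproduces the
  statistical structure of steering (sustained forward input, anticipatory
  braking that grows with τ) but not individual joystick idiosyncrasies.
- The stopping rule and guard radii (0.05 m arrival, 0.25 m pass-by)
  introduce a policy-discretization floor of a few centimeters in stopping
  accuracy; the veridical noiseless agent stops within 0.15 m of any
  reachable target, and this bound is frozen as a regression test.
- Angular calibration (θ_cal) in the original task is unknown; all angular
  magnitudes (wmax, angular gains) scale with it.
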