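# steerdyn

Simulation and model-based analysis of human path integration under
trial-varying control dynamics.

## The problem

In virtual-navigation steering tasks, a participant drives to a remembered
target using a joystick whose effect on velocity is filtered through a leaky
integrator:

    v[t+1] = α v[t] + β u[t],      α = exp(-Δt/τ)

The time constant τ sets the *control dynamics*: small τ means the joystick
commands velocity, large τ means it effectively commands acceleration.  When
τ varies randomly from trial to trial (a bounded log-domain random walk) and
the speed ceiling is re-calibrated each trial so every τ allows the same
nominal travel time, accurate path integration requires the participant to
*infer* τ from sensory cues (optic flow, vestibular signals, or both) — an
internal-model problem, not just a control problem.

The analyses here quantify how stopping behavior depends on τ and whether a
Bayesian observer explains it:

- **Response gain** `g = Σ(target·stop)/Σ(target²)`: no-intercept regression
  slope of stopping position on target position (1 = unbiased,
  < 1 = undershoot), radial and angular components separately.
- **Residual errors** `ε_r = r̃ − g_r r` and their correlation with τ: the
  fingerprint of misestimated dynamics.
- **Bayesian τ-estimator**: with φ = log τ, a Gaussian prior N(μ_prior, σ_p²)
  and a likelihood centered on the true φ with width σ_l give the closed-form
  posterior point estimate

      τ̂ = exp[(λ² φ + μ_prior) / (λ² + 1)],   λ = σ_p / σ_l

  fitted per sensory condition by minimizing the mean squared distance
  between the *believed* stopping position — the actual joystick trace
  re-integrated under τ̂ — and the gain-scaled target (the mean response).
- **Alternative estimators**: a trial-wise-updated (dynamic) prior, a fixed
  τ̂, carry-over of the previous visual/combined trial's τ, and a
  non-inferential sensory-feedback controller that brakes at a fixed
  distance from the target.
- **Model validation**: a model that captures the participant's belief
  should leave the *subjective* residual errors (from believed stops)
  uncorrelated with τ.

Because the original participant dataset requires a separate download, the
package ships a first-class synthetic-session generator: a closed-loop agent
whose internal τ estimate is the Bayesian posterior above (plus trial-wise
belief jitter and motor noise) steers to targets drawn like the experiment's
(distance 2.5–5.5 m, bearing ±38°), under a single τ walk spanning randomly
interleaved sensory conditions.  All analyses and fits run end-to-end on
these sessions.

## Worked example

```python
from steerdyn import SessionConfig, generate_session
from steerdyn.control_dynamics import SimConfig
from steerdyn.io_cli import bundle_from_trials
from steerdyn import behavioral_analysis as ba, observer_models as om

cfg = SessionConfig(n_participants=1, trials_per_condition=150)
bundle = bundle_from_trials(generate_session(cfg, seed=1), seed=1)

for cond in ("vestibular", "visual"):
    df, traces = bundle.condition_view(cond, participant=0)
    gains = ba.response_gain(df)
    eps = ba.residual_errors(df, gains)
    stats = ba.tau_error_stats(eps.eps_r, df["tau"].to_numpy())
    fit = om.fit_static_prior(df, traces, gains, SimConfig())
    rep = om.validate_subjective_residuals(df, traces, fit.tau_hat, gains, SimConfig())
    print(f"{cond}: g_r={gains.g_r:.3f} g_theta={gains.g_theta:.3f} "
          f"corr(eps_r, tau)={stats.r:.3f}")
    print(f"  static prior fit: lambda={fit.params['lambda_ratio']:.3f} "
          f"mu_prior={fit.params['mu_prior']:.3f} mse={fit.mse:.4f}")
    print(f"  subjective residual corr: {rep.subjective_r:+.3f} "
          f"(actual {rep.actual_r:+.3f})")
```

prints

```
vestibular: g_r=0.874 g_theta=0.978 corr(eps_r, tau)=0.948
  static prior fit: lambda=0.315 mu_prior=0.420 mse=0.0122
  subjective residual corr: -0.007 (actual +0.948)
visual: g_r=0.856 g_theta=0.941 corr(eps_r, tau)=0.878
  static prior fit: lambda=0.938 mu_prior=0.382 mse=0.0093
  subjective residual corr: +0.012 (actual +0.878)
```

Read: both synthetic conditions undershoot (radial gains ≈ 0.86–0.87) and
their actual stopping errors correlate strongly with τ.  The fitted
static-prior observer recovers the generating width ratios (the vestibular
agent was generated with λ = 0.3, the visual one with λ = 1.0) and, once the
believed trajectories are reconstructed under the fitted τ̂, the subjective
residual errors are decorrelated from τ (−0.007 and +0.012) — the model
explains the τ-dependence away.

The same pipeline is scriptable from the shell:

```
steerdyn simulate --config cfg.yaml --seed 7 --out data/
steerdyn analyze  --data data/ --out results/
steerdyn fit      --data data/ --out results/ --models static,dynamic,fixed
steerdyn validate --data data/ --fits results/fits.json --out results/
steerdyn report   --results results/ --out results/
```

## Layout

- `steerdyn.control_dynamics` — leaky integrator, closed-form gain
  calibration, bang-bang solution, pose integration
- `steerdyn.tau_process` — stationary AR(1) walk over log τ
- `steerdyn.synthetic_data` — targets, Bayesian steering agent, sessions
- `steerdyn.behavioral_analysis` — gains, residuals, τ regressions,
  no-adaptation null, joystick summaries
- `steerdyn.observer_models` — estimator family, fitting, validation,
  comparison
- `steerdyn.io_cli` — dataset files (CSV + HDF5 + JSON manifest), YAML
  config, CLI

See `docs/methods.md` for the modelling assumptions, parameter defaults,
and known limitations.
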