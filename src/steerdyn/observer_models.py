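"""Internal-model estimators of the control time constant.

The modelling framework reconstructs, trial by trial, the trajectory a
participant *believed* they travelled: an estimator produces a per-trial
time-constant estimate ``tau_hat``, the actual joystick input is
re-integrated under the dynamics implied by ``tau_hat``, and the resulting
believed stopping location is compared with the participant's mean response
(the gain-scaled target).  Estimators:

``static``
    Bayesian observer with a fixed Gaussian prior over ``phi = log tau``:
    the posterior mean/median/mode coincide and give the closed form
    ``phi_hat = (lambda^2 * phi + mu_prior) / (lambda^2 + 1)`` where
    ``lambda = sigma_prior / sigma_likelihood``.  Two free parameters
    ``(mu_prior, lambda)`` per sensory condition.
``dynamic``
    Same observer, but the prior mean is updated every trial as a weighted
    average of the previous prior mean and the current measurement,
    ``mu[i] = (1 - k) mu[i-1] + k phi[i]`` with ``k = lambda^2/(lambda^2+1)``
    and ``mu[1] = phi[1]``.  One free parameter ``lambda``.
``fixed``
    A sensory-independent model: one fixed ``tau_hat`` for all trials.
``carryover``
    The current vestibular trial inherits either the true time constant or
    the posterior estimate from the most recent visual/combined trial.
``switch``
    A non-inferential sensory-feedback controller: keep the recorded
    angular input, drive the linear channel at full forward input and
    switch to full braking at a fixed Euclidean distance from the
    gain-scaled (bias-corrected) target.

All model fits minimize the mean squared Euclidean distance between the
believed (or, for the switch model, predicted) stopping location and the
gain-scaled target, with a deterministic coarse-grid search followed by
Nelder-Mead refinement.  Validation asks whether the *subjective* residual
errors -- residuals of believed stops -- are decorrelated from the time
constant, as they should be if the model captures the participant's belief.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from steerdyn import _kernels
from steerdyn.behavioral_analysis import GainEstimate, tau_error_stats
from steerdyn.control_dynamics import SimConfig, make_dynamics

__all__ = [
    "ObserverParams",
    "PaddedTraces",
    "ModelFit",
    "SwitchModelParams",
    "DynamicPriorState",
    "ValidationReport",
    "posterior_tau",
    "believed_stop",
    "believed_stops",
    "fit_static_prior",
    "fit_dynamic_prior",
    "fit_fixed_tau",
    "carryover_estimate",
    "fit_switch_model",
    "validate_subjective_residuals",
    "paired_correlation_test",
    "compare_models",
    "bootstrap_ci",
]

logger = logging.getLogger(__name__)

#: Multiple-comparison-adjusted significance level for model-implied
#: residual-error correlations.
VALIDATION_ALPHA = 0.0085


@dataclass(frozen=True)
class ObserverParams:
    """Static-prior Bayesian observer: prior mean (log-s) and width ratio."""

    mu_prior: float
    lambda_ratio: float

    def __post_init__(self) -> None:
        if self.lambda_ratio < 0:
            raise ValueError("lambda_ratio must be >= 0")


@dataclass(frozen=True)
class DynamicPriorState:
    """Trial-wise prior means of the dynamic-prior observer."""

    mu_prior: np.ndarray
    k: float

    @property
    def prior_weight(self) -> float:
        """Weight 1 - k given to the previous trial's prior in the update."""
        return 1.0 - self.k


@dataclass(frozen=True)
class SwitchModelParams:
    """Switch distance (m) of the sensory-feedback controller."""

    switch_mean: float
    switch_sd: float

    def __post_init__(self) -> None:
        if self.switch_mean <= 0 or self.switch_sd < 0:
            raise ValueError("switch_mean must be > 0 and switch_sd >= 0")


@dataclass
class ModelFit:
    """Result of fitting one internal model to one condition's trials."""

    kind: str
    params: dict
    mse: float
    n_trials: int
    tau_hat: np.ndarray | None = None
    extra: dict = field(default_factory=dict)


@dataclass(frozen=True)
class ValidationReport:
    """Actual vs subjective residual-error correlations with tau."""

    actual_r: float
    actual_theta: float
    subjective_r: float
    subjective_theta: float
    p_subjective_r: float
    p_subjective_theta: float
    alpha: float = VALIDATION_ALPHA

    @property
    def subjective_significant(self) -> tuple[bool, bool]:
        return (
            self.p_subjective_r < self.alpha,
            self.p_subjective_theta < self.alpha,
        )


def posterior_tau(tau_trial, p: ObserverParams):
    """Closed-form posterior time-constant estimate.

    The measurement is centered on the true log time constant; the
    Gaussian-product posterior over ``phi`` has mean (= median = mode)
    ``(lambda^2 * log tau + mu_prior) / (lambda^2 + 1)``, back-transformed
    with ``exp``.  ``lambda -> inf`` returns the true value, ``lambda = 0``
    the prior mean.
    """
    tau_trial = np.asarray(tau_trial, dtype=float)
    if np.any(tau_trial <= 0):
        raise ValueError("tau_trial must be positive")
    if math.isinf(p.lambda_ratio):
        out = tau_trial
    else:
        lam2 = p.lambda_ratio**2
        out = np.exp((lam2 * np.log(tau_trial) + p.mu_prior) / (lam2 + 1.0))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# believed-trajectory reconstruction


@dataclass
class PaddedTraces:
    """Zero-padded joystick traces of a set of trials, ready for kernels."""

    uv: np.ndarray
    uw: np.ndarray
    lengths: np.ndarray
    dt: float

    @classmethod
    def from_traces(
        cls, traces: list[tuple[np.ndarray, np.ndarray]], dt: float
    ) -> "PaddedTraces":
        n = len(traces)
        max_len = max(t[0].shape[0] for t in traces)
        uv = np.zeros((n, max_len))
        uw = np.zeros((n, max_len))
        lengths = np.empty(n, dtype=np.int64)
        for i, (a, b) in enumerate(traces):
            uv[i, : a.shape[0]] = a
            uw[i, : b.shape[0]] = b
            lengths[i] = a.shape[0]
        return cls(uv=uv, uw=uw, lengths=lengths, dt=dt)

    def __len__(self) -> int:
        return self.uv.shape[0]


def _dyn_arrays(taus: np.ndarray, cfg: SimConfig):
    alpha = np.exp(-cfg.dt / taus)
    denom = 2.0 * taus
    z = cfg.T / denom
    lc = z + np.log1p(np.exp(-2.0 * z)) - math.log(2.0)
    vmax = cfg.x_cal / denom / lc
    wmax = cfg.theta_cal / denom / lc
    return alpha, vmax * (1.0 - alpha), wmax * (1.0 - alpha)


def believed_stops(
    padded: PaddedTraces,
    tau_hat: np.ndarray,
    cfg: SimConfig = SimConfig(),
    yoked_gains: bool = True,
    true_tau: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Believed stop coordinates from re-integrating actual input under tau_hat.

    With ``yoked_gains`` (default) the input gains are recomputed from
    ``tau_hat`` through the calibration formula, as a participant who
    believes the dynamics are ``tau_hat`` would assume; otherwise the
    trial's true gains (from ``true_tau``) are kept and only the filter
    coefficient follows ``tau_hat``.
    """
    tau_hat = np.asarray(tau_hat, dtype=float)
    if np.any(tau_hat <= 0):
        raise ValueError("tau_hat must be positive")
    alpha, beta_v, beta_w = _dyn_arrays(tau_hat, cfg)
    if not yoked_gains:
        if true_tau is None:
            raise ValueError("true_tau required when yoked_gains=False")
        _, beta_v, beta_w = _dyn_arrays(np.asarray(true_tau, dtype=float), cfg)
    return _kernels.believed_endpoints(
        padded.uv, padded.uw, padded.lengths, alpha, beta_v, beta_w, cfg.dt
    )


def believed_stop(
    u_v: np.ndarray,
    u_w: np.ndarray,
    tau_hat: float,
    cfg: SimConfig = SimConfig(),
    yoked_gains: bool = True,
    true_tau: float | None = None,
) -> tuple[float, float]:
    """Believed stop of one trial, as polar (r, theta) about the origin."""
    padded = PaddedTraces.from_traces(
        [(np.asarray(u_v, dtype=float), np.asarray(u_w, dtype=float))], cfg.dt
    )
    xs, ys = believed_stops(
        padded,
        np.array([tau_hat]),
        cfg,
        yoked_gains=yoked_gains,
        true_tau=None if true_tau is None else np.array([true_tau]),
    )
    return float(np.hypot(xs[0], ys[0])), float(np.arctan2(ys[0], xs[0]))


def _goal_xy(df: pd.DataFrame, gains: GainEstimate) -> tuple[np.ndarray, np.ndarray]:
    """Gain-scaled targets (the mean stopping position) in Cartesian."""
    r = gains.g_r * df["target_r"].to_numpy(dtype=float)
    th = gains.g_theta * df["target_theta"].to_numpy(dtype=float)
    return r * np.cos(th), r * np.sin(th)


def _condition_inputs(
    df: pd.DataFrame,
    traces: dict[int, tuple[np.ndarray, np.ndarray]],
    cfg: SimConfig,
) -> PaddedTraces:
    items = [
        (np.asarray(traces[i][0], dtype=float), np.asarray(traces[i][1], dtype=float))
        for i in range(len(df))
    ]
    return PaddedTraces.from_traces(items, cfg.dt)


def _mse(
    padded: PaddedTraces,
    tau_hat: np.ndarray,
    gx: np.ndarray,
    gy: np.ndarray,
    cfg: SimConfig,
    yoked_gains: bool,
    true_tau: np.ndarray | None,
) -> float:
    xs, ys = believed_stops(padded, tau_hat, cfg, yoked_gains, true_tau)
    return float(np.mean((xs - gx) ** 2 + (ys - gy) ** 2))


# ---------------------------------------------------------------------------
# model fitting

_LAMBDA_GRID = np.geomspace(0.01, 10.0, 9)


def _refine(objective, x0: np.ndarray) -> optimize.OptimizeResult:
    return optimize.minimize(
        objective,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 400},
    )


def fit_static_prior(
    df: pd.DataFrame,
    traces: dict[int, tuple[np.ndarray, np.ndarray]],
    gains: GainEstimate,
    cfg: SimConfig = SimConfig(),
    yoked_gains: bool = True,
) -> ModelFit:
    """Fit the static-prior Bayesian observer ``(mu_prior, lambda)``.

    Deterministic: a coarse grid over ``mu_prior`` (observed log-tau range
    widened by 1) and log-spaced ``lambda`` in [0.01, 10], then Nelder-Mead
    refinement in ``(mu_prior, log lambda)``.
    """
    tau = df["tau"].to_numpy(dtype=float)
    padded = _condition_inputs(df, traces, cfg)
    gx, gy = _goal_xy(df, gains)
    true_tau = None if yoked_gains else tau
    phi = np.log(tau)

    def tau_hat_of(mu: float, lam: float) -> np.ndarray:
        lam2 = lam * lam
        return np.exp((lam2 * phi + mu) / (lam2 + 1.0))

    def objective(x: np.ndarray) -> float:
        mu, loglam = x
        # beyond lam ~ e^30 the observer is numerically veridical; clamping
        # keeps the simplex from wandering into overflow on flat tails
        lam = math.exp(min(max(loglam, -30.0), 30.0))
        return _mse(padded, tau_hat_of(mu, lam), gx, gy, cfg, yoked_gains, true_tau)

    mu_grid = np.linspace(phi.min() - 1.0, phi.max() + 1.0, 9)
    grid_vals = [
        ((mu, math.log(lam)), objective(np.array([mu, math.log(lam)])))
        for mu in mu_grid
        for lam in _LAMBDA_GRID
    ]
    (mu0, loglam0), best = min(grid_vals, key=lambda t: t[1])
    if np.ptp(tau) == 0.0:
        warnings.warn(
            "all time constants identical: static-prior objective is flat in "
            "(mu_prior, lambda); returning the grid optimum"
        )
        res_x, res_f = np.array([mu0, loglam0]), best
    else:
        res = _refine(objective, np.array([mu0, loglam0]))
        res_x, res_f = res.x, float(res.fun)
    mu_star = float(res_x[0])
    lam_star = float(math.exp(min(max(res_x[1], -30.0), 30.0)))
    params = ObserverParams(mu_prior=mu_star, lambda_ratio=lam_star)
    return ModelFit(
        kind="static",
        params={"mu_prior": mu_star, "lambda_ratio": lam_star},
        mse=res_f,
        n_trials=len(df),
        tau_hat=tau_hat_of(mu_star, lam_star),
        extra={"observer": params, "yoked_gains": yoked_gains},
    )


def _dynamic_tau_hat(phi: np.ndarray, lam: float) -> tuple[np.ndarray, np.ndarray]:
    lam2 = lam * lam
    k = lam2 / (lam2 + 1.0)
    mu = np.empty_like(phi)
    mu[0] = phi[0]
    for i in range(1, phi.shape[0]):
        mu[i] = (1.0 - k) * mu[i - 1] + k * phi[i]
    tau_hat = np.exp((lam2 * phi + mu) / (lam2 + 1.0))
    return tau_hat, mu


def fit_dynamic_prior(
    df: pd.DataFrame,
    traces: dict[int, tuple[np.ndarray, np.ndarray]],
    gains: GainEstimate,
    cfg: SimConfig = SimConfig(),
    yoked_gains: bool = True,
) -> ModelFit:
    """Fit the dynamic-prior observer (single parameter ``lambda``).

    The prior mean evolves as ``mu[i] = (1-k) mu[i-1] + k phi[i]`` with
    ``k = lambda^2/(lambda^2+1)`` and is seeded with the first trial's
    ``phi``; trials must be in chronological order.
    """
    if "trial_index" in df.columns:
        ti = df["trial_index"].to_numpy()
        if np.any(np.diff(ti) < 0):
            raise ValueError("trials must be in chronological order")
    tau = df["tau"].to_numpy(dtype=float)
    phi = np.log(tau)
    padded = _condition_inputs(df, traces, cfg)
    gx, gy = _goal_xy(df, gains)
    true_tau = None if yoked_gains else tau

    def objective(x: np.ndarray) -> float:
        tau_hat, _ = _dynamic_tau_hat(phi, math.exp(float(x[0])))
        return _mse(padded, tau_hat, gx, gy, cfg, yoked_gains, true_tau)

    grid = [(math.log(lam), objective(np.array([math.log(lam)]))) for lam in _LAMBDA_GRID]
    loglam0, _ = min(grid, key=lambda t: t[1])
    res = _refine(objective, np.array([loglam0]))
    lam_star = float(math.exp(res.x[0]))
    tau_hat, mu = _dynamic_tau_hat(phi, lam_star)
    k = lam_star**2 / (lam_star**2 + 1.0)
    state = DynamicPriorState(mu_prior=mu, k=k)
    return ModelFit(
        kind="dynamic",
        params={"lambda_ratio": lam_star, "k": k, "prior_weight": 1.0 - k},
        mse=float(res.fun),
        n_trials=len(df),
        tau_hat=tau_hat,
        extra={"state": state, "yoked_gains": yoked_gains},
    )


def fit_fixed_tau(
    df: pd.DataFrame,
    traces: dict[int, tuple[np.ndarray, np.ndarray]],
    gains: GainEstimate,
    cfg: SimConfig = SimConfig(),
    yoked_gains: bool = True,
) -> ModelFit:
    """Fit the sensory-independent model: one fixed ``tau_hat`` for all trials."""
    tau = df["tau"].to_numpy(dtype=float)
    padded = _condition_inputs(df, traces, cfg)
    gx, gy = _goal_xy(df, gains)
    true_tau = None if yoked_gains else tau
    n = len(df)

    def objective(x: np.ndarray) -> float:
        t = math.exp(float(x[0]))
        return _mse(padded, np.full(n, t), gx, gy, cfg, yoked_gains, true_tau)

    grid_taus = np.geomspace(0.1, 30.0, 25)
    grid = [(math.log(t), objective(np.array([math.log(t)]))) for t in grid_taus]
    x0, _ = min(grid, key=lambda t: t[1])
    res = _refine(objective, np.array([x0]))
    tau_star = float(math.exp(res.x[0]))
    return ModelFit(
        kind="fixed",
        params={"tau_fixed": tau_star},
        mse=float(res.fun),
        n_trials=n,
        tau_hat=np.full(n, tau_star),
        extra={"yoked_gains": yoked_gains},
    )


def carryover_estimate(
    df: pd.DataFrame,
    variant: str = "true_tau",
    observer: ObserverParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Carry-over estimates for vestibular trials of an interleaved session.

    For each vestibular trial, ``tau_hat`` is taken from the most recent
    preceding visual or combined trial: either that trial's true time
    constant (``variant="true_tau"``) or its static-prior posterior
    estimate (``variant="posterior"``, requires ``observer`` -- typically
    the static fit of the visual/combined trials).  Vestibular trials with
    no predecessor are dropped.

    Returns ``(row_positions, tau_hat)`` where row positions index into
    ``df`` (which must be in chronological order).
    """
    if variant not in ("true_tau", "posterior"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "posterior" and observer is None:
        raise ValueError("posterior variant requires observer parameters")
    cond = df["condition"].to_numpy()
    if not np.any((cond == "visual") | (cond == "combined")):
        raise ValueError("dataset has no visual/combined trials to carry over from")
    tau = df["tau"].to_numpy(dtype=float)
    rows = []
    est = []
    last: float | None = None
    for i in range(len(df)):
        if cond[i] == "vestibular":
            if last is not None:
                rows.append(i)
                est.append(last)
        else:
            if variant == "true_tau":
                last = tau[i]
            else:
                last = float(posterior_tau(tau[i], observer))
    return np.asarray(rows, dtype=np.int64), np.asarray(est, dtype=float)


def fit_switch_model(
    df: pd.DataFrame,
    traces: dict[int, tuple[np.ndarray, np.ndarray]],
    gains: GainEstimate,
    cfg: SimConfig = SimConfig(),
    timeout_factor: float = 4.0,
) -> ModelFit:
    """Fit the sensory-feedback (switch-distance) controller.

    Each trial keeps its recorded angular input; the linear input is full
    forward until the simulated distance to the gain-scaled target first
    drops below the switch distance, then full braking until the speed
    falls below ``cfg.v_stop``.  The mean switch distance minimizes the
    mean squared distance between predicted and actual stops (grid +
    Nelder-Mead); the spread is the standard deviation of per-trial best
    switch distances.  Trials that never approach within the switch
    distance stop at their closest approach and are counted as flagged.
    """
    tau = df["tau"].to_numpy(dtype=float)
    gx, gy = _goal_xy(df, gains)
    sx = df["stop_r"].to_numpy() * np.cos(df["stop_theta"].to_numpy())
    sy = df["stop_r"].to_numpy() * np.sin(df["stop_theta"].to_numpy())
    n = len(df)
    n_max = int(round(timeout_factor * cfg.T / cfg.dt))
    dyn = [make_dynamics(float(t), cfg) for t in tau]
    uws = [np.ascontiguousarray(traces[i][1], dtype=float) for i in range(n)]

    def rollout_all(d: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xs = np.empty(n)
        ys = np.empty(n)
        ok = np.empty(n, dtype=bool)
        for i in range(n):
            p = dyn[i]
            xs[i], ys[i], ok[i] = _kernels.switch_rollout(
                uws[i], p.alpha, p.beta_v, p.beta_w,
                gx[i], gy[i], d, cfg.v_stop, cfg.dt, n_max,
            )
        return xs, ys, ok

    def objective(x: np.ndarray) -> float:
        d = math.exp(float(x[0]))
        xs, ys, _ = rollout_all(d)
        return float(np.mean((xs - sx) ** 2 + (ys - sy) ** 2))

    grid_d = np.geomspace(0.02, 3.0, 15)
    grid = [(math.log(d), objective(np.array([math.log(d)]))) for d in grid_d]
    x0, _ = min(grid, key=lambda t: t[1])
    res = _refine(objective, np.array([x0]))
    d_star = float(math.exp(res.x[0]))
    xs, ys, ok = rollout_all(d_star)

    # per-trial best switch distance: coarse-to-fine search over switch steps
    best_d = np.empty(n)
    for i in range(n):
        p = dyn[i]

        def err_at(k: int) -> tuple[float, float]:
            px, py, swx, swy = _kernels.switch_rollout_at_step(
                uws[i], p.alpha, p.beta_v, p.beta_w, k, cfg.v_stop, cfg.dt, n_max
            )
            e = (px - sx[i]) ** 2 + (py - sy[i]) ** 2
            d = math.hypot(gx[i] - swx, gy[i] - swy)
            return e, d

        coarse = list(range(0, n_max, 20))
        errs = [err_at(k)[0] for k in coarse]
        k0 = coarse[int(np.argmin(errs))]
        cand = range(max(0, k0 - 20), min(n_max, k0 + 21))
        pairs = [err_at(k) for k in cand]
        best_d[i] = pairs[int(np.argmin([p_[0] for p_ in pairs]))][1]

    params = SwitchModelParams(switch_mean=d_star, switch_sd=float(np.std(best_d)))
    pred_r = np.hypot(xs, ys)
    pred_theta = np.arctan2(ys, xs)
    return ModelFit(
        kind="switch",
        params={"switch_mean": params.switch_mean, "switch_sd": params.switch_sd},
        mse=float(res.fun),
        n_trials=n,
        tau_hat=None,
        extra={
            "switch_params": params,
            "pred_stop_r": pred_r,
            "pred_stop_theta": pred_theta,
            "n_flagged": int(np.sum(~ok)),
            "per_trial_switch_distance": best_d,
        },
    )


# ---------------------------------------------------------------------------
# validation and comparison


def validate_subjective_residuals(
    df: pd.DataFrame,
    traces: dict[int, tuple[np.ndarray, np.ndarray]],
    tau_hat: np.ndarray,
    gains: GainEstimate,
    cfg: SimConfig = SimConfig(),
    yoked_gains: bool = True,
) -> ValidationReport:
    """Correlations of actual and subjective residual errors with tau.

    Subjective residuals substitute the believed stop (re-integration of
    the actual input under ``tau_hat``) for the actual stop in the
    residual-error definition; a model that captures the participant's
    belief should leave them uncorrelated with the time constant (judged
    at the multiple-comparison-adjusted level ``VALIDATION_ALPHA``).
    """
    tau = df["tau"].to_numpy(dtype=float)
    padded = _condition_inputs(df, traces, cfg)
    xs, ys = believed_stops(
        padded,
        np.asarray(tau_hat, dtype=float),
        cfg,
        yoked_gains=yoked_gains,
        true_tau=None if yoked_gains else tau,
    )
    bel_r = np.hypot(xs, ys)
    bel_theta = np.arctan2(ys, xs)
    eps_act_r = df["stop_r"].to_numpy() - gains.g_r * df["target_r"].to_numpy()
    eps_act_t = (
        df["stop_theta"].to_numpy() - gains.g_theta * df["target_theta"].to_numpy()
    )
    eps_sub_r = bel_r - gains.g_r * df["target_r"].to_numpy()
    eps_sub_t = bel_theta - gains.g_theta * df["target_theta"].to_numpy()
    act_r = tau_error_stats(eps_act_r, tau)
    act_t = tau_error_stats(eps_act_t, tau)
    sub_r = tau_error_stats(eps_sub_r, tau)
    sub_t = tau_error_stats(eps_sub_t, tau)
    return ValidationReport(
        actual_r=act_r.r,
        actual_theta=act_t.r,
        subjective_r=sub_r.r,
        subjective_theta=sub_t.r,
        p_subjective_r=sub_r.p,
        p_subjective_theta=sub_t.p,
    )


def paired_correlation_test(
    actual: np.ndarray, subjective: np.ndarray
) -> tuple[float, float]:
    """Wilcoxon signed-rank test of |actual| vs |subjective| correlations.

    Applied across participants; returns (statistic, p).  Identical inputs
    give p = 1 (no evidence of a difference).
    """
    a = np.abs(np.asarray(actual, dtype=float))
    s = np.abs(np.asarray(subjective, dtype=float))
    if np.allclose(a, s):
        return 0.0, 1.0
    res = stats.wilcoxon(a, s)
    return float(res.statistic), float(res.pvalue)


def _paired_t(x: np.ndarray, y: np.ndarray) -> float:
    d = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.allclose(d, 0.0):
        return 1.0
    return float(stats.ttest_rel(x, y).pvalue)


def compare_models(
    reports: dict[str, list[ValidationReport]],
    fits: dict[str, list[ModelFit]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tabulate per-model subjective correlations and paired-test p-values.

    ``reports`` maps model name to per-participant validation reports on
    the same dataset.  Returns (summary table, pairwise paired-t p-values
    on the subjective radial correlations).  The paired test compares the
    correlations themselves (signed), matching how the model comparison is
    usually reported; the summary table also lists mean absolute
    correlations for magnitude comparisons.
    """
    if len(reports) < 2:
        raise ValueError("need at least two models to compare")
    names = list(reports)
    rows = []
    for name in names:
        rs = reports[name]
        row = {
            "model": name,
            "mean_subjective_r": float(np.mean([r.subjective_r for r in rs])),
            "mean_subjective_theta": float(np.mean([r.subjective_theta for r in rs])),
            "mean_abs_subjective_r": float(
                np.mean([abs(r.subjective_r) for r in rs])
            ),
            "mean_actual_r": float(np.mean([r.actual_r for r in rs])),
        }
        if fits is not None and name in fits:
            row["mean_mse"] = float(np.mean([f.mse for f in fits[name]]))
        rows.append(row)
    pvals = pd.DataFrame(index=names, columns=names, dtype=float)
    for i, a in enumerate(names):
        for b in names[i:]:
            p = _paired_t(
                [r.subjective_r for r in reports[a]],
                [r.subjective_r for r in reports[b]],
            )
            pvals.loc[a, b] = p
            pvals.loc[b, a] = p
    return pd.DataFrame(rows), pvals


def bootstrap_ci(
    values: np.ndarray,
    stat=np.mean,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of ``stat`` over participants."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    n = values.shape[0]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        boots[b] = stat(values[rng.integers(0, n, size=n)])
    lo, hi = np.quantile(boots, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)
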