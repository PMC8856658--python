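"""Descriptive analyses of steering responses.

All estimators work on a per-trial summary table (one row per trial with
columns ``tau``, ``target_r``, ``target_theta``, ``stop_r``, ``stop_theta``)
plus, where joystick traces are needed, a mapping from row index to input
arrays.  Radial quantities are in meters and angular quantities in radians
throughout; degrees appear only at report boundaries.

The central quantity is the *response gain*: the slope of a no-intercept
regression of stopping position on target position (1 = unbiased, < 1 =
undershooting).  Residual errors are per-trial deviations from the
gain-scaled target, ``eps_r = stop_r - g_r * target_r``; their correlation
with the control time constant tau measures how strongly steering errors
depend on the (mis)estimated control dynamics.  The no-adaptation null
re-integrates observed joystick input under other trials' time constants,
giving the gain-vs-tau pattern expected if steering ignored the dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from steerdyn import _kernels
from steerdyn.control_dynamics import SimConfig, make_dynamics

__all__ = [
    "GainEstimate",
    "ResidualErrors",
    "TauErrorStats",
    "InteractionCoeffs",
    "NullAdaptationResult",
    "origin_slope",
    "response_gain",
    "tertile_split",
    "tertile_gains",
    "residual_errors",
    "tau_error_stats",
    "interaction_regression",
    "partial_correlations",
    "null_no_adaptation",
    "joystick_summaries",
]


@dataclass(frozen=True)
class GainEstimate:
    """No-intercept regression slopes of stops on targets.

    ``r2_*`` are uncentered coefficients of determination
    (``1 - SSE / sum(y^2)``, the standard choice for regression through the
    origin); ``delta_r2_*`` is the gain in uncentered R^2 from adding an
    intercept.
    """

    g_r: float
    g_theta: float
    r2_r: float
    r2_theta: float
    delta_r2_r: float
    delta_r2_theta: float
    n: int


@dataclass(frozen=True)
class ResidualErrors:
    """Per-trial deviations from the gain-scaled mean response."""

    eps_r: np.ndarray
    eps_theta: np.ndarray


@dataclass(frozen=True)
class TauErrorStats:
    """Pearson correlation and univariate slope of residual error on tau."""

    r: float
    slope: float
    p: float


@dataclass(frozen=True)
class InteractionCoeffs:
    """Standardized no-intercept coefficients of target and target*tau.

    ``b_*`` multiply the target, ``a_*`` the target-tau interaction; both
    are estimated on variables scaled by their standard deviation (no
    centering).  ``partial_*`` hold Pearson partial correlations of the
    response with target, tau, and target*tau, controlling for the other
    two.
    """

    b_r: float
    a_r: float
    b_theta: float
    a_theta: float
    partial_r: dict[str, float]
    partial_theta: dict[str, float]


@dataclass(frozen=True)
class NullAdaptationResult:
    """No-adaptation null gains and the actual-vs-null adaptation slope.

    ``slope_* = 1`` means actual gains track the null (no adaptation to the
    dynamics); 0 means actual gains are flat across tau (perfect
    adaptation).
    """

    null_gains: list[GainEstimate]
    actual_gains: list[GainEstimate]
    slope_r: float
    slope_theta: float
    n_base: int


def origin_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """No-intercept least squares: slope, uncentered R^2, delta R^2 with intercept."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(np.dot(x, x))
    if sxx == 0.0:
        raise ValueError("all-zero regressor: slope through the origin undefined")
    g = float(np.dot(x, y)) / sxx
    ssy = float(np.dot(y, y))
    sse0 = float(np.sum((y - g * x) ** 2))
    r2_0 = 1.0 - sse0 / ssy if ssy > 0 else float("nan")
    # with intercept, R^2 still computed on the uncentered total sum of squares
    X = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    sse1 = float(np.sum((y - X @ coef) ** 2))
    r2_1 = 1.0 - sse1 / ssy if ssy > 0 else float("nan")
    return g, r2_0, r2_1 - r2_0


def _gains(df: pd.DataFrame) -> GainEstimate:
    g_r, r2_r, d_r = origin_slope(df["target_r"].to_numpy(), df["stop_r"].to_numpy())
    g_t, r2_t, d_t = origin_slope(
        df["target_theta"].to_numpy(), df["stop_theta"].to_numpy()
    )
    return GainEstimate(g_r, g_t, r2_r, r2_t, d_r, d_t, len(df))


def response_gain(df: pd.DataFrame) -> GainEstimate:
    """Radial and angular response gains of a set of trials.

    Stops are regressed on targets without an intercept, separately per
    component: ``g = sum(target * stop) / sum(target^2)``.
    """
    if len(df) < 2:
        raise ValueError("need at least 2 trials to estimate a response gain")
    return _gains(df)


def tertile_split(df: pd.DataFrame) -> list[pd.DataFrame]:
    """Split trials into three equal-size groups of increasing tau.

    Ties in tau are broken by row order for determinism; when the trial
    count is not divisible by 3, the lower groups take the remainder.
    """
    if len(df) < 3:
        raise ValueError("need at least 3 trials for a tertile split")
    order = np.lexsort((np.arange(len(df)), df["tau"].to_numpy()))
    n = len(df)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    out = []
    start = 0
    for s in sizes:
        out.append(df.iloc[order[start : start + s]])
        start += s
    return out


def tertile_gains(df: pd.DataFrame) -> list[GainEstimate]:
    """Response gains within each tau tertile (low, mid, high).

    A tertile of a single trial degenerates to the ratio stop/target.
    """
    return [_gains(part) for part in tertile_split(df)]


def residual_errors(df: pd.DataFrame, gains: GainEstimate) -> ResidualErrors:
    """Per-trial deviations from the gain-scaled target positions."""
    eps_r = df["stop_r"].to_numpy() - gains.g_r * df["target_r"].to_numpy()
    eps_t = df["stop_theta"].to_numpy() - gains.g_theta * df["target_theta"].to_numpy()
    return ResidualErrors(eps_r=eps_r, eps_theta=eps_t)


def tau_error_stats(eps: np.ndarray, taus: np.ndarray) -> TauErrorStats:
    """Pearson correlation and regression slope of residual errors on tau."""
    eps = np.asarray(eps, dtype=float)
    taus = np.asarray(taus, dtype=float)
    if eps.size < 3:
        raise ValueError("need at least 3 trials")
    if np.ptp(eps) == 0.0 or np.ptp(taus) == 0.0:
        raise ValueError("zero-variance input: correlation undefined")
    lr = stats.linregress(taus, eps)
    return TauErrorStats(r=float(lr.rvalue), slope=float(lr.slope), p=float(lr.pvalue))


def _sd_scale(a: np.ndarray, name: str) -> np.ndarray:
    sd = float(np.std(a))
    if sd == 0.0:
        raise ValueError(f"predictor {name!r} has zero variance (rank deficient)")
    return a / sd


def partial_correlations(y: np.ndarray, X: dict[str, np.ndarray]) -> dict[str, float]:
    """Pearson partial correlation of ``y`` with each named predictor.

    Computed by residualizing ``y`` and the predictor of interest against
    the remaining predictors (with an intercept) and correlating the
    residuals -- equivalent to the inverse-correlation-matrix formula.
    """
    names = list(X)
    out: dict[str, float] = {}
    for name in names:
        others = [X[n] for n in names if n != name]
        Z = np.column_stack(others + [np.ones_like(y)])
        ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
        rx = X[name] - Z @ np.linalg.lstsq(Z, X[name], rcond=None)[0]
        out[name] = float(stats.pearsonr(ry, rx)[0])
    return out


def interaction_regression(df: pd.DataFrame) -> InteractionCoeffs:
    """Two-predictor no-intercept regression of stops on target and target*tau.

    All variables are scaled by their standard deviation (no centering)
    before the fit, so the coefficients are comparable across predictors.
    Partial correlations of the response with target, tau, and target*tau
    are reported alongside.
    """
    if len(df) < 3:
        raise ValueError("need at least 3 trials")
    tau = df["tau"].to_numpy(dtype=float)
    if np.ptp(tau) == 0.0:
        raise ValueError("predictor 'tau' is constant (rank deficient)")
    out: dict[str, tuple[float, float]] = {}
    partials: dict[str, dict[str, float]] = {}
    for comp, tcol, scol in (
        ("r", "target_r", "stop_r"),
        ("theta", "target_theta", "stop_theta"),
    ):
        x = df[tcol].to_numpy(dtype=float)
        y = df[scol].to_numpy(dtype=float)
        inter = x * tau
        Xs = np.column_stack(
            [_sd_scale(x, tcol), _sd_scale(inter, f"{tcol}*tau")]
        )
        ys = _sd_scale(y, scol)
        coef, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        out[comp] = (float(coef[0]), float(coef[1]))
        partials[comp] = partial_correlations(
            ys, {"target": Xs[:, 0], "tau": _sd_scale(tau, "tau"), "target_tau": Xs[:, 1]}
        )
    return InteractionCoeffs(
        b_r=out["r"][0],
        a_r=out["r"][1],
        b_theta=out["theta"][0],
        a_theta=out["theta"][1],
        partial_r=partials["r"],
        partial_theta=partials["theta"],
    )


def _reintegrated_stops(
    uv_list: list[np.ndarray],
    uw_list: list[np.ndarray],
    taus: np.ndarray,
    cfg: SimConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Stop polar coordinates from re-integrating traces under new taus."""
    n = len(uv_list)
    max_len = max(u.shape[0] for u in uv_list)
    uv = np.zeros((n, max_len))
    uw = np.zeros((n, max_len))
    lengths = np.empty(n, dtype=np.int64)
    for i, (a, b) in enumerate(zip(uv_list, uw_list)):
        uv[i, : a.shape[0]] = a
        uw[i, : b.shape[0]] = b
        lengths[i] = a.shape[0]
    alpha = np.empty(n)
    beta_v = np.empty(n)
    beta_w = np.empty(n)
    for i, tau in enumerate(taus):
        p = make_dynamics(float(tau), cfg)
        alpha[i] = p.alpha
        beta_v[i] = p.beta_v
        beta_w[i] = p.beta_w
    xs, ys = _kernels.believed_endpoints(uv, uw, lengths, alpha, beta_v, beta_w, cfg.dt)
    return np.hypot(xs, ys), np.arctan2(ys, xs)


def null_no_adaptation(
    df: pd.DataFrame,
    traces: dict[int, tuple[np.ndarray, np.ndarray]],
    cfg: SimConfig = SimConfig(),
    tau_tolerance: float = 0.2,
    seed: int | None = 0,
) -> NullAdaptationResult:
    """Simulated no-adaptation null gains and the adaptation slope.

    Trials whose tau lies within ``tau_tolerance`` of the sampling mean are
    re-integrated under tau values drawn (without replacement where
    possible) from the *other* trials, producing trajectories whose
    steering ignores the substituted dynamics.  The simulated trajectories
    are grouped by substituted tau using the tertile edges of the full
    dataset, gains are computed against the original trials' targets, and
    the actual tertile gains are regressed on the null tertile gains: a
    slope of 1 means the data behave like the no-adaptation null, 0 means
    gains are unaffected by tau.

    ``traces`` maps dataframe row positions (0..n-1) to ``(u_v, u_w)``.
    """
    tau = df["tau"].to_numpy(dtype=float)
    mean_tau = float(tau.mean())
    base_mask = np.abs(tau - mean_tau) <= tau_tolerance
    if not base_mask.any():
        raise ValueError(
            f"no trials with tau within {tau_tolerance} s of the mean "
            f"({mean_tau:.3f} s); increase tau_tolerance"
        )
    rng = np.random.default_rng(seed)
    base_idx = np.flatnonzero(base_mask)
    donor_idx = np.flatnonzero(~base_mask)
    if donor_idx.size == 0:
        raise ValueError("no donor trials outside the tolerance window")
    subs = rng.choice(
        donor_idx, size=base_idx.size, replace=donor_idx.size < base_idx.size
    )
    sub_tau = tau[subs]

    uv_list = [np.asarray(traces[i][0], dtype=float) for i in base_idx]
    uw_list = [np.asarray(traces[i][1], dtype=float) for i in base_idx]
    sim_r, sim_theta = _reintegrated_stops(uv_list, uw_list, sub_tau, cfg)

    sim_df = pd.DataFrame(
        {
            "tau": sub_tau,
            "target_r": df["target_r"].to_numpy()[base_idx],
            "target_theta": df["target_theta"].to_numpy()[base_idx],
            "stop_r": sim_r,
            "stop_theta": sim_theta,
        }
    )
    # tertile edges from the full dataset's taus
    parts = tertile_split(df)
    edges = [float(part["tau"].max()) for part in parts[:2]]
    actual_gains = [response_gain(part) for part in parts]
    bins = np.digitize(sub_tau, edges, right=True)
    null_gains = []
    for b in range(3):
        grp = sim_df[bins == b]
        if len(grp) < 2:
            raise ValueError(
                f"null tertile {b} has {len(grp)} trials; increase tau_tolerance"
            )
        null_gains.append(response_gain(grp))

    def _slope(actual, null):
        a = np.array(actual)
        x = np.array(null)
        if np.ptp(x) == 0.0:
            return float("nan")
        return float(stats.linregress(x, a).slope)

    slope_r = _slope([g.g_r for g in actual_gains], [g.g_r for g in null_gains])
    slope_t = _slope(
        [g.g_theta for g in actual_gains], [g.g_theta for g in null_gains]
    )
    return NullAdaptationResult(
        null_gains=null_gains,
        actual_gains=actual_gains,
        slope_r=slope_r,
        slope_theta=slope_t,
        n_base=int(base_idx.size),
    )


def joystick_summaries(
    df: pd.DataFrame,
    traces: dict[int, tuple[np.ndarray, np.ndarray]],
    dt: float = 1.0 / 60.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-trial joystick input areas and cumulative braking.

    Areas are trapezoidal integrals of |u| over time (input times seconds);
    cumulative braking is the area of the negative part of the linear
    channel.  Returns the per-trial table and a per-condition summary with
    the Pearson correlation of braking against tau.
    """
    rows = []
    for i in range(len(df)):
        uv, uw = traces[i]
        uv = np.asarray(uv, dtype=float)
        uw = np.asarray(uw, dtype=float)
        rows.append(
            {
                "area_v": float(np.trapezoid(np.abs(uv), dx=dt)),
                "area_w": float(np.trapezoid(np.abs(uw), dx=dt)),
                "braking": float(np.trapezoid(np.clip(-uv, 0.0, None), dx=dt)),
            }
        )
    per_trial = pd.concat([df.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    summaries = []
    group_cols = ["condition"] if "condition" in per_trial.columns else []
    grouped = per_trial.groupby(group_cols) if group_cols else [((), per_trial)]
    for key, grp in grouped:
        if len(grp) >= 2 and np.ptp(grp["tau"].to_numpy()) > 0:
            r, p = stats.pearsonr(grp["braking"], grp["tau"])
        else:
            r, p = float("nan"), float("nan")
        summaries.append(
            {
                "condition": key[0] if group_cols else "all",
                "mean_area_v": float(grp["area_v"].mean()),
                "mean_area_w": float(grp["area_w"].mean()),
                "mean_braking": float(grp["braking"].mean()),
                "braking_tau_r": float(r),
                "braking_tau_p": float(p),
            }
        )
    return per_trial, pd.DataFrame(summaries)
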