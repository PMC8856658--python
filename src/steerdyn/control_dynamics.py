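"""Joystick-to-velocity control dynamics for the steering task.

The virtual joystick drives linear and angular velocity through a discrete
exponentially-weighted moving average (a leaky integrator), mimicking an
inertial body under viscous damping:

    v[t+1] = alpha * v[t] + beta_v * u_v[t],    alpha = exp(-dt / tau)

Small time constants ``tau`` make the joystick a velocity controller; large
ones make it approximately an acceleration controller.  The input gains
``beta`` are calibrated so that, for every ``tau``, an idealized bang-bang
controller (full forward input, then full braking) covers a nominal
displacement ``x_cal`` in exactly the nominal trial duration ``T``.  The
continuous-time bang-bang solution gives the speed ceiling in closed form:

    vmax(tau) = x_cal / (2 * tau * log cosh(T / (2 * tau)))

with the forward-to-brake switch at ``s = tau * log((1 + exp(T/tau)) / 2)``,
which is independent of ``vmax``.  Both expressions are evaluated in
numerically stable log-space forms so that ``T / tau`` in the hundreds does
not overflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MEAN_ABS_TARGET_BEARING",
    "SimConfig",
    "DynamicsParams",
    "JoystickTrace",
    "Trajectory",
    "log_cosh",
    "switching_time",
    "make_dynamics",
    "calibrated_vmax",
    "bang_bang_velocity",
    "bang_bang_displacement",
    "simulate_dynamics",
    "integrate_pose",
]

logger = logging.getLogger(__name__)

#: Mean absolute target bearing for targets uniform on +/-38 deg (19 deg).
MEAN_ABS_TARGET_BEARING = math.radians(19.0)

#: Default angular calibration displacement: twice the maximum target
#: bearing (2 x 38 deg).  Reaching a target at bearing theta along a
#: circular arc requires a total heading change of 2*theta, so this is the
#: turn the most eccentric target demands; anything much smaller makes the
#: minimum turning radius x_cal/theta_cal exceed the target distances and
#: leaves eccentric targets unreachable in nominal time.
DEFAULT_THETA_CAL = math.radians(76.0)


@dataclass(frozen=True)
class SimConfig:
    """Global simulation constants.

    Parameters
    ----------
    dt : float
        Simulation time step in seconds (60 Hz stimulus update).
    T : float
        Nominal trial duration in seconds used by the gain calibration.
    x_cal : float
        Calibration linear displacement in meters (average target distance).
    theta_cal : float
        Calibration angular displacement in radians.  Defaults to twice the
        maximum target bearing (76 deg), the heading change an arc onto the
        most eccentric target requires; see ``DEFAULT_THETA_CAL``.
    v_stop : float
        Stopping-velocity threshold in m/s (1 cm/s).
    """

    dt: float = 1.0 / 60.0
    T: float = 8.5
    x_cal: float = 4.0
    theta_cal: float = DEFAULT_THETA_CAL
    v_stop: float = 0.01

    def __post_init__(self) -> None:
        for name in ("dt", "T", "x_cal", "theta_cal"):
            if getattr(self, name) <= 0:
                raise ValueError(f"SimConfig.{name} must be positive")


@dataclass(frozen=True)
class DynamicsParams:
    """Per-trial discrete leaky-integrator coefficients.

    ``vmax = beta_v / (1 - alpha)`` is the speed a sustained maximal input
    saturates at; likewise ``wmax`` for the angular channel.
    """

    tau: float
    alpha: float
    beta_v: float
    beta_w: float
    vmax: float
    wmax: float

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie strictly inside (0, 1)")
        if self.vmax <= 0 or self.wmax <= 0:
            raise ValueError("velocity ceilings must be positive")
        for beta, ceil in ((self.beta_v, self.vmax), (self.beta_w, self.wmax)):
            if abs(beta / (1.0 - self.alpha) - ceil) > 1e-12 * ceil:
                raise ValueError("beta inconsistent with ceiling: beta != ceil*(1-alpha)")


@dataclass(frozen=True)
class JoystickTrace:
    """Dimensionless joystick input samples, each channel in [-1, 1]."""

    u_v: np.ndarray
    u_w: np.ndarray
    dt: float = 1.0 / 60.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "u_v", np.asarray(self.u_v, dtype=float))
        object.__setattr__(self, "u_w", np.asarray(self.u_w, dtype=float))
        if self.u_v.shape != self.u_w.shape:
            raise ValueError("u_v and u_w must have equal length")

    def __len__(self) -> int:
        return self.u_v.shape[0]


@dataclass
class Trajectory:
    """Velocities and integrated 2D pose of one trial.

    Pose arrays have one more sample than the velocity arrays (they include
    the initial pose at the origin, facing +x).
    """

    v: np.ndarray
    w: np.ndarray
    heading: np.ndarray
    x: np.ndarray
    y: np.ndarray
    stop_index: int

    @property
    def stop_xy(self) -> tuple[float, float]:
        return float(self.x[self.stop_index]), float(self.y[self.stop_index])

    @property
    def stop_polar(self) -> tuple[float, float]:
        """Stop position as (radial distance m, bearing rad) about the origin."""
        sx, sy = self.stop_xy
        return math.hypot(sx, sy), math.atan2(sy, sx)


def log_cosh(z):
    """``log(cosh(z))``, stable for |z| up to ~1e8.

    Uses ``log cosh z = |z| + log1p(exp(-2|z|)) - log 2``.
    """
    z = np.abs(np.asarray(z, dtype=float))
    out = z + np.log1p(np.exp(-2.0 * z)) - math.log(2.0)
    return out if out.ndim else float(out)


def switching_time(tau: float, T: float) -> float:
    """Forward-to-brake switch time of the calibrated bang-bang controller.

    ``s = tau * log((1 + exp(T/tau)) / 2)``, evaluated as
    ``tau * (logaddexp(0, T/tau) - log 2)`` so that ``T/tau`` up to ~1e3
    does not overflow.  ``s`` does not depend on ``vmax``.
    """
    if tau <= 0 or T <= 0:
        raise ValueError("tau and T must be positive")
    return float(tau * (np.logaddexp(0.0, T / tau) - math.log(2.0)))


def calibrated_vmax(tau: float, x: float, T: float) -> float:
    """Speed ceiling making the bang-bang displacement at ``T`` equal ``x``."""
    if tau <= 0 or x <= 0 or T <= 0:
        raise ValueError("tau, x and T must be positive")
    return x / (2.0 * tau) / log_cosh(T / (2.0 * tau))


def make_dynamics(tau: float, cfg: SimConfig = SimConfig()) -> DynamicsParams:
    """Derive discrete filter coefficients and calibrated gains for ``tau``.

    Raises
    ------
    ValueError
        If ``tau`` is not positive.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    alpha = math.exp(-cfg.dt / tau)
    vmax = calibrated_vmax(tau, cfg.x_cal, cfg.T)
    wmax = calibrated_vmax(tau, cfg.theta_cal, cfg.T)
    return DynamicsParams(
        tau=tau,
        alpha=alpha,
        beta_v=vmax * (1.0 - alpha),
        beta_w=wmax * (1.0 - alpha),
        vmax=vmax,
        wmax=wmax,
    )


def _exp_neg_s_over_tau(tau: float, T: float) -> float:
    # exp(-s/tau) = 2 exp(-T/tau) / (1 + exp(-T/tau)); stable for large T/tau
    e = math.exp(-T / tau)
    return 2.0 * e / (1.0 + e)


def bang_bang_velocity(t, tau: float, T: float, vmax: float):
    """Continuous-time velocity of the calibrated bang-bang controller.

    Full positive input from 0 to the switch time ``s``, then full negative
    input; the velocity returns exactly to zero at ``t = T``.
    """
    if tau <= 0 or T <= 0 or vmax <= 0:
        raise ValueError("tau, T and vmax must be positive")
    t = np.asarray(t, dtype=float)
    s = switching_time(tau, T)
    v_s = vmax * (1.0 - _exp_neg_s_over_tau(tau, T))
    rising = vmax * -np.expm1(-np.clip(t, 0.0, None) / tau)
    falling = -vmax + (v_s + vmax) * np.exp(-(t - s) / tau)
    out = np.where(t <= s, rising, falling)
    return out if out.ndim else float(out)


def bang_bang_displacement(tau: float, T: float, vmax: float) -> float:
    """Displacement accumulated by time ``T``: ``2 tau vmax log cosh(T/(2 tau))``."""
    if tau <= 0 or T <= 0 or vmax <= 0:
        raise ValueError("tau, T and vmax must be positive")
    return 2.0 * tau * vmax * log_cosh(T / (2.0 * tau))


def simulate_dynamics(
    u: JoystickTrace,
    p: DynamicsParams,
    v0: float = 0.0,
    w0: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Run the discrete leaky integrator over a joystick trace.

    Returns the velocity after each input sample, i.e. ``v[k]`` is the
    linear velocity produced by inputs ``u[0..k]`` starting from ``v0``.
    Samples outside [-1, 1] are clipped to the hardware bound with a logged
    warning.
    """
    u_v, u_w = u.u_v, u.u_w
    if np.any(np.abs(u_v) > 1.0) or np.any(np.abs(u_w) > 1.0):
        logger.warning("joystick samples outside [-1, 1]; clipping to bounds")
        u_v = np.clip(u_v, -1.0, 1.0)
        u_w = np.clip(u_w, -1.0, 1.0)
    from steerdyn._kernels import lowpass

    v = lowpass(np.ascontiguousarray(u_v), p.alpha, p.beta_v, v0)
    w = lowpass(np.ascontiguousarray(u_w), p.alpha, p.beta_w, w0)
    return v, w


def integrate_pose(v: np.ndarray, w: np.ndarray, dt: float) -> Trajectory:
    """Integrate unicycle kinematics from the origin, initially facing +x.

    Midpoint-heading Euler step: the position increment over step ``t`` uses
    the heading at the middle of the step,

        x[t+1] = x[t] + v[t] * cos(heading[t] + w[t] * dt / 2) * dt

    and ``heading[t+1] = heading[t] + w[t] * dt``, which recovers
    closed-form circular arcs to second order in ``dt``.
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape:
        raise ValueError("v and w must have equal length")
    n = v.shape[0]
    heading = np.empty(n + 1)
    heading[0] = 0.0
    heading[1:] = np.cumsum(w) * dt
    h_mid = heading[:-1] + 0.5 * w * dt
    x = np.empty(n + 1)
    y = np.empty(n + 1)
    x[0] = 0.0
    y[0] = 0.0
    x[1:] = np.cumsum(v * np.cos(h_mid)) * dt
    y[1:] = np.cumsum(v * np.sin(h_mid)) * dt
    return Trajectory(v=v, w=w, heading=heading, x=x, y=y, stop_index=n)
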