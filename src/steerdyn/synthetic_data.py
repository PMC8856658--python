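"""Synthetic steering sessions with a Bayesian-agent participant.

The generator emulates the statistical structure of a path-integration
steering experiment: targets uniform over a fan (distance 2.5-5.5 m,
bearing +/-38 deg), a single log-normal AR(1) walk of the control time
constant spanning the whole session, three randomly interleaved sensory
conditions, and steering produced by a closed-loop agent whose internal
estimate of the time constant is shrunk toward a prior.

The agent instantiates the Bayesian observer generatively: on each trial
its internal log time constant is the closed-form posterior
``phi_hat = (lambda^2 log tau + mu_prior) / (lambda^2 + 1)`` plus
trial-wise belief jitter.  It integrates its own joystick output under the
dynamics implied by ``exp(phi_hat)`` (a believed pose), steers toward the
gain-scaled target in belief space, and brakes when the believed remaining
distance falls below the believed full-brake stopping distance.  The world
integrates the same (motor-noisy) joystick output under the true dynamics,
so misestimation of the time constant produces stopping errors that
correlate with it -- the signature the analyses are designed to detect.
Sensory condition enters only through the agent parameters (prior strength,
noise); no stimulus rendering is simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from steerdyn import _kernels
from steerdyn.control_dynamics import (
    JoystickTrace,
    SimConfig,
    Trajectory,
    integrate_pose,
    make_dynamics,
    simulate_dynamics,
)
from steerdyn.tau_process import TauWalkParams, sample_tau_sequence, walk_params

__all__ = [
    "CONDITIONS",
    "TargetSpec",
    "AgentParams",
    "TrialRecord",
    "SessionConfig",
    "default_agents",
    "sample_targets",
    "simulate_agent_trial",
    "generate_session",
    "session_frame",
]

CONDITIONS = ("vestibular", "visual", "combined")

#: Prior-to-likelihood width ratios per sensory condition (the fitted regime:
#: a narrow prior dominates when only inertial cues are available).
DEFAULT_LAMBDA = {"vestibular": 0.3, "visual": 1.0, "combined": 0.8}

TARGET_R_RANGE = (2.5, 5.5)
TARGET_THETA_MAX = math.radians(38.0)


@dataclass(frozen=True)
class TargetSpec:
    """Target position in polar coordinates about the start (r m, theta rad)."""

    r: float
    theta: float

    def __post_init__(self) -> None:
        if not (TARGET_R_RANGE[0] <= self.r <= TARGET_R_RANGE[1]):
            raise ValueError(f"target distance {self.r} outside {TARGET_R_RANGE} m")
        if abs(self.theta) > TARGET_THETA_MAX + 1e-12:
            raise ValueError("target bearing outside +/-38 deg")

    @property
    def xy(self) -> tuple[float, float]:
        return self.r * math.cos(self.theta), self.r * math.sin(self.theta)


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of the synthetic participant.

    ``mu_prior`` (log-s) and ``lambda_ratio`` (prior SD over likelihood SD)
    define the internal time-constant estimator; ``lambda_ratio = inf``
    yields veridical estimates, 0 a pure-prior agent.  ``belief_jitter_sd``
    adds trial-wise Gaussian jitter (log-s) to the internal estimate,
    standing in for unmeasurable fluctuations of the belief.
    ``target_gain_r``/``target_gain_theta`` are the intended response gains
    (< 1 emulates the undershooting typical of such tasks).
    """

    condition: str = "combined"
    mu_prior: float = 0.0
    lambda_ratio: float = 0.8
    motor_noise_sd: float = 0.05
    belief_jitter_sd: float = 0.1
    target_gain_r: float = 0.85
    target_gain_theta: float = 0.95

    def __post_init__(self) -> None:
        if self.lambda_ratio < 0:
            raise ValueError("lambda_ratio must be >= 0")
        if self.motor_noise_sd < 0 or self.belief_jitter_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.target_gain_r <= 0 or self.target_gain_theta <= 0:
            raise ValueError("intended gains must be positive")


@dataclass
class TrialRecord:
    """One synthetic trial: metadata, input trace, trajectory, stop position."""

    participant: int
    trial_index: int
    condition: str
    tau: float
    tau_hat_gen: float
    target: TargetSpec
    joystick: JoystickTrace
    trajectory: Trajectory
    stop_r: float
    stop_theta: float
    timed_out: bool


def default_agents(
    mu_prior: float,
    motor_noise_sd: float = 0.05,
    belief_jitter_sd: float = 0.1,
) -> dict[str, AgentParams]:
    """Per-condition agent defaults sharing a common prior mean."""
    return {
        cond: AgentParams(
            condition=cond,
            mu_prior=mu_prior,
            lambda_ratio=DEFAULT_LAMBDA[cond],
            motor_noise_sd=motor_noise_sd,
            belief_jitter_sd=belief_jitter_sd,
        )
        for cond in CONDITIONS
    }


@dataclass
class SessionConfig:
    """Layout of a synthetic session.

    Trials are split evenly across the three sensory conditions and the
    condition labels randomly interleaved, while a single time-constant
    walk spans all trials of a participant (as in the experiment).
    """

    n_participants: int = 15
    trials_per_condition: int = 480
    walk: TauWalkParams = field(default_factory=walk_params)
    sim: SimConfig = field(default_factory=SimConfig)
    agents: dict[str, AgentParams] | None = None
    k_ang: float = 2.0
    k_damp: float = 1.0
    timeout_factor: float = 4.0

    def resolved_agents(self) -> dict[str, AgentParams]:
        if self.agents is None:
            return default_agents(mu_prior=self.walk.mu_phi)
        return dict(self.agents)


def sample_targets(
    n: int, seed: int | np.random.Generator | None = None
) -> list[TargetSpec]:
    """Draw ``n`` i.i.d. targets: distance uniform on 2.5-5.5 m, bearing on +/-38 deg."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = rng.uniform(*TARGET_R_RANGE, size=n)
    theta = rng.uniform(-TARGET_THETA_MAX, TARGET_THETA_MAX, size=n)
    return [TargetSpec(float(ri), float(ti)) for ri, ti in zip(r, theta)]


def _posterior_phi(tau: float, mu_prior: float, lambda_ratio: float) -> float:
    if math.isinf(lambda_ratio):
        return math.log(tau)
    lam2 = lambda_ratio * lambda_ratio
    return (lam2 * math.log(tau) + mu_prior) / (lam2 + 1.0)


def simulate_agent_trial(
    target: TargetSpec,
    tau: float,
    agent: AgentParams,
    cfg: SimConfig = SimConfig(),
    seed: int | np.random.Generator | None = None,
    k_ang: float = 2.0,
    k_damp: float = 1.0,
    timeout_factor: float = 4.0,
    participant: int = 0,
    trial_index: int = 0,
) -> TrialRecord:
    """Simulate one closed-loop trial of the synthetic agent.

    ``k_ang`` is the proportional steering gain on the believed bearing
    error; ``k_damp`` scales the turn-rate damping relative to critical
    damping of the linearized heading loop (1.0 = critically damped under
    the believed dynamics; damping only engages for sluggish,
    acceleration-like time constants).  The trial ends when the actual
    speed drops below ``cfg.v_stop`` after the agent believes it has
    stopped, or at a hard timeout of ``timeout_factor * cfg.T`` (the trial
    is then flagged, not dropped).
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    phi_hat = _posterior_phi(tau, agent.mu_prior, agent.lambda_ratio)
    if agent.belief_jitter_sd > 0:
        phi_hat += agent.belief_jitter_sd * rng.standard_normal()
    tau_hat = math.exp(phi_hat)

    p_true = make_dynamics(tau, cfg)
    p_bel = make_dynamics(tau_hat, cfg)

    goal_r = agent.target_gain_r * target.r
    goal_theta = agent.target_gain_theta * target.theta
    gx = goal_r * math.cos(goal_theta)
    gy = goal_r * math.sin(goal_theta)

    # Turn-rate damping at k_damp x critical for the linearized heading loop
    # heading'' = (k_ang*wmax*berr - (1+kd)*w)/tau; kd=0 already overdamps
    # velocity-like taus, so only the excess above critical is applied.
    kd = k_damp * max(0.0, 2.0 * math.sqrt(k_ang * p_bel.wmax * tau_hat) - 1.0)

    n_max = int(round(timeout_factor * cfg.T / cfg.dt))
    if agent.motor_noise_sd > 0:
        noise_v = agent.motor_noise_sd * rng.standard_normal(n_max)
        noise_w = agent.motor_noise_sd * rng.standard_normal(n_max)
    else:
        noise_v = np.zeros(n_max)
        noise_w = np.zeros(n_max)

    uv, uw, n_used, timed_out = _kernels.agent_loop(
        gx,
        gy,
        p_true.alpha,
        p_true.beta_v,
        p_true.beta_w,
        p_bel.alpha,
        p_bel.beta_v,
        p_bel.beta_w,
        p_bel.vmax,
        p_bel.wmax,
        tau_hat,
        k_ang,
        kd,
        cfg.v_stop,
        cfg.dt,
        noise_v,
        noise_w,
    )
    joystick = JoystickTrace(uv[:n_used].copy(), uw[:n_used].copy(), dt=cfg.dt)
    v, w = simulate_dynamics(joystick, p_true)
    traj = integrate_pose(v, w, cfg.dt)
    stop_r, stop_theta = traj.stop_polar
    return TrialRecord(
        participant=participant,
        trial_index=trial_index,
        condition=agent.condition,
        tau=float(tau),
        tau_hat_gen=tau_hat,
        target=target,
        joystick=joystick,
        trajectory=traj,
        stop_r=stop_r,
        stop_theta=stop_theta,
        timed_out=bool(timed_out),
    )


def generate_session(
    cfg: SessionConfig = SessionConfig(), seed: int | None = None
) -> list[TrialRecord]:
    """Generate a full multi-participant synthetic dataset.

    Each participant gets an independent random stream derived from
    ``seed``; within a participant, one time-constant walk spans all trials
    and the condition labels are a random even interleaving.
    """
    agents = cfg.resolved_agents()
    n_total = cfg.trials_per_condition * len(agents)
    trials: list[TrialRecord] = []
    streams = np.random.SeedSequence(seed).spawn(cfg.n_participants)
    for pid, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        labels = np.repeat(list(agents), cfg.trials_per_condition)
        rng.shuffle(labels)
        taus = sample_tau_sequence(cfg.walk, n_total, rng)
        targets = sample_targets(n_total, rng)
        for i in range(n_total):
            trials.append(
                simulate_agent_trial(
                    targets[i],
                    float(taus[i]),
                    agents[labels[i]],
                    cfg.sim,
                    rng,
                    k_ang=cfg.k_ang,
                    k_damp=cfg.k_damp,
                    timeout_factor=cfg.timeout_factor,
                    participant=pid,
                    trial_index=i,
                )
            )
    return trials


def session_frame(trials: list[TrialRecord]) -> "pandas.DataFrame":
    """Per-trial summary table (one row per trial, angles in radians)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "participant": [t.participant for t in trials],
            "trial_index": [t.trial_index for t in trials],
            "condition": [t.condition for t in trials],
            "tau": [t.tau for t in trials],
            "tau_hat_gen": [t.tau_hat_gen for t in trials],
            "target_r": [t.target.r for t in trials],
            "target_theta": [t.target.theta for t in trials],
            "stop_r": [t.stop_r for t in trials],
            "stop_theta": [t.stop_theta for t in trials],
            "timed_out": [t.timed_out for t in trials],
        }
    )
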