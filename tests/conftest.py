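import math

import numpy as np
import pytest

from steerdyn.control_dynamics import SimConfig
from steerdyn.io_cli import bundle_from_trials
from steerdyn.synthetic_data import AgentParams, SessionConfig, generate_session
from steerdyn.tau_process import walk_params


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig()


@pytest.fixture(scope="session")
def walk():
    return walk_params()


@pytest.fixture(scope="session")
def small_bundle(walk):
    """One participant, 60 trials per interleaved condition (fast, reused)."""
    cfg = SessionConfig(n_participants=1, trials_per_condition=60, walk=walk)
    return bundle_from_trials(generate_session(cfg, 42), config={}, seed=42)


@pytest.fixture(scope="session")
def make_condition_bundle(walk, sim_cfg):
    """Factory for single-condition sessions with a given prior-width ratio."""

    def _make(
        lam: float,
        n_participants: int = 1,
        n_trials: int = 450,
        seed: int = 0,
        **agent_kwargs,
    ):
        agent = AgentParams(
            condition="combined",
            mu_prior=walk.mu_phi,
            lambda_ratio=lam,
            **agent_kwargs,
        )
        cfg = SessionConfig(
            n_participants=n_participants,
            trials_per_condition=n_trials,
            walk=walk,
            sim=sim_cfg,
            agents={"combined": agent},
        )
        return bundle_from_trials(generate_session(cfg, seed), config={}, seed=seed)

    return _make
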