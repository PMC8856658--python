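"""Trial-to-trial evolution of the control time constant.

The log time constant ``phi = log tau`` follows a stationary AR(1) process
across trials,

    phi[t+1] = c * phi[t] + eta[t],      eta ~ N(mu_eta, sigma_eta^2)

parameterized so that the marginal distribution of ``phi`` is
``N(mu_phi, sigma_phi^2)`` with the bounds ``tau_minus``/``tau_plus``
placed two marginal standard deviations from the mean: about 95% of
sampled time constants then fall inside ``[tau_minus, tau_plus]``.  The
walk's own timescale ``tau_phi`` (in trials) sets the update coefficient
``c = exp(-1/tau_phi)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["TauWalkParams", "walk_params", "sample_tau_sequence"]


@dataclass(frozen=True)
class TauWalkParams:
    """Parameters of the log-domain AR(1) time-constant process.

    ``mu_phi = (log tau_minus + log tau_plus) / 2`` and
    ``sigma_phi = (log tau_plus - log tau_minus) / 4`` define the marginal;
    ``mu_eta = mu_phi (1 - c)`` and ``sigma_eta^2 = sigma_phi^2 (1 - c^2)``
    make the process stationary at that marginal.
    """

    tau_minus: float
    tau_plus: float
    tau_phi: float
    c: float
    mu_phi: float
    sigma_phi: float
    mu_eta: float
    sigma_eta: float


def walk_params(
    tau_minus: float = 0.6, tau_plus: float = 3.0, tau_phi: float = 2.0
) -> TauWalkParams:
    """Build a stationary walk from its bounds and timescale.

    Defaults: bounds 0.6-3.0 s (velocity-like to acceleration-like control)
    and a two-trial walk timescale.
    """
    if not (0.0 < tau_minus <= tau_plus):
        raise ValueError("need 0 < tau_minus <= tau_plus")
    if tau_phi <= 0:
        raise ValueError("tau_phi must be positive")
    c = math.exp(-1.0 / tau_phi)
    mu_phi = 0.5 * (math.log(tau_minus) + math.log(tau_plus))
    sigma_phi = 0.25 * (math.log(tau_plus) - math.log(tau_minus))
    return TauWalkParams(
        tau_minus=tau_minus,
        tau_plus=tau_plus,
        tau_phi=tau_phi,
        c=c,
        mu_phi=mu_phi,
        sigma_phi=sigma_phi,
        mu_eta=mu_phi * (1.0 - c),
        sigma_eta=sigma_phi * math.sqrt(1.0 - c * c),
    )


def sample_tau_sequence(
    p: TauWalkParams,
    n: int,
    seed: int | np.random.Generator | None = None,
    clamp: bool = False,
) -> np.ndarray:
    """Sample ``n`` trial time constants from the stationary walk.

    The first log time constant is drawn from the stationary marginal
    ``N(mu_phi, sigma_phi^2)``, then the AR(1) recursion is applied.  With
    ``clamp=True`` the log process is hard-truncated to
    ``[log tau_minus, log tau_plus]`` after each step (a sensitivity-check
    variant; the default process is only probabilistically bounded).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    phi = np.empty(n)
    lo = math.log(p.tau_minus)
    hi = math.log(p.tau_plus)
    cur = p.mu_phi + p.sigma_phi * rng.standard_normal()
    if clamp:
        cur = min(max(cur, lo), hi)
    phi[0] = cur
    if n > 1:
        eta = p.mu_eta + p.sigma_eta * rng.standard_normal(n - 1)
        for t in range(1, n):
            cur = p.c * cur + eta[t - 1]
            if clamp:
                cur = min(max(cur, lo), hi)
            phi[t] = cur
    return np.exp(phi)
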