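"""Numba-compiled numeric kernels.

Everything here is a tight per-sample loop: the leaky-integrator filter,
pose integration, batched believed-stop re-integration (the inner loop of
model fitting, executed hundreds of times per fit), the closed-loop
synthetic agent, and the switch-distance controller rollouts.  All kernels
take plain float64 scalars and contiguous arrays; callers own unit handling
and validation.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "lowpass",
    "pose_endpoint",
    "believed_endpoints",
    "agent_loop",
    "switch_rollout",
    "switch_rollout_at_step",
]


@njit(cache=True)
def lowpass(u, alpha, beta, v0):
    """v[t] = alpha*v[t-1] + beta*u[t] starting from v0 (returned v excludes v0)."""
    n = u.shape[0]
    v = np.empty(n)
    prev = v0
    for t in range(n):
        prev = alpha * prev + beta * u[t]
        v[t] = prev
    return v


@njit(cache=True)
def pose_endpoint(v, w, dt):
    """Endpoint (x, y, heading) of midpoint-heading unicycle integration."""
    x = 0.0
    y = 0.0
    h = 0.0
    for t in range(v.shape[0]):
        hm = h + 0.5 * w[t] * dt
        x += v[t] * math.cos(hm) * dt
        y += v[t] * math.sin(hm) * dt
        h += w[t] * dt
    return x, y, h


@njit(cache=True)
def believed_endpoints(uv, uw, lengths, alpha, beta_v, beta_w, dt):
    """Stop positions implied by re-integrating joystick traces under new dynamics.

    ``uv``/``uw`` are zero-padded (n_trials, max_len) input arrays with valid
    lengths in ``lengths``; ``alpha``/``beta_v``/``beta_w`` are per-trial
    filter coefficients.  Returns per-trial endpoint coordinates.
    """
    n = uv.shape[0]
    xs = np.empty(n)
    ys = np.empty(n)
    for i in range(n):
        a = alpha[i]
        bv = beta_v[i]
        bw = beta_w[i]
        v = 0.0
        w = 0.0
        x = 0.0
        y = 0.0
        h = 0.0
        for t in range(lengths[i]):
            v = a * v + bv * uv[i, t]
            w = a * w + bw * uw[i, t]
            hm = h + 0.5 * w * dt
            x += v * math.cos(hm) * dt
            y += v * math.sin(hm) * dt
            h += w * dt
        xs[i] = x
        ys[i] = y
    return xs, ys


@njit(cache=True)
def agent_loop(
    gx,
    gy,
    a_true,
    bv_true,
    bw_true,
    a_bel,
    bv_bel,
    bw_bel,
    vmax_bel,
    wmax_bel,
    tau_bel,
    k_ang,
    k_damp,
    v_stop,
    dt,
    noise_v,
    noise_w,
):
    """Closed-loop steering of the synthetic agent toward goal (gx, gy).

    The agent integrates its own (noisy) joystick output under its believed
    dynamics (a_bel, ...) while the world integrates the same output under
    the true dynamics (a_true, ...).  Linear policy: the agent first turns
    toward the goal (forward input zero while the bearing error exceeds
    0.1 rad and the goal is more than 0.5 m away, cos^2-gated otherwise,
    zero whenever the goal is behind); it switches to full braking when the
    believed distance to goal drops below the believed full-brake stopping
    distance
    tau_bel*(v - vmax_bel*log(1 + v/vmax_bel)), below a 0.05 m arrival
    radius, or when the believed distance starts growing within 0.25 m of
    the goal (a pass-by guard); braking holds until the believed speed falls
    below v_stop, then the input is zero.  Angular policy: proportional
    control on the believed bearing error with gain k_ang, damped by the
    believed turn rate (-k_damp * w / wmax_bel, with the damping gain
    supplied by the caller) so that heading does not ring under
    acceleration-like dynamics.  Gaussian motor noise (pre-drawn in
    noise_v/noise_w, whose length sets the hard timeout) is added before
    clipping to [-1, 1].

    Returns (u_v, u_w, n_used, timed_out); only the first n_used samples of
    the input arrays are meaningful.
    """
    n_max = noise_v.shape[0]
    uv = np.zeros(n_max)
    uw = np.zeros(n_max)
    av = 0.0
    aw = 0.0
    ax = 0.0
    ay = 0.0
    ah = 0.0
    bv = 0.0
    bw = 0.0
    bx = 0.0
    by = 0.0
    bh = 0.0
    phase = 0  # 0 forward, 1 braking, 2 believed-stopped
    n_used = n_max
    timed_out = True
    prev_dist = 1e30
    for t in range(n_max):
        dx = gx - bx
        dy = gy - by
        dist = math.sqrt(dx * dx + dy * dy)
        berr = math.atan2(dy, dx) - bh
        while berr > math.pi:
            berr -= 2.0 * math.pi
        while berr < -math.pi:
            berr += 2.0 * math.pi
        ucw = k_ang * berr - k_damp * bw / wmax_bel
        if ucw > 1.0:
            ucw = 1.0
        elif ucw < -1.0:
            ucw = -1.0
        if phase == 0:
            brake = 0.0
            if bv > 0.0:
                brake = tau_bel * (bv - vmax_bel * math.log(1.0 + bv / vmax_bel))
            if dist <= brake or dist < 0.05 or (dist < 0.25 and dist > prev_dist):
                phase = 1
                ucv = -1.0
            else:
                # align before committing to speed; near the goal small
                # angular errors are unavoidable, so only gate smoothly there
                ca = math.cos(berr)
                if ca <= 0.0 or (dist > 0.5 and abs(berr) > 0.1):
                    ucv = 0.0
                else:
                    ucv = ca * ca
        elif phase == 1:
            if bv <= v_stop:
                phase = 2
                ucv = 0.0
            else:
                ucv = -1.0
        else:
            ucv = 0.0
        u_v = ucv + noise_v[t]
        if u_v > 1.0:
            u_v = 1.0
        elif u_v < -1.0:
            u_v = -1.0
        u_w = ucw + noise_w[t]
        if u_w > 1.0:
            u_w = 1.0
        elif u_w < -1.0:
            u_w = -1.0
        uv[t] = u_v
        uw[t] = u_w
        # believed state update
        bv = a_bel * bv + bv_bel * u_v
        bw = a_bel * bw + bw_bel * u_w
        hm = bh + 0.5 * bw * dt
        bx += bv * math.cos(hm) * dt
        by += bv * math.sin(hm) * dt
        bh += bw * dt
        # true state update
        av = a_true * av + bv_true * u_v
        aw = a_true * aw + bw_true * u_w
        hm = ah + 0.5 * aw * dt
        ax += av * math.cos(hm) * dt
        ay += av * math.sin(hm) * dt
        ah += aw * dt
        prev_dist = dist
        if phase == 2 and abs(av) < v_stop:
            n_used = t + 1
            timed_out = False
            break
    return uv, uw, n_used, timed_out


@njit(cache=True)
def switch_rollout(uw, alpha, beta_v, beta_w, gx, gy, d_switch, v_stop, dt, n_max):
    """Stop position of the switch-distance controller on one trial.

    Keeps the recorded angular input ``uw`` (zero beyond its padded length),
    applies full forward linear input until the Euclidean distance to
    (gx, gy) first drops below ``d_switch``, then full braking until the
    speed falls below ``v_stop``.  If the rollout never reaches the switch
    distance, the closest approach is returned and the trial flagged.

    Returns (x_stop, y_stop, reached_switch).
    """
    v = 0.0
    w = 0.0
    x = 0.0
    y = 0.0
    h = 0.0
    phase = 0
    best_d = 1e30
    best_x = 0.0
    best_y = 0.0
    for t in range(n_max):
        dx = gx - x
        dy = gy - y
        d = math.sqrt(dx * dx + dy * dy)
        if d < best_d:
            best_d = d
            best_x = x
            best_y = y
        if phase == 0 and d <= d_switch:
            phase = 1
        if phase == 0:
            ucv = 1.0
        elif phase == 1:
            if v <= v_stop:
                return x, y, True
            ucv = -1.0
        u_w = uw[t] if t < uw.shape[0] else 0.0
        v = alpha * v + beta_v * ucv
        w = alpha * w + beta_w * u_w
        hm = h + 0.5 * w * dt
        x += v * math.cos(hm) * dt
        y += v * math.sin(hm) * dt
        h += w * dt
    if phase == 1:
        return x, y, True
    return best_x, best_y, False


@njit(cache=True)
def switch_rollout_at_step(uw, alpha, beta_v, beta_w, k_switch, v_stop, dt, n_max):
    """Stop position when braking starts at a fixed sample index ``k_switch``.

    Also returns the distance-from-start at the switch sample, used to map
    switch steps back to switch distances.
    """
    v = 0.0
    w = 0.0
    x = 0.0
    y = 0.0
    h = 0.0
    sx = 0.0
    sy = 0.0
    for t in range(n_max):
        if t < k_switch:
            ucv = 1.0
        else:
            if t == k_switch:
                sx = x
                sy = y
            if v <= v_stop:
                return x, y, sx, sy
            ucv = -1.0
        u_w = uw[t] if t < uw.shape[0] else 0.0
        v = alpha * v + beta_v * ucv
        w = alpha * w + beta_w * u_w
        hm = h + 0.5 * w * dt
        x += v * math.cos(hm) * dt
        y += v * math.sin(hm) * dt
        h += w * dt
    return x, y, sx, sy
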