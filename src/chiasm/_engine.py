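"""Vectorized closed-loop simulation kernels (numba).

Two kernels share the same inner update, differing only in what they emit:

* :func:`batch_summaries` — runs a batch of independent trials and returns
  post-warmup accumulators (squared errors, motor statistics, mean absolute
  activities, mismatch/alignment counters).  Used by the scan engine, where
  storing full traces for millions of trials would be wasteful.
* :func:`batch_traces` — same dynamics, but records the full per-step trace
  (node activities, targets, body positions, errors, sensory drives).  Used
  by :func:`chiasm.task.run_trial` and the mechanism analysis.

All stochastic inputs (target sign series, node noise, process noise) are
pre-generated by the caller, which makes the closed loop a deterministic
function of its input arrays and allows exact sharing of task realizations
across candidate architectures and noise levels.

Trial layout: weight matrices are indexed ``W[trial, target, source]``; the
short-delay matrix collects every link with delay ``d_short`` and the
long-delay matrix the excitatory commissural links with delay ``d_long``
(per-trial).  Within a step: the tracking error is computed from the current
body position, split into rectified left/right drives by the twist blend,
the network advances synchronously from its delayed history, and the body
then moves under the just-computed motor activities.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Accumulator column layout of batch_summaries' first output.
ACC_E2X, ACC_E2Y, ACC_M2, ACC_ASYM, ACC_MISMATCH, ACC_ALIGN = range(6)
N_ACC = 6

# Sensory drive modes.
DRIVE_TWIST = 0   # rectified left/right split blended by the twist parameter
DRIVE_COMMON = 1  # laterality-neutral broadcast: u_L = u_R = e_x / 2


@njit(cache=True)
def _twist_drive(ex, theta):
    """Rectified left/right sensory drives for error ``ex`` at twist ``theta``.

    u_L = (1-theta)*max(-ex,0) + theta*max(ex,0)
    u_R = (1-theta)*max(ex,0)  + theta*max(-ex,0)
    """
    if ex >= 0.0:
        return theta * ex, (1.0 - theta) * ex
    return (1.0 - theta) * (-ex), theta * (-ex)


@njit(cache=True)
def batch_summaries(
    w_short, w_long, d_long, theta, tx, ty, nn, px, py,
    g, k_move, k_y, warmup, two_d, drive_mode,
):
    """Run ``B`` independent trials; return post-warmup accumulators.

    Parameters are arrays over trials: ``w_short``/``w_long`` are
    ``(B, 6, 6)``, ``d_long`` ``(B,)`` int64, ``theta`` ``(B,)``, ``tx``/
    ``px`` (and ``ty``/``py`` when ``two_d``) are ``(B, T)`` and ``nn`` is
    ``(B, T, 6)`` noise already scaled to its standard deviation.

    Returns ``(acc, absx)``: ``acc`` is ``(B, 6)`` with post-warmup sums of
    [e_x^2, e_y^2, m_L^2 + m_R^2, (m_L - m_R)^2, |e_x - u_x|,
    aligned-step count] and ``absx`` is ``(B, 6)`` post-warmup sums of
    ``|x_j(t)|`` per node.
    """
    B, T = tx.shape
    maxd = 1
    for b in range(B):
        if d_long[b] > maxd:
            maxd = d_long[b]
    D = maxd + 2  # ring depth: strictly more than the largest delay
    acc = np.zeros((B, N_ACC))
    absx = np.zeros((B, 6))
    for b in range(B):
        hist = np.zeros((6, D))
        new = np.zeros(6)
        xb = 0.0
        yb = 0.0
        dl = d_long[b]
        th = theta[b]
        for t in range(T):
            ex = tx[b, t] - xb
            if drive_mode == DRIVE_TWIST:
                u_l, u_r = _twist_drive(ex, th)
            else:
                u_l = 0.5 * ex
                u_r = 0.5 * ex
            s1 = (t - 1) % D
            s2 = (t - dl) % D
            for i in range(6):
                net = nn[b, t, i]
                for j in range(6):
                    net += w_short[b, i, j] * hist[j, s1]
                    net += w_long[b, i, j] * hist[j, s2]
                if i == 0:
                    net += u_l
                elif i == 1:
                    net += u_r
                new[i] = np.tanh(g * net)
            cur = t % D
            for i in range(6):
                hist[i, cur] = new[i]
            m_l = new[4]
            m_r = new[5]
            if t >= warmup:
                ux = m_r - m_l
                acc[b, ACC_E2X] += ex * ex
                acc[b, ACC_M2] += m_l * m_l + m_r * m_r
                acc[b, ACC_ASYM] += (m_l - m_r) * (m_l - m_r)
                acc[b, ACC_MISMATCH] += abs(ex - ux)
                if (ex > 0.0 and ux > 0.0) or (ex < 0.0 and ux < 0.0):
                    acc[b, ACC_ALIGN] += 1.0
                for i in range(6):
                    absx[b, i] += abs(new[i])
            xb = xb + k_move * (m_r - m_l) + px[b, t]
            if two_d:
                ey = ty[b, t] - yb
                if t >= warmup:
                    acc[b, ACC_E2Y] += ey * ey
                yb = yb + k_y * ey + py[b, t]
    return acc, absx


@njit(cache=True)
def batch_traces(
    w_short, w_long, d_long, theta, tx, ty, nn, px, py,
    g, k_move, k_y, two_d, drive_mode,
):
    """Identical dynamics to :func:`batch_summaries`, recording full traces.

    Returns ``(nodes, body_x, body_y, u_lr)`` where ``nodes`` is
    ``(B, T, 6)`` activities, ``body_x``/``body_y`` are ``(B, T)`` body
    positions *before* the step's motor update (so that
    ``e(t) = target(t) - body(t)`` holds row-wise) and ``u_lr`` is
    ``(B, T, 2)`` sensory drives.
    """
    B, T = tx.shape
    maxd = 1
    for b in range(B):
        if d_long[b] > maxd:
            maxd = d_long[b]
    D = maxd + 2
    nodes = np.zeros((B, T, 6))
    body_x = np.zeros((B, T))
    body_y = np.zeros((B, T))
    u_lr = np.zeros((B, T, 2))
    for b in range(B):
        hist = np.zeros((6, D))
        new = np.zeros(6)
        xb = 0.0
        yb = 0.0
        dl = d_long[b]
        th = theta[b]
        for t in range(T):
            body_x[b, t] = xb
            body_y[b, t] = yb
            ex = tx[b, t] - xb
            if drive_mode == DRIVE_TWIST:
                u_l, u_r = _twist_drive(ex, th)
            else:
                u_l = 0.5 * ex
                u_r = 0.5 * ex
            u_lr[b, t, 0] = u_l
            u_lr[b, t, 1] = u_r
            s1 = (t - 1) % D
            s2 = (t - dl) % D
            for i in range(6):
                net = nn[b, t, i]
                for j in range(6):
                    net += w_short[b, i, j] * hist[j, s1]
                    net += w_long[b, i, j] * hist[j, s2]
                if i == 0:
                    net += u_l
                elif i == 1:
                    net += u_r
                new[i] = np.tanh(g * net)
            cur = t % D
            for i in range(6):
                hist[i, cur] = new[i]
                nodes[b, t, i] = new[i]
            m_l = new[4]
            m_r = new[5]
            xb = xb + k_move * (m_r - m_l) + px[b, t]
            if two_d:
                ey = ty[b, t] - yb
                yb = yb + k_y * ey + py[b, t]
    return nodes, body_x, body_y, u_lr
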