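"""Compiled inner loops for the simulation engine.

A full simulated subject experiences roughly 4.6e5 timesteps (two 12-session
phases whose sessions each end with an 18,000-timestep home-cage interval),
and experiments run 40-80 subjects, so the per-timestep arithmetic is
implemented here as numba-compiled loops over raw arrays.  The math is
identical to the reference operations in :mod:`avoidsim.model`; the test
suite drives both paths with the same uniform variates and requires the
trajectories to agree.

All functions mutate the weight arrays ``m`` (n_actions x n_channels),
``c`` (n_actions) and ``v`` (n_channels) in place and thread the previous
state value ``V_prev`` through their return values.  One uniform variate is
consumed per executed timestep, read sequentially from a pre-drawn array.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Channel indices (order fixed by avoidsim.model.CHANNELS).
WARNING, SHOCK, ITI_SIGNAL, TEST_CTX, HOME_CTX, NOVEL_CTX = range(6)

# Response-class codes used by the trial runner.
RESP_AVOID, RESP_ESCAPE, RESP_NONE = 0, 1, 2


@njit(cache=False)
def _select_action(m, c, inputs, T, P, press_allowed, u):
    """Softmax action selection (max-subtracted) via inverse-CDF on ``u``."""
    n = m.shape[0]
    start = 0 if press_allowed else 1
    # action values M_a = sum_i m_ai * I_i + c_a * P
    M = np.empty(n)
    for a in range(n):
        acc = c[a] * P
        for i in range(6):
            if inputs[i] != 0.0:
                acc += m[a, i]
        M[a] = acc / T
    mx = M[start]
    for a in range(start + 1, n):
        if M[a] > mx:
            mx = M[a]
    Z = 0.0
    for a in range(start, n):
        M[a] = np.exp(M[a] - mx)
        Z += M[a]
    threshold = u * Z
    acc = 0.0
    chosen = n - 1
    for a in range(start, n):
        acc += M[a]
        if threshold < acc:
            chosen = a
            break
    return chosen


@njit(cache=False)
def _learn(m, c, v, V_prev, chosen, was_press, inputs_now, inputs_next, shock_next,
           P, gamma, alpha, eps, R_shock, R_press, decay, v_bound):
    """Trace update, reinforcement, TD error and weight updates for one step."""
    n = m.shape[0]
    for a in range(n):
        c[a] *= decay
    c[chosen] = 1.0

    if shock_next:
        R = R_shock
    elif was_press:
        R = R_press
    else:
        R = 0.0

    V_new = 0.0
    for i in range(6):
        if inputs_next[i] != 0.0:
            V_new += v[i]
    PE = R + gamma * V_new - V_prev

    for i in range(6):
        if inputs_now[i] != 0.0:
            v[i] += alpha * PE
            if v[i] > v_bound:
                v[i] = v_bound
            elif v[i] < -v_bound:
                v[i] = -v_bound
            mi = m[chosen, i] + eps * (PE - m[chosen, i])
            m[chosen, i] = mi if mi > 0.0 else 0.0
    return V_new


@njit(cache=False)
def run_const_segment(m, c, v, V_prev, inputs, next_inputs, u, press_allowed,
                      T, P, gamma, alpha, eps, R_shock, R_press, decay, v_bound):
    """Run ``len(u)`` steps under constant inputs (pre-session / home cage).

    The final step transitions to ``next_inputs``.  Returns the updated
    ``V_prev`` and the number of lever presses emitted.
    """
    n_steps = u.shape[0]
    presses = 0
    for k in range(n_steps):
        chosen = _select_action(m, c, inputs, T, P, press_allowed, u[k])
        was_press = press_allowed and chosen == 0
        if was_press:
            presses += 1
        nxt = inputs if k < n_steps - 1 else next_inputs
        V_prev = _learn(m, c, v, V_prev, chosen, was_press, inputs, nxt, False,
                        P, gamma, alpha, eps, R_shock, R_press, decay, v_bound)
    return V_prev, presses


@njit(cache=False)
def run_trial(m, c, v, V_prev, u, next_inputs,
              warning_len, shock_len, iti_len, shock_on, signal_on,
              sig_lo, sig_hi, ctx_idx, lever_in_iti,
              T, P, gamma, alpha, eps, R_shock, R_press, decay, v_bound,
              itr_out):
    """Simulate one trial: warning -> (shock) -> fixed-length ITI.

    A lever press during the warning or shock period terminates both stimuli
    immediately and starts the ITI (avoidance if within the warning period,
    escape if during shock).  With no press the trial runs its full course
    and latency is scored at the trial maximum.  ITI presses are recorded
    per ITI timestep in ``itr_out`` (length ``iti_len``); when
    ``lever_in_iti`` is false the press action is excluded from the softmax.

    Returns ``(latency, response_code, shocks_received, V_prev)``.
    """
    inputs_now = np.zeros(6)
    inputs_next = np.zeros(6)
    total_pre = warning_len + shock_len
    max_len = total_pre + iti_len
    latency = max_len
    resp = RESP_NONE
    shocks = 0
    t = 0  # index into u

    # --- warning and shock periods -------------------------------------
    for s in range(1, total_pre + 1):
        in_shock = s > warning_len
        inputs_now[:] = 0.0
        inputs_now[WARNING] = 1.0
        inputs_now[ctx_idx] = 1.0
        if in_shock and shock_on:
            inputs_now[SHOCK] = 1.0
            shocks += 1
        chosen = _select_action(m, c, inputs_now, T, P, True, u[t])
        t += 1
        was_press = chosen == 0
        if was_press:
            latency = s
            resp = RESP_AVOID if s <= warning_len else RESP_ESCAPE
            # immediate termination of warning and shock; ITI begins
            _iti_inputs(inputs_next, 1, iti_len, signal_on, sig_lo, sig_hi, ctx_idx)
            shock_next = False
        else:
            if s < total_pre:
                inputs_next[:] = 0.0
                inputs_next[WARNING] = 1.0
                inputs_next[ctx_idx] = 1.0
                shock_next = shock_on and (s + 1) > warning_len
                if shock_next:
                    inputs_next[SHOCK] = 1.0
            else:
                _iti_inputs(inputs_next, 1, iti_len, signal_on, sig_lo, sig_hi, ctx_idx)
                shock_next = False
        V_prev = _learn(m, c, v, V_prev, chosen, was_press, inputs_now, inputs_next,
                        shock_next, P, gamma, alpha, eps, R_shock, R_press, decay, v_bound)
        if was_press:
            break

    # --- inter-trial interval ------------------------------------------
    for j in range(1, iti_len + 1):
        _iti_inputs(inputs_now, j, iti_len, signal_on, sig_lo, sig_hi, ctx_idx)
        chosen = _select_action(m, c, inputs_now, T, P, lever_in_iti, u[t])
        t += 1
        was_press = lever_in_iti and chosen == 0
        if was_press:
            itr_out[j - 1] = 1
        if j < iti_len:
            _iti_inputs(inputs_next, j + 1, iti_len, signal_on, sig_lo, sig_hi, ctx_idx)
        else:
            inputs_next[:] = next_inputs
        V_prev = _learn(m, c, v, V_prev, chosen, was_press, inputs_now, inputs_next,
                        False, P, gamma, alpha, eps, R_shock, R_press, decay, v_bound)

    return latency, resp, shocks, V_prev


@njit(cache=False)
def _iti_inputs(out, j, iti_len, signal_on, sig_lo, sig_hi, ctx_idx):
    """Stimulus vector for ITI timestep ``j`` (1-based)."""
    out[:] = 0.0
    out[ctx_idx] = 1.0
    if signal_on and sig_lo <= j <= sig_hi:
        out[ITI_SIGNAL] = 1.0
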