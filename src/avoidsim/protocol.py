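"""Behavioral protocol engine for discriminated lever-press avoidance.

The protocol mirrors a standard rodent escape-avoidance preparation.  Each
trial opens with a 6-timestep warning tone (1 timestep = 10 s); unless the
subject presses the lever, shock follows for up to 30 timesteps with the
warning still on.  A press at any point during warning or shock terminates
both stimuli immediately (scored as avoidance or escape respectively) and
starts a fixed-length safe inter-trial interval (ITI) that, in signalled
conditions, is marked by an ITI signal.  Sessions hold 20 trials, open with
a 6-timestep stimulus-free period in the test context, and are separated by
an 18,000-timestep interval in which only the home-context input is active.
An acquisition phase (shock on) is followed by an extinction phase
(shock and, unless configured otherwise, the ITI signal never presented).

Lever presses during the ITI are scored as inter-trial responses (ITRs),
counted in three equal ITI segments.  Latency to press is recorded per
trial; trials without a press score the trial maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from . import kernel
from .model import (
    CHANNELS,
    N_CHANNELS,
    PRESS_ACTION,
    Agent,
    ConfigurationError,
    ModelParams,
    model_step,
)

__all__ = [
    "ProtocolConfig",
    "TrialRecord",
    "SimulationRun",
    "PHASES",
    "sex_params",
    "build_inputs",
    "run_trial",
    "run_presession",
    "run_intersession",
    "run_simulation",
]

PHASES = ("acquisition", "extinction")

_W = CHANNELS.index("warning")
_SH = CHANNELS.index("shock")
_SIG = CHANNELS.index("iti_signal")
_TEST = CHANNELS.index("test_context")
_HOME = CHANNELS.index("home_context")
_NOVEL = CHANNELS.index("novel_context")

_RESP_NAMES = ("avoidance", "escape", "none")


@dataclass(frozen=True)
class ProtocolConfig:
    """Timeline parameters and phase flags of one protocol variant."""

    timestep_seconds: float = 10.0
    sessions_per_phase: int = 12
    trials_per_session: int = 20
    warning_len: int = 6
    shock_len_max: int = 30
    iti_len: int = 18
    presession_len: int = 6
    intersession_len: int = 18_000
    shock_on: bool = True                 # shock delivered in acquisition
    signal_in_acquisition: bool = False
    signal_in_extinction: bool = False
    signal_window: Literal["full_iti", "first_3", "last_3"] = "full_iti"
    context_shift_in_extinction: bool = False
    lever_enabled_in_iti: bool = True

    def __post_init__(self) -> None:
        for name in ("sessions_per_phase", "trials_per_session", "warning_len",
                     "shock_len_max", "iti_len", "presession_len", "intersession_len"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.signal_window not in ("full_iti", "first_3", "last_3"):
            raise ConfigurationError(f"unknown signal_window {self.signal_window!r}")
        if self.signal_window != "full_iti" and self.iti_len != 18:
            raise ConfigurationError("windowed ITI signals require the 18-timestep ITI")

    @property
    def max_trial_len(self) -> int:
        """Maximum trial length (54 for the standard protocol)."""
        return self.warning_len + self.shock_len_max + self.iti_len

    def signal_bounds(self) -> tuple[int, int]:
        """Inclusive 1-based ITI-timestep range in which the signal is shown."""
        if self.signal_window == "first_3":
            return 1, 3
        if self.signal_window == "last_3":
            return self.iti_len - 2, self.iti_len
        return 1, self.iti_len

    def phase_settings(self, phase: str) -> tuple[bool, bool, int]:
        """Return (shock active, ITI signal active, context channel) for a phase."""
        if phase == "acquisition":
            return self.shock_on, self.signal_in_acquisition, _TEST
        if phase == "extinction":
            ctx = _NOVEL if self.context_shift_in_extinction else _TEST
            return False, self.signal_in_extinction, ctx
        raise ConfigurationError(f"unknown phase {phase!r}")


@dataclass(frozen=True)
class TrialRecord:
    """Scored outcome of a single trial."""

    phase: str
    session_idx: int          # 1-based within phase
    trial_idx: int            # 1-based within session
    response_class: str       # avoidance | escape | none
    latency: int              # 1-based timestep of first press, else trial max
    itr_segments: tuple[int, int, int]
    shocks_received: int


@dataclass
class SimulationRun:
    """Complete behavioral and weight record of one simulated subject."""

    seed: int
    sex: str | None
    labels: dict
    config: ProtocolConfig
    params: ModelParams
    records: list[TrialRecord]
    #: end-of-trial snapshots, shape (n_trials, 2, n_channels):
    #: axis 1 is (critic weights v, actor press-row weights m).
    weights: np.ndarray

    def trials_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "phase": [r.phase for r in self.records],
                "session": [r.session_idx for r in self.records],
                "trial": [r.trial_idx for r in self.records],
                "response": [r.response_class for r in self.records],
                "latency": [r.latency for r in self.records],
                "itr_seg1": [r.itr_segments[0] for r in self.records],
                "itr_seg2": [r.itr_segments[1] for r in self.records],
                "itr_seg3": [r.itr_segments[2] for r in self.records],
                "shocks": [r.shocks_received for r in self.records],
            }
        )

    def weights_frame(self):
        import pandas as pd

        n_trials = self.weights.shape[0]
        rows = []
        for k, rec in enumerate(self.records):
            for ch_idx, ch in enumerate(CHANNELS):
                rows.append(
                    (rec.phase, rec.session_idx, rec.trial_idx, ch,
                     self.weights[k, 0, ch_idx], self.weights[k, 1, ch_idx])
                )
        assert len(rows) == n_trials * N_CHANNELS
        return pd.DataFrame(
            rows, columns=["phase", "session", "trial", "channel", "v", "m_press"]
        )


def sex_params(sex: str) -> ModelParams:
    """Parameter set for a simulated sex.

    Males and females share every parameter except shock cost (males -4,
    females -8; females are modelled as more shock-sensitive) and the critic
    learning rate alpha (males 0.05, females 0.01; a lower rate preserves
    acquired state values longer, the proposed substrate of greater female
    sensitivity to safety-signal omission).
    """
    if sex == "male":
        return ModelParams(R_shock=-4.0, alpha=0.05)
    if sex == "female":
        return ModelParams(R_shock=-8.0, alpha=0.01)
    raise ConfigurationError(f"unknown sex label {sex!r}; expected 'male' or 'female'")


def build_inputs(
    phase: str, period: str, step: int, config: ProtocolConfig
) -> tuple[np.ndarray, bool]:
    """Stimulus vector and shock flag for one timeline position.

    ``period`` is one of ``presession``, ``warning``, ``shock``, ``iti`` or
    ``intersession``; ``step`` is the 1-based timestep within that period.
    The shock flag reports whether the shock input is active at this
    position (it is also a channel of the returned vector).
    """
    shock_on, signal_on, ctx = config.phase_settings(phase)
    vec = np.zeros(N_CHANNELS)
    if period == "intersession":
        if not 1 <= step <= config.intersession_len:
            raise ConfigurationError("intersession step out of range")
        vec[_HOME] = 1.0
        return vec, False
    if period == "presession":
        if not 1 <= step <= config.presession_len:
            raise ConfigurationError("presession step out of range")
        vec[ctx] = 1.0
        return vec, False
    vec[ctx] = 1.0
    if period == "warning":
        if not 1 <= step <= config.warning_len:
            raise ConfigurationError("warning step out of range")
        vec[_W] = 1.0
        return vec, False
    if period == "shock":
        if not 1 <= step <= config.shock_len_max:
            raise ConfigurationError("shock step out of range")
        vec[_W] = 1.0
        if shock_on:
            vec[_SH] = 1.0
        return vec, bool(shock_on)
    if period == "iti":
        if not 1 <= step <= config.iti_len:
            raise ConfigurationError("ITI step out of range")
        lo, hi = config.signal_bounds()
        if signal_on and lo <= step <= hi:
            vec[_SIG] = 1.0
        return vec, False
    raise ConfigurationError(f"unknown timeline period {period!r}")


def _kernel_params(params: ModelParams) -> tuple:
    # the kernel takes the *effective* per-action perseveration gain
    return (params.T, params.trace_gain, params.gamma, params.alpha,
            params.epsilon_actor, params.R_shock, params.R_press,
            params.trace_decay, params.v_bound)


def _segment_itrs(itr_steps: np.ndarray) -> tuple[int, int, int]:
    """Sum per-timestep ITI presses into three equal segments."""
    parts = np.array_split(itr_steps, 3)
    return tuple(int(p.sum()) for p in parts)


def run_trial(
    agent: Agent,
    config: ProtocolConfig,
    phase: str,
    rng: np.random.Generator | None = None,
    *,
    u: np.ndarray | None = None,
    next_inputs: np.ndarray | None = None,
    session_idx: int = 1,
    trial_idx: int = 1,
    use_kernel: bool = True,
) -> TrialRecord:
    """Run one trial, mutating ``agent`` and returning the scored record.

    One uniform variate is budgeted per possible timestep: ``u`` (or a fresh
    draw from ``rng``) has length ``config.max_trial_len`` and is consumed
    sequentially for the timesteps actually executed.  ``next_inputs`` is
    the stimulus vector of the timestep that follows the trial (defaults to
    the next trial's first warning timestep), needed for the final
    temporal-difference transition.
    """
    if u is None:
        if rng is None:
            raise ConfigurationError("run_trial needs either rng or u")
        u = rng.random(config.max_trial_len)
    if len(u) < config.max_trial_len:
        raise ConfigurationError("uniform array shorter than the maximum trial length")
    shock_on, signal_on, ctx = config.phase_settings(phase)
    if next_inputs is None:
        next_inputs, _ = build_inputs(phase, "warning", 1, config)
    lo, hi = config.signal_bounds()
    itr_steps = np.zeros(config.iti_len, dtype=np.int64)

    if use_kernel:
        latency, resp, shocks, V_prev = kernel.run_trial(
            agent.actor.m, agent.actor.c, agent.critic.v, agent.critic.V_prev,
            np.asarray(u, dtype=float), np.asarray(next_inputs, dtype=float),
            config.warning_len, config.shock_len_max, config.iti_len,
            shock_on, signal_on, lo, hi, ctx, config.lever_enabled_in_iti,
            *_kernel_params(agent.params), itr_steps,
        )
        agent.critic.V_prev = V_prev
    else:
        latency, resp, shocks = _run_trial_py(
            agent, config, phase, u, np.asarray(next_inputs, dtype=float), itr_steps
        )
    return TrialRecord(
        phase=phase,
        session_idx=session_idx,
        trial_idx=trial_idx,
        response_class=_RESP_NAMES[resp],
        latency=int(latency),
        itr_segments=_segment_itrs(itr_steps),
        shocks_received=int(shocks),
    )


def _run_trial_py(agent, config, phase, u, next_inputs, itr_steps):
    """Pure-Python trial runner built from the reference model operations.

    Mirrors :func:`avoidsim.kernel.run_trial` step for step; kept as the
    readable specification of the trial timeline and as the oracle for the
    compiled path.
    """
    shock_on, signal_on, ctx = config.phase_settings(phase)
    total_pre = config.warning_len + config.shock_len_max
    latency, resp, shocks = config.max_trial_len, kernel.RESP_NONE, 0
    t = 0

    def pre_inputs(s):
        if s <= config.warning_len:
            return build_inputs(phase, "warning", s, config)
        return build_inputs(phase, "shock", s - config.warning_len, config)

    def iti_inputs(j):
        return build_inputs(phase, "iti", j, config)[0]

    pressed = False
    for s in range(1, total_pre + 1):
        inputs_now, shock_now = pre_inputs(s)
        if shock_now:
            shocks += 1

        def successor(chosen, s=s):
            if chosen == PRESS_ACTION:
                return iti_inputs(1), False
            if s < total_pre:
                return pre_inputs(s + 1)
            return iti_inputs(1), False

        result = model_step(agent, inputs_now, successor, u=u[t])
        t += 1
        if result.was_press:
            latency = s
            resp = kernel.RESP_AVOID if s <= config.warning_len else kernel.RESP_ESCAPE
            pressed = True
            break

    for j in range(1, config.iti_len + 1):
        inputs_now = iti_inputs(j)
        nxt = iti_inputs(j + 1) if j < config.iti_len else next_inputs
        result = model_step(
            agent, inputs_now, (nxt, False), u=u[t],
            press_allowed=config.lever_enabled_in_iti,
        )
        t += 1
        if result.was_press:
            itr_steps[j - 1] = 1
    return latency, resp, shocks


def _run_const(agent, inputs, next_inputs, u, use_kernel=True, press_allowed=True):
    """Run a constant-input segment (pre-session or home-cage interval)."""
    inputs = np.asarray(inputs, dtype=float)
    next_inputs = np.asarray(next_inputs, dtype=float)
    if use_kernel:
        V_prev, presses = kernel.run_const_segment(
            agent.actor.m, agent.actor.c, agent.critic.v, agent.critic.V_prev,
            inputs, next_inputs, np.asarray(u, dtype=float), press_allowed,
            *_kernel_params(agent.params),
        )
        agent.critic.V_prev = V_prev
        return presses
    presses = 0
    n = len(u)
    for k in range(n):
        nxt = inputs if k < n - 1 else next_inputs
        result = model_step(agent, inputs, (nxt, False), u=u[k], press_allowed=press_allowed)
        presses += result.was_press
    return presses


def run_presession(agent, config, phase, rng=None, *, u=None, next_inputs=None,
                   use_kernel=True):
    """Run the stimulus-free period that opens a session (context only)."""
    if u is None:
        u = rng.random(config.presession_len)
    inputs, _ = build_inputs(phase, "presession", 1, config)
    if next_inputs is None:
        next_inputs, _ = build_inputs(phase, "warning", 1, config)
    return _run_const(agent, inputs, next_inputs, u, use_kernel=use_kernel)


def run_intersession(agent, config, rng=None, *, u=None, next_inputs=None,
                     phase: str = "acquisition", use_kernel=True):
    """Run the home-cage interval that follows a session.

    Only the home-context input is active; the full action set (including
    the lever press, at its usual energy cost) remains available.
    ``next_inputs`` defaults to the pre-session context of the next session.
    """
    if u is None:
        u = rng.random(config.intersession_len)
    inputs = np.zeros(N_CHANNELS)
    inputs[_HOME] = 1.0
    if next_inputs is None:
        next_inputs, _ = build_inputs(phase, "presession", 1, config)
    return _run_const(agent, inputs, next_inputs, u, use_kernel=use_kernel)


def run_simulation(
    sex: str | None,
    config: ProtocolConfig,
    seed: int,
    *,
    params: ModelParams | None = None,
    labels: dict | None = None,
    use_kernel: bool = True,
) -> SimulationRun:
    """Run one subject through acquisition followed by extinction.

    ``sex`` selects the parameter set via :func:`sex_params`; pass
    ``params`` to override it (e.g. for single-parameter grids).  The whole
    run is one continuous timestep stream: the critic's previous state value
    carries across every trial, session and phase boundary, and weights are
    snapshotted at the end of every trial.
    """
    if params is None:
        if sex is None:
            raise ConfigurationError("run_simulation needs a sex label or explicit params")
        params = sex_params(sex)
    rng = np.random.default_rng(seed)
    agent = Agent.fresh(params)
    records: list[TrialRecord] = []
    n_trials_total = 2 * config.sessions_per_phase * config.trials_per_session
    weights = np.zeros((n_trials_total, 2, N_CHANNELS))

    k = 0
    for p_idx, phase in enumerate(PHASES):
        for session in range(1, config.sessions_per_phase + 1):
            run_presession(agent, config, phase, u=rng.random(config.presession_len),
                           use_kernel=use_kernel)
            for trial in range(1, config.trials_per_session + 1):
                if trial < config.trials_per_session:
                    nxt, _ = build_inputs(phase, "warning", 1, config)
                else:
                    nxt = np.zeros(N_CHANNELS)
                    nxt[_HOME] = 1.0
                rec = run_trial(
                    agent, config, phase,
                    u=rng.random(config.max_trial_len), next_inputs=nxt,
                    session_idx=session, trial_idx=trial, use_kernel=use_kernel,
                )
                records.append(rec)
                weights[k, 0] = agent.critic.v
                weights[k, 1] = agent.actor.m[PRESS_ACTION]
                k += 1
            last_overall = phase == PHASES[-1] and session == config.sessions_per_phase
            if last_overall:
                nxt = np.zeros(N_CHANNELS)
                nxt[_HOME] = 1.0
            else:
                next_phase = phase if session < config.sessions_per_phase else PHASES[p_idx + 1]
                nxt, _ = build_inputs(next_phase, "presession", 1, config)
            run_intersession(agent, config, u=rng.random(config.intersession_len),
                             next_inputs=nxt, use_kernel=use_kernel)
    return SimulationRun(
        seed=seed, sex=sex, labels=dict(labels or {}), config=config,
        params=params, records=records, weights=weights,
    )
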