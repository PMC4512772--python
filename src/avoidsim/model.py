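"""Actor-critic temporal-difference learning agent.

The agent couples a linear *critic*, which assigns a scalar value
``V = sum_i v_i I_i`` to the current stimulus configuration, with an *actor*
that maps the same binary stimulus vector onto a softmax policy over 100
candidate actions (action 0 is the lever press; the rest stand for arbitrary
behaviors such as rearing or grooming).  On every 10-s timestep the actor
samples an action, the environment delivers reinforcement ``R`` (shock, a
small lever-press energy cost, or nothing), and the critic emits the
temporal-difference prediction error

    PE = R + gamma * V(next state) - V(previous state)

which drives both the critic weights (``dv_i = alpha * PE * I_i``, bounded by
the shock magnitude) and the actor weights of the chosen action
(``dm_ri = epsilon * (PE - m_ri) * I_i``, floored at zero).  A decaying
per-action perseveration trace ``c`` biases the policy toward recently
emitted actions via the bonus ``c_a * P`` in the action values.

Everything here is deliberately small and explicit; the batched simulation
engine in :mod:`avoidsim.kernel` implements the identical arithmetic for
speed, and the test-suite holds the two paths to agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CHANNELS",
    "N_CHANNELS",
    "PRESS_ACTION",
    "ModelParams",
    "ActorState",
    "CriticState",
    "Agent",
    "StepResult",
    "ConfigurationError",
    "make_inputs",
    "validate_inputs",
    "action_values",
    "action_probabilities",
    "sample_action",
    "update_trace",
    "external_reinforcement",
    "state_value",
    "prediction_error",
    "update_critic",
    "update_actor",
    "model_step",
]

#: Named binary stimulus channels, in fixed order.  ``warning`` precedes and
#: accompanies shock; ``iti_signal`` marks (part of) the safe inter-trial
#: interval; exactly one context channel is active at any time.
CHANNELS = ("warning", "shock", "iti_signal", "test_context", "home_context", "novel_context")
N_CHANNELS = len(CHANNELS)

#: Index of the lever-press action within the actor's action set.
PRESS_ACTION = 0


class ConfigurationError(ValueError):
    """Raised for invalid parameters, inputs, or mismatched dimensions."""


@dataclass(frozen=True)
class ModelParams:
    """All scalar free parameters of the actor and critic.

    Defaults are the values used for every simulated group; only
    ``R_shock`` (shock cost) and ``alpha`` (critic learning rate) vary
    between the simulated sexes (see :func:`avoidsim.protocol.sex_params`).
    """

    n_actions: int = 100
    T: float = 1.0            # softmax temperature (explore/exploit)
    P: float = 0.25           # perseveration gain
    gamma: float = 0.9        # temporal discount factor
    alpha: float = 0.05       # critic learning rate
    epsilon_actor: float = 0.005  # actor learning rate
    R_shock: float = -4.0     # shock reinforcement (negative)
    R_press: float = -0.2     # lever-press energy cost (negative)
    trace_decay: float = 0.95  # perseveration-trace decay per timestep
    m_init: float = 0.01      # initial actor weight value
    #: How the perseveration term enters the action values.  "summed" reads
    #: the value equation with the trace term inside the sum over input
    #: slots; with the row-uniform trace update this is a per-action bonus
    #: of ``n_channels * P * c_a``.  "per_action" adds the bonus once
    #: (``P * c_a``).  The summed form is the default: it produces the
    #: marked decline of inter-trial responding across the safe interval and
    #: the session-start warm-up seen in the behavior being modelled.
    trace_mode: str = "summed"

    def __post_init__(self) -> None:
        if self.n_actions < 1:
            raise ConfigurationError("n_actions must be positive")
        if not self.T > 0:
            raise ConfigurationError("softmax temperature T must be > 0")
        if not 0.0 <= self.gamma <= 1.0:
            raise ConfigurationError("gamma must lie in [0, 1]")
        if not self.alpha > 0:
            raise ConfigurationError("alpha must be > 0")
        if not self.epsilon_actor > 0:
            raise ConfigurationError("epsilon_actor must be > 0")
        if not 0.0 < self.trace_decay < 1.0:
            raise ConfigurationError("trace_decay must lie in (0, 1)")
        if not self.R_shock < self.R_press < 0:
            raise ConfigurationError("require R_shock < R_press < 0")
        if self.trace_mode not in ("summed", "per_action"):
            raise ConfigurationError("trace_mode must be 'summed' or 'per_action'")

    @property
    def v_bound(self) -> float:
        """Magnitude bound on critic weights: |R_shock|."""
        return abs(self.R_shock)

    @property
    def trace_gain(self) -> float:
        """Effective per-action perseveration gain (see ``trace_mode``)."""
        return self.P * (N_CHANNELS if self.trace_mode == "summed" else 1.0)


def make_inputs(**active: int) -> np.ndarray:
    """Build a binary stimulus vector from channel names.

    >>> make_inputs(warning=1, test_context=1)
    array([1., 0., 0., 1., 0., 0.])
    """
    vec = np.zeros(N_CHANNELS)
    for name, value in active.items():
        if name not in CHANNELS:
            raise ConfigurationError(f"unknown stimulus channel {name!r}")
        vec[CHANNELS.index(name)] = float(value)
    validate_inputs(vec)
    return vec


def validate_inputs(inputs: np.ndarray) -> None:
    """Check that ``inputs`` is a valid binary stimulus vector.

    The home context represents the animal removed from the apparatus, so it
    is never co-active with any other channel.
    """
    inputs = np.asarray(inputs)
    if inputs.shape != (N_CHANNELS,):
        raise ConfigurationError(
            f"input vector must have {N_CHANNELS} channels, got shape {inputs.shape}"
        )
    if not np.all(np.isin(inputs, (0.0, 1.0))):
        raise ConfigurationError("stimulus activations must be binary 0/1")
    home = inputs[CHANNELS.index("home_context")]
    if home == 1.0 and inputs.sum() > 1.0:
        raise ConfigurationError("home context must be presented alone")


@dataclass
class ActorState:
    """Actor weights ``m`` (action x channel, >= 0) and perseveration trace ``c``."""

    m: np.ndarray
    c: np.ndarray

    @classmethod
    def fresh(cls, params: ModelParams) -> "ActorState":
        return cls(
            m=np.full((params.n_actions, N_CHANNELS), params.m_init, dtype=float),
            c=np.zeros(params.n_actions, dtype=float),
        )


@dataclass
class CriticState:
    """Critic weights ``v`` (one per channel) and the previous state value ``V'``."""

    v: np.ndarray
    V_prev: float = 0.0

    @classmethod
    def fresh(cls) -> "CriticState":
        return cls(v=np.zeros(N_CHANNELS, dtype=float), V_prev=0.0)


@dataclass(frozen=True)
class StepResult:
    """Outcome of a single model timestep."""

    chosen_action: int
    R: float
    PE: float
    was_press: bool


@dataclass
class Agent:
    """Bundles parameters, actor and critic state for one simulated subject."""

    params: ModelParams
    actor: ActorState
    critic: CriticState

    @classmethod
    def fresh(cls, params: ModelParams) -> "Agent":
        return cls(params=params, actor=ActorState.fresh(params), critic=CriticState.fresh())

    def copy(self) -> "Agent":
        return Agent(
            params=self.params,
            actor=ActorState(m=self.actor.m.copy(), c=self.actor.c.copy()),
            critic=CriticState(v=self.critic.v.copy(), V_prev=self.critic.V_prev),
        )


def action_values(actor: ActorState, inputs: np.ndarray, params: ModelParams) -> np.ndarray:
    """Per-action values ``M_a = sum_i m_ai I_i + trace_gain * c_a``.

    The perseveration trace is per action (the last executed action carries
    c = 1, others decay); ``params.trace_mode`` controls whether its bonus
    counts once per input slot ("summed", gain ``n_channels * P``) or once
    per action ("per_action", gain ``P``).
    """
    inputs = np.asarray(inputs, dtype=float)
    if actor.m.shape != (params.n_actions, N_CHANNELS):
        raise ConfigurationError(
            f"actor weight matrix has shape {actor.m.shape}, "
            f"expected {(params.n_actions, N_CHANNELS)}"
        )
    if inputs.shape != (N_CHANNELS,):
        raise ConfigurationError("input vector does not match the stimulus channel set")
    return actor.m @ inputs + actor.c * params.trace_gain


def action_probabilities(
    values: np.ndarray, T: float, allowed: np.ndarray | None = None
) -> np.ndarray:
    """Softmax policy ``Pr(a) = exp(M_a/T) / sum_b exp(M_b/T)``.

    Computed with max-subtraction for numerical stability.  ``allowed`` is an
    optional boolean mask; excluded actions (e.g. a retracted lever) receive
    probability zero and the rest renormalize.
    """
    values = np.asarray(values, dtype=float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise FloatingPointError(f"non-finite action value at index {bad[0]}")
    scaled = values / T
    if allowed is None:
        shifted = scaled - scaled.max()
        ex = np.exp(shifted)
        return ex / ex.sum()
    allowed = np.asarray(allowed, dtype=bool)
    probs = np.zeros_like(scaled)
    sub = scaled[allowed]
    ex = np.exp(sub - sub.max())
    probs[allowed] = ex / ex.sum()
    return probs


def sample_action(probs: np.ndarray, rng: np.random.Generator) -> int:
    """Draw an action index by inverse-CDF over the fixed action ordering."""
    probs = np.asarray(probs, dtype=float)
    if abs(probs.sum() - 1.0) > 1e-9 or np.any(probs < 0):
        raise ConfigurationError("probabilities do not form a valid distribution")
    return sample_action_from_uniform(probs, rng.random())


def sample_action_from_uniform(probs: np.ndarray, u: float) -> int:
    """Inverse-CDF draw given a uniform variate ``u`` in [0, 1)."""
    cdf = np.cumsum(probs)
    idx = int(np.searchsorted(cdf, u, side="right"))
    return min(idx, len(probs) - 1)


def update_trace(actor: ActorState, chosen: int, decay: float) -> ActorState:
    """Set ``c_chosen = 1`` and decay every other trace multiplicatively.

    Mutates ``actor`` in place and returns it.
    """
    if not 0 <= chosen < len(actor.c):
        raise ConfigurationError(f"action index {chosen} out of range")
    actor.c *= decay
    actor.c[chosen] = 1.0
    return actor


def external_reinforcement(was_press: bool, shock_next: bool, params: ModelParams) -> float:
    """Reinforcement delivered for this timestep.

    Shock at the next timestep dominates; otherwise a lever press incurs its
    energy cost; otherwise nothing.  (A press terminates warning and shock
    immediately, so in the protocol shock can never follow a press.)
    """
    if shock_next:
        return params.R_shock
    if was_press:
        return params.R_press
    return 0.0


def state_value(critic: CriticState, inputs: np.ndarray) -> float:
    """Critic state value ``V = sum_i v_i I_i``."""
    inputs = np.asarray(inputs, dtype=float)
    if inputs.shape != critic.v.shape:
        raise ConfigurationError("input vector does not match critic weights")
    return float(critic.v @ inputs)


def prediction_error(R: float, V_new: float, V_prev: float, gamma: float) -> float:
    """Temporal-difference prediction error ``PE = R + gamma V - V'``."""
    return R + gamma * V_new - V_prev


def update_critic(
    critic: CriticState, PE: float, inputs_prev: np.ndarray, params: ModelParams
) -> CriticState:
    """Apply ``dv_i = alpha PE I_i`` then clip each weight to ``+-|R_shock|``.

    ``inputs_prev`` is the stimulus vector of the predecessor state (the one
    whose value entered the PE as ``V'``): standard TD(0) credit assignment.
    Mutates ``critic`` in place and returns it.
    """
    inputs_prev = np.asarray(inputs_prev, dtype=float)
    critic.v += params.alpha * PE * inputs_prev
    np.clip(critic.v, -params.v_bound, params.v_bound, out=critic.v)
    return critic


def update_actor(
    actor: ActorState, chosen: int, PE: float, inputs_prev: np.ndarray, params: ModelParams
) -> ActorState:
    """Apply ``dm_ri = epsilon (PE - m_ri) I_i`` to the chosen action's row.

    Only active channels change and the result is floored at zero.  Mutates
    ``actor`` in place and returns it.
    """
    if not 0 <= chosen < actor.m.shape[0]:
        raise ConfigurationError(f"action index {chosen} out of range")
    inputs_prev = np.asarray(inputs_prev, dtype=float)
    row = actor.m[chosen]
    row += params.epsilon_actor * (PE - row) * inputs_prev
    np.maximum(row, 0.0, out=row)
    return actor


def model_step(
    agent: Agent,
    inputs_now: np.ndarray,
    next_state,
    rng: np.random.Generator | None = None,
    *,
    u: float | None = None,
    press_allowed: bool = True,
) -> StepResult:
    """Advance the agent by one timestep.

    ``next_state`` is a callable ``chosen -> (inputs_next, shock_next)``
    supplied by the environment, because the successor state depends on the
    action taken (a press terminates the warning/shock period).  It may also
    be a plain ``(inputs_next, shock_next)`` pair when the successor does not
    depend on the action.  Exactly one uniform variate is consumed per step,
    either from ``rng`` or supplied directly as ``u``.
    """
    p = agent.params
    values = action_values(agent.actor, inputs_now, p)
    allowed = None
    if not press_allowed:
        allowed = np.ones(p.n_actions, dtype=bool)
        allowed[PRESS_ACTION] = False
    probs = action_probabilities(values, p.T, allowed=allowed)
    if u is None:
        if rng is None:
            raise ConfigurationError("model_step needs either rng or u")
        u = rng.random()
    chosen = sample_action_from_uniform(probs, u)
    update_trace(agent.actor, chosen, p.trace_decay)

    if callable(next_state):
        inputs_next, shock_next = next_state(chosen)
    else:
        inputs_next, shock_next = next_state
    was_press = chosen == PRESS_ACTION and press_allowed

    R = external_reinforcement(was_press, shock_next, p)
    V_new = state_value(agent.critic, inputs_next)
    PE = prediction_error(R, V_new, agent.critic.V_prev, p.gamma)
    update_critic(agent.critic, PE, inputs_now, p)
    update_actor(agent.actor, chosen, PE, inputs_now, p)
    agent.critic.V_prev = V_new
    return StepResult(chosen_action=chosen, R=R, PE=PE, was_press=was_press)
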