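# Methods

## Model

The agent is a linear actor-critic operating on binary stimulus vectors
over six channels: warning, shock, ITI signal, test context, home context,
novel context. One timestep represents 10 s.

The critic assigns each state the value `V = Σᵢ vᵢ Iᵢ` and, after every
timestep, computes the temporal-difference error
`PE = R + γ V(s_{t+1}) − V(s_t)` using the value of the successor state as
computed with the pre-update weights; `V` of the entered state becomes the
stored "previous value" for the next step. Credit is assigned to the
predecessor state's inputs — `Δvᵢ = α·PE·Iᵢ(t)` — the standard TD(0)
convention, and likewise for the actor update of the chosen action,
`Δm_rᵢ = ε·(PE − m_rᵢ)·Iᵢ(t)`. Critic weights are clipped to
`±|R_shock|` after each update; actor weights are floored at zero after
each update (apply-then-clip order).

Reinforcement is `R_shock` whenever shock is present at the next timestep
(this dominates), else the press cost `−0.2` when the lever press was
selected, else 0. Because a press terminates warning and shock
immediately, shock never follows a press.

Action selection is a softmax over 100 actions at temperature `T`,
computed with max-subtraction (mathematically identical, numerically
stable), sampled by inverse CDF over the fixed action ordering: exactly
one uniform variate is consumed per timestep. Action 0 is the lever press;
actions 1–99 stand for arbitrary behaviors.

### Perseveration trace

The trace is per action: the executed action's trace is set to 1, all
others decay by ×0.95 per timestep, so `c ∈ [0,1]` and the argmax always
marks the last executed action. The value equation admits two readings of
the trace term: counted once per action (`M_a = Σᵢ m_aᵢ Iᵢ + P·c_a`) or
once per input slot (`M_a = Σᵢ (m_aᵢ Iᵢ + P·c_aᵢ)`, which with the
row-uniform trace equals `Σᵢ m_aᵢ Iᵢ + n_channels·P·c_a`). The summed
form is the default (`ModelParams.trace_mode="summed"`): with it,
inter-trial responding declines markedly across the ITI (the trace left by
the avoidance press fades over the interval) and avoidance shows a
session-start warm-up, both prominent features of the behavior being
modelled; the per-action form leaves both nearly flat. The alternative is
available as `trace_mode="per_action"`.

## Parameters

| parameter | default | units / role |
|---|---|---|
| `T` | 1.0 | softmax temperature (explore/exploit) |
| `P` | 0.25 | perseveration gain per input slot |
| `gamma` | 0.9 | discount per 10-s timestep |
| `alpha` | 0.05 male / 0.01 female | critic learning rate |
| `epsilon_actor` | 0.005 | actor learning rate |
| `R_shock` | −4 male / −8 female | shock reinforcement |
| `R_press` | −0.2 | lever-press energy cost |
| `trace_decay` | 0.95 | trace decay per timestep |
| `m_init` | 0.01 | initial actor weights |

The two sex-dependent parameters carry the account: the larger shock cost
makes simulated females acquire avoidance faster and to a higher level;
the smaller critic learning rate makes their learned state values —
including the value of a trained safety signal — persist longer, so its
omission in extinction matters more to them.

## Protocol engine

Trials are variable-length: a press at timestep `L ≤ 36` shortens the
trial to `L` + the fixed ITI; without a press the trial runs
warning (6) + shock period (30) + ITI and latency is scored at the trial
maximum (54 standard, 39 at the 30-s ITI). Each session: 6 stimulus-free
context timesteps, then 20 trials; each session is followed by an
18,000-timestep home-cage interval in which only the home-context input is
active and the full action set (lever included, at its usual cost) remains
available. The value stream is continuous: `V_prev` is never reset across
trial, session or phase boundaries (it starts at 0, and after the final
home-cage interval the terminal transition is taken to remain in the home
state). The ITI signal is never contingent on behavior; in windowed
variants it occupies the first or last three ITI timesteps. Under a
context shift the whole extinction phase (pre-session and ITIs included)
runs on the novel-context channel. When the lever is disabled during the
ITI, the press action is removed from the softmax and the remaining 99
actions renormalize; trace updates still apply to the chosen action.

ITR counts are reported in three equal ITI segments (6 timesteps each at
the 180-s ITI, 1 each at 30 s). Pre-session and home-cage presses incur
the press cost but are not scored.

The per-timestep loop is compiled with numba; a pure-Python reference
path implements the identical arithmetic through the documented operations
and the test suite drives both with the same uniform variates and requires
agreement. Per-simulation uniforms are drawn in fixed blocks (one per
possible trial timestep, whether or not the trial ends early), which makes
runs bit-reproducible given (parameters, protocol, seed).

## Experiments and seeds

Experiment grids follow the study design: 10 simulations per group by
default, seeds `base·10⁴ + cell·10² + replicate`, so cells and replicates
occupy disjoint streams and any subset of a grid reuses the identical
seeds. The `exp2` grids vary one of the two sex parameters while holding
the other fixed at either of its levels.

## Statistics

The split-plot mixed ANOVA supports balanced designs with 1–3 fully
crossed between-subject factors and one within-subject factor. Sums of
squares come from marginal means by inclusion–exclusion (exact for
balanced data); between effects are tested against subjects-within-groups,
within effects against its interaction with the within factor. The
Greenhouse–Geisser ε is estimated from the covariance of the within-level
vectors pooled across between-group cells — `(Σλ)² / ((k−1)Σλ²)` over the
eigenvalues of the double-centered matrix, clipped to `[1/(k−1), 1]` — and
multiplies the dfs of every within effect whenever ε < 1 (no sphericity
pre-test). Effect size is partial η² = SS_effect/(SS_effect+SS_error).
Degenerate strata (constant data) define F = 0. Follow-ups are
pooled-variance independent t tests with `r = √(t²/(t²+df))` and
Bonferroni adjustment by the number of comparisons actually run.

## What the simulations do and do not reproduce

Passing tests establish the qualitative account: females acquire faster
and to a higher level; the critic values a full-length ITI signal
positively (conditioned-reinforcement-like) and a 30-s-ITI or
end-of-interval signal negatively; omission of a trained signal speeds
female extinction at the 180-s ITI and slows it at the 30-s ITI; ITRs
decline across the ITI and are more frequent in females; all of this
survives a context shift and does not require ITRs.

The quantitative group-level statistics are weaker than the corresponding
published ones: with these equations the extinction-phase sex × signal
interaction is directionally present but typically reaches only
p ≈ 0.01–0.4 at n = 10/group rather than p < .001, and the
high-shock/high-α configuration plateaus near 82–85% rather than 90%
avoidance. The cause is a compensating equilibrium: the positive
prediction error of each avoidance press is credited to the warning
input, so warning fear relaxes exactly as fast as pressing is reinforced,
which caps how much a safety signal can differentiate groups.
Alternative credit-assignment conventions that break this compensation
were explored and each contradicts another established property of the
model (crediting the post-press state pins warning fear and abolishes
extinction; crediting successor inputs flips the sign of an
end-of-interval signal); the implementation therefore follows the
equations as stated and reports the resulting effect sizes honestly.

## Numerical conventions and limitations

Softmax underflow can yield exact-zero probabilities when scaled values
differ by more than ~700; normalization is preserved. The home-context
value is not exactly zero (home-cage presses cost −0.2, producing a small
negative drift, |v_home| < ~0.2 against bounds of 4–8). The model has no
eligibility traces beyond one-step TD, no nonlinear function
approximation, linear stimulus summation only, and no representation of
the lever itself (relevant to interpreting the disabled-lever variant).
Simulated subjects differ only by seed — real animals vary in parameters
as well, so between-subject variance here is a lower bound on empirical
variance.
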