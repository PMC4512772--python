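# avoidsim

Actor-critic temporal-difference simulation of discriminated lever-press
escape-avoidance learning in rats, built to study how signals associated
with the safe inter-trial interval (ITI) change the extinction of avoidance
— and why simulated females and males use such signals differently.

## Who this is for

Researchers in computational psychiatry and associative learning who want a
self-contained, reproducible implementation of a classic two-parameter
account of sex differences in avoidance: females are modelled with a higher
shock cost (greater shock sensitivity, faster acquisition) and a lower
critic learning rate (slower revision of learned state values, greater
sensitivity to the omission of a trained safety signal). The package
simulates the full behavioral protocols, produces tidy per-trial and
per-session tables, and applies the field's standard split-plot statistics.

## The model

At every 10-s timestep the agent observes a binary stimulus vector
`I = (warning, shock, ITI signal, test context, home context, novel context)`.

**Critic** (state valuation): `V = Σᵢ vᵢ Iᵢ`, with temporal-difference
prediction error

```
PE = R + γ·V(next state) − V(previous state),      γ = 0.9
Δvᵢ = α · PE · Iᵢ,          |vᵢ| ≤ |R_shock|
```

`R` is `R_shock` when shock occurs on the next timestep, else the lever-press
energy cost `−0.2` for a press, else 0.

**Actor** (action selection among 100 actions, action 0 = lever press):

```
M_a = Σᵢ m_aᵢ Iᵢ + (perseveration bonus) · c_a
Pr(a) = e^{M_a/T} / Σ_b e^{M_b/T},                  T = 1.0
Δm_rᵢ = ε · (PE − m_rᵢ) · Iᵢ   (chosen action r),   m ≥ 0,  ε = 0.005
```

`c_a` is a perseveration trace (1 for the last executed action, ×0.95 per
timestep otherwise; gain `P = 0.25` per input slot).

**Protocol**: 54-timestep trials (6 warning, up to 30 shock, 18 ITI), a
press terminates warning and shock immediately and starts the ITI; 20
trials per session, 12 sessions of acquisition then 12 of extinction, an
18,000-timestep home-cage interval between sessions. Presses during the
warning are scored avoidance, during shock escape, during the ITI as
inter-trial responses (ITRs).

**Sexes**: male `R_shock = −4, α = 0.05`; female `R_shock = −8, α = 0.01`;
everything else shared.

Eight experiment grids (`exp1_omitted` … `exp6_signal_timing`) vary the
signal's presence, the ITI length, its timing within the ITI, the testing
context, and ITR availability. A self-contained split-plot mixed ANOVA
(1–3 between factors × one within factor, Greenhouse–Geisser corrected,
partial η²) and Bonferroni follow-up t tests analyse the simulated behavior.

## Worked example

```python
from avoidsim import ProtocolConfig, run_simulation

run = run_simulation("female", ProtocolConfig(signal_in_acquisition=True), seed=42)
```

Printing the per-session avoidance proportions and end-of-acquisition
critic weights (`examples/01_single_subject.py`) gives:

```
acquisition avoidance by session: [0.1  0.45 1.  1.  1.  0.95 1.  0.95 1.  0.95 1.  0.85]
extinction  avoidance by session: [0.8  0.7  0.45 0.4  0.6  0.35 0.35 0.35 0.25 0.2  0.15 0.25]

end-of-acquisition critic weights:
  warning        -0.315
  shock          -7.255
  iti_signal     +0.687
  test_context   -1.214
  home_context   -0.016
```

The subject acquires avoidance within three sessions and extinguishes
gradually. The critic assigns negative value to the warning and the test
context (learned danger), pins the shock input near the −8 bound, and gives
the ITI signal a *positive* value: having reliably followed successful
avoidance, the safety signal behaves like a conditioned reinforcer. Under a
30-s ITI, or a signal placed in the last 30 s of the interval, the same
weight turns negative (`examples/03_signal_value_by_iti_geometry.py`).

Other examples: `02_safety_signal_extinction.py` (the sex × signal design
and its ANOVA) and `04_split_plot_anova.py` (the statistics pipeline on
synthetic data). A thin CLI mirrors the library:

```bash
avoidsim run exp1_omitted --n-per-group 10 --seed 1 --out results/exp1
avoidsim analyze results/exp1
avoidsim selftest
```

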