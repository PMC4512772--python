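"""Shared fixtures.

The heavy fixtures run full experiment grids (10 simulations per group, the
scale at which the group-level claims are stated) once per session; the
assertions in the experiment and acceptance tests are all made against
these fixed-seed runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from avoidsim.experiments import make_experiment, run_experiment
from avoidsim.model import Agent, ModelParams
from avoidsim.protocol import ProtocolConfig
from avoidsim.stats import session_summary


@pytest.fixture(scope="session")
def exp1_results():
    """Experiment 1, signal omitted in extinction, n = 10/group."""
    return run_experiment(make_experiment("exp1_omitted", base_seed=1))


@pytest.fixture(scope="session")
def exp1_always_results():
    """Experiment 1 variant with the ITI signal always present in extinction."""
    return run_experiment(make_experiment("exp1_always_present", base_seed=1))


@pytest.fixture(scope="session")
def exp3_results():
    return run_experiment(make_experiment("exp3_context_shift", base_seed=1))


@pytest.fixture(scope="session")
def exp4_results():
    """Experiment 4 (30-s ITI), n = 10/group."""
    return run_experiment(make_experiment("exp4_short_iti", base_seed=1))


@pytest.fixture(scope="session")
def exp2_high_alpha_results():
    """Experiment 2 alpha grid with shock cost held at -8: alpha = 0.05 cells."""
    spec = make_experiment("exp2_alpha_grid", base_seed=1, held_shock=-8.0)
    return run_experiment(spec, subset={"alpha": 0.05})


@pytest.fixture(scope="session")
def exp6_present_results():
    """Experiment 6 signal-present groups (first vs last 30 s), n = 10/group."""
    spec = make_experiment("exp6_signal_timing", base_seed=1)
    return run_experiment(spec, subset={"signal": "present"})


@pytest.fixture(scope="session")
def exp1_summary(exp1_results):
    return session_summary(exp1_results.trials, group_cols=["sex", "signal"])


@pytest.fixture(scope="session")
def exp4_summary(exp4_results):
    return session_summary(exp4_results.trials, group_cols=["sex", "signal"])


def end_of_acquisition_weights(results, channel):
    """Mean end-of-acquisition critic weight per group for one channel."""
    w = results.weights
    sel = w[
        (w.phase == "acquisition") & (w.session == 12) & (w.trial == 20)
        & (w.channel == channel)
    ]
    label_cols = [c for c in ("sex", "signal", "timing", "iti_len", "alpha", "shock_cost")
                  if c in w.columns]
    return sel.groupby(label_cols, observed=True).v.mean()


@pytest.fixture
def male_agent():
    return Agent.fresh(ModelParams(R_shock=-4.0, alpha=0.05))


@pytest.fixture
def standard_config():
    return ProtocolConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
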