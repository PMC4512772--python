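"""Factories and runners for the six simulation experiments.

Each experiment is a fully crossed grid of simulated groups (cells), ten
subjects per cell by default, each subject a seeded run of the avoidance
protocol.  The experiments probe when omission of an inter-trial-interval
(ITI) safety signal changes the extinction of avoidance:

* ``exp1_omitted`` -- male/female x signal present/absent in acquisition,
  signal never shown in extinction (the headline sex x signal interaction).
* ``exp1_always_present`` -- identical acquisition, but the signal is always
  shown in extinction (tests whether mere novelty of a change suffices).
* ``exp2_shock_grid`` / ``exp2_alpha_grid`` -- single-parameter grids that
  dissociate the two "sex" parameters: vary shock cost (-4 vs -8) with the
  critic learning rate held fixed, or vary the learning rate (0.01 vs 0.05)
  with shock cost held fixed.
* ``exp3_context_shift`` -- extinction in a novel context.
* ``exp4_short_iti`` -- ITI shortened from 180 s to 30 s (3 timesteps).
* ``exp5_no_itr`` -- lever press disabled during the ITI (no ITRs), at both
  ITI lengths.
* ``exp6_signal_timing`` -- 30-s signal in the first or last 30 s of the
  180-s ITI.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import ConfigurationError, ModelParams
from .protocol import ProtocolConfig, SimulationRun, run_simulation, sex_params

__all__ = [
    "EXPERIMENT_NAMES",
    "ExperimentCell",
    "ExperimentSpec",
    "ExperimentResults",
    "make_experiment",
    "run_experiment",
    "simulation_seed",
]

EXPERIMENT_NAMES = (
    "exp1_omitted",
    "exp1_always_present",
    "exp2_shock_grid",
    "exp2_alpha_grid",
    "exp3_context_shift",
    "exp4_short_iti",
    "exp5_no_itr",
    "exp6_signal_timing",
)


@dataclass(frozen=True)
class ExperimentCell:
    """One group of the design grid."""

    index: int
    labels: dict
    params: ModelParams
    config: ProtocolConfig
    sex: str | None = None


@dataclass(frozen=True)
class ExperimentSpec:
    """A named experiment: its cells, replication count and seed stream."""

    name: str
    cells: tuple[ExperimentCell, ...]
    n_per_group: int = 10
    base_seed: int = 0
    between_factors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ConfigurationError("n_per_group must be at least 2")


@dataclass
class ExperimentResults:
    """Tidy behavioral and weight tables for a completed experiment."""

    spec: ExperimentSpec
    trials: pd.DataFrame
    weights: pd.DataFrame
    runs: list[SimulationRun] = field(default_factory=list)


def simulation_seed(base_seed: int, cell_index: int, replicate: int) -> int:
    """Deterministic, non-overlapping seed per simulation."""
    return base_seed * 10_000 + cell_index * 100 + replicate


def _signal_levels():
    return ("present", "absent")


def _sex_cells(config_for, extra_labels=None):
    """Standard male/female x signal-present/absent grid."""
    cells = []
    idx = 0
    for sex in ("male", "female"):
        for signal in _signal_levels():
            labels = {"sex": sex, "signal": signal, **(extra_labels or {})}
            cells.append(
                ExperimentCell(
                    index=idx, labels=labels, params=sex_params(sex),
                    config=config_for(signal == "present"), sex=sex,
                )
            )
            idx += 1
    return cells


def make_experiment(
    name: str,
    n_per_group: int = 10,
    base_seed: int = 0,
    *,
    held_alpha: float = 0.01,
    held_shock: float = -4.0,
) -> ExperimentSpec:
    """Build the design grid for one of the named experiments.

    ``held_alpha`` fixes the critic learning rate for ``exp2_shock_grid``
    (the complementary sub-experiment uses 0.05); ``held_shock`` fixes the
    shock cost for ``exp2_alpha_grid`` (-4 or -8).
    """
    if name == "exp1_omitted":
        cells = _sex_cells(lambda sig: ProtocolConfig(signal_in_acquisition=sig))
        between = ("sex", "signal")
    elif name == "exp1_always_present":
        cells = _sex_cells(
            lambda sig: ProtocolConfig(signal_in_acquisition=sig, signal_in_extinction=True)
        )
        between = ("sex", "signal")
    elif name == "exp2_shock_grid":
        cells = []
        for idx, (shock, signal) in enumerate(
            itertools.product((-4.0, -8.0), _signal_levels())
        ):
            cells.append(
                ExperimentCell(
                    index=idx,
                    labels={"shock_cost": shock, "signal": signal, "alpha": held_alpha},
                    params=ModelParams(R_shock=shock, alpha=held_alpha),
                    config=ProtocolConfig(signal_in_acquisition=signal == "present"),
                )
            )
        between = ("shock_cost", "signal")
    elif name == "exp2_alpha_grid":
        cells = []
        for idx, (alpha, signal) in enumerate(
            itertools.product((0.01, 0.05), _signal_levels())
        ):
            cells.append(
                ExperimentCell(
                    index=idx,
                    labels={"alpha": alpha, "signal": signal, "shock_cost": held_shock},
                    params=ModelParams(R_shock=held_shock, alpha=alpha),
                    config=ProtocolConfig(signal_in_acquisition=signal == "present"),
                )
            )
        between = ("alpha", "signal")
    elif name == "exp3_context_shift":
        cells = _sex_cells(
            lambda sig: ProtocolConfig(
                signal_in_acquisition=sig, context_shift_in_extinction=True
            )
        )
        between = ("sex", "signal")
    elif name == "exp4_short_iti":
        cells = _sex_cells(
            lambda sig: ProtocolConfig(signal_in_acquisition=sig, iti_len=3)
        )
        between = ("sex", "signal")
    elif name == "exp5_no_itr":
        cells = []
        idx = 0
        for sex in ("male", "female"):
            for signal in _signal_levels():
                for iti_len in (18, 3):
                    cells.append(
                        ExperimentCell(
                            index=idx,
                            labels={"sex": sex, "signal": signal, "iti_len": iti_len},
                            params=sex_params(sex),
                            config=ProtocolConfig(
                                signal_in_acquisition=signal == "present",
                                iti_len=iti_len,
                                lever_enabled_in_iti=False,
                            ),
                            sex=sex,
                        )
                    )
                    idx += 1
        between = ("sex", "signal", "iti_len")
    elif name == "exp6_signal_timing":
        cells = []
        idx = 0
        for sex in ("male", "female"):
            for signal in _signal_levels():
                for timing in ("first_3", "last_3"):
                    cells.append(
                        ExperimentCell(
                            index=idx,
                            labels={"sex": sex, "signal": signal, "timing": timing},
                            params=sex_params(sex),
                            config=ProtocolConfig(
                                signal_in_acquisition=signal == "present",
                                signal_window=timing,
                            ),
                            sex=sex,
                        )
                    )
                    idx += 1
        between = ("sex", "signal", "timing")
    else:
        raise ConfigurationError(
            f"unknown experiment {name!r}; expected one of {EXPERIMENT_NAMES}"
        )
    return ExperimentSpec(
        name=name, cells=tuple(cells), n_per_group=n_per_group,
        base_seed=base_seed, between_factors=between,
    )


def run_experiment(
    spec: ExperimentSpec,
    *,
    subset: dict | None = None,
    keep_runs: bool = False,
    progress: callable | None = None,
) -> ExperimentResults:
    """Run every cell of the grid and assemble tidy result tables.

    ``subset`` optionally restricts the grid to cells whose labels match
    the given values (cell indices, and therefore seeds, are unchanged).
    ``progress`` is an optional callable invoked with a status string after
    each cell.
    """
    trials_parts, weights_parts, runs = [], [], []
    for cell in spec.cells:
        if subset and any(cell.labels.get(k) != v for k, v in subset.items()):
            continue
        for rep in range(spec.n_per_group):
            seed = simulation_seed(spec.base_seed, cell.index, rep)
            run = run_simulation(
                cell.sex, cell.config, seed, params=cell.params, labels=cell.labels
            )
            sim_id = f"c{cell.index}r{rep}"
            tf = run.trials_frame()
            tf.insert(0, "sim", sim_id)
            wf = run.weights_frame()
            wf.insert(0, "sim", sim_id)
            for key, value in cell.labels.items():
                tf[key] = value
                wf[key] = value
            tf["seed"] = seed
            trials_parts.append(tf)
            weights_parts.append(wf)
            if keep_runs:
                runs.append(run)
        if progress is not None:
            progress(f"{spec.name}: cell {cell.index} ({cell.labels}) done")
    if not trials_parts:
        raise ConfigurationError("subset matched no cells of the design grid")
    return ExperimentResults(
        spec=spec,
        trials=pd.concat(trials_parts, ignore_index=True),
        weights=pd.concat(weights_parts, ignore_index=True),
        runs=runs,
    )
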