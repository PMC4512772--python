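"""Run configuration, validation and file output.

A run is described by a :class:`RunConfig`: the experiment name, replication
count, base seed, output directory, and optional overrides of any model
parameter (``alpha``, ``R_shock``, ``T`` ...) or protocol field (``iti_len``,
``signal_window`` ...).  Configurations load from YAML files and/or
``key=value`` override strings; every override is validated against the
type invariants before any simulation starts.  Outputs are tidy CSVs plus
JSON statistics, and the exact effective configuration is echoed next to
them so a directory is always regenerable.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiments import EXPERIMENT_NAMES
from .model import ConfigurationError, ModelParams
from .protocol import ProtocolConfig

__all__ = ["RunConfig", "parse_config", "write_outputs", "read_config_file"]

_PARAM_FIELDS = {f.name: f.type for f in fields(ModelParams)}
_PROTOCOL_FIELDS = {f.name: f.type for f in fields(ProtocolConfig)}
_TOP_FIELDS = ("experiment", "n_per_group", "seed", "out", "verbose",
               "held_alpha", "held_shock")


@dataclass(frozen=True)
class RunConfig:
    """Validated description of one experiment run."""

    experiment: str
    n_per_group: int = 10
    seed: int = 0
    out: str = "results"
    verbose: bool = False
    held_alpha: float = 0.01   # exp2_shock_grid only
    held_shock: float = -4.0   # exp2_alpha_grid only
    param_overrides: dict = field(default_factory=dict)
    protocol_overrides: dict = field(default_factory=dict)

    def effective_params(self, base: ModelParams) -> ModelParams:
        return replace(base, **self.param_overrides) if self.param_overrides else base

    def effective_protocol(self, base: ProtocolConfig) -> ProtocolConfig:
        return replace(base, **self.protocol_overrides) if self.protocol_overrides else base

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in _TOP_FIELDS}
        d.update(self.param_overrides)
        d.update(self.protocol_overrides)
        return d


def _coerce(name: str, value, annotation: str):
    """Coerce a string/YAML scalar to the declared field type."""
    ann = str(annotation)
    try:
        if "bool" in ann:
            if isinstance(value, bool):
                return value
            if str(value).lower() in ("true", "1", "yes"):
                return True
            if str(value).lower() in ("false", "0", "no"):
                return False
            raise ValueError(value)
        if "int" in ann:
            return int(value)
        if "float" in ann:
            return float(value)
        return str(value)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid value for field {name!r}: {value!r}") from exc


def parse_config(
    file: str | Path | None = None,
    overrides: list[str] | dict | None = None,
    **top,
) -> RunConfig:
    """Build a validated :class:`RunConfig` from a YAML file and overrides.

    ``overrides`` accepts ``key=value`` strings (as from a ``--set`` flag) or
    a plain dict.  Unknown keys and values violating the model or protocol
    invariants raise :class:`ConfigurationError` naming the field.
    """
    raw: dict = {}
    if file is not None:
        raw.update(read_config_file(file))
    if isinstance(overrides, dict):
        raw.update(overrides)
    elif overrides:
        for item in overrides:
            if "=" not in item:
                raise ConfigurationError(f"override {item!r} is not of the form key=value")
            key, _, value = item.partition("=")
            raw[key.strip()] = value.strip()
    raw.update({k: v for k, v in top.items() if v is not None})

    known_top = {}
    param_over = {}
    proto_over = {}
    for key, value in raw.items():
        if key in ("param_overrides", "protocol_overrides"):
            # nested form produced by config echo round-trips
            dest = param_over if key == "param_overrides" else proto_over
            dest.update(value or {})
        elif key in _TOP_FIELDS:
            known_top[key] = value
        elif key in _PARAM_FIELDS:
            param_over[key] = _coerce(key, value, _PARAM_FIELDS[key])
        elif key in _PROTOCOL_FIELDS:
            proto_over[key] = _coerce(key, value, _PROTOCOL_FIELDS[key])
        else:
            raise ConfigurationError(f"unknown configuration key {key!r}")

    if "experiment" not in known_top:
        raise ConfigurationError("configuration must name an experiment")
    if known_top["experiment"] not in EXPERIMENT_NAMES:
        raise ConfigurationError(
            f"unknown experiment {known_top['experiment']!r}; "
            f"expected one of {EXPERIMENT_NAMES}"
        )
    if "n_per_group" in known_top:
        known_top["n_per_group"] = int(known_top["n_per_group"])
    if "seed" in known_top:
        known_top["seed"] = int(known_top["seed"])
    if "verbose" in known_top:
        known_top["verbose"] = _coerce("verbose", known_top["verbose"], "bool")
    for k in ("held_alpha", "held_shock"):
        if k in known_top:
            known_top[k] = float(known_top[k])

    cfg = RunConfig(param_overrides=param_over, protocol_overrides=proto_over, **known_top)
    # re-validate overrides against the dataclass invariants before running
    try:
        cfg.effective_params(ModelParams())
    except ConfigurationError as exc:
        raise ConfigurationError(f"invalid model parameter override: {exc}") from exc
    try:
        cfg.effective_protocol(ProtocolConfig())
    except ConfigurationError as exc:
        raise ConfigurationError(f"invalid protocol override: {exc}") from exc
    return cfg


def read_config_file(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"configuration file {path} must hold a mapping")
    return data


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"cannot serialize {type(obj)}")


def write_outputs(
    out_dir: str | Path,
    *,
    config: RunConfig | None = None,
    trials: pd.DataFrame | None = None,
    behavior: pd.DataFrame | None = None,
    weights: pd.DataFrame | None = None,
    anova: dict | None = None,
    followups: list | None = None,
    log_lines: list[str] | None = None,
) -> Path:
    """Write the standard output set into ``out_dir`` (created if missing).

    CSVs carry headers and full-precision floats; rerunning with the same
    configuration and seed overwrites byte-identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if trials is not None:
        trials.to_csv(out / "trials.csv", index=False)
    if behavior is not None:
        behavior.to_csv(out / "behavior.csv", index=False)
    if weights is not None:
        weights.to_csv(out / "weights.csv", index=False)
    if anova is not None:
        with open(out / "anova.json", "w") as fh:
            json.dump(anova, fh, indent=2, default=_json_default)
            fh.write("\n")
    if followups is not None:
        with open(out / "followups.json", "w") as fh:
            json.dump(followups, fh, indent=2, default=_json_default)
            fh.write("\n")
    if config is not None:
        with open(out / "config.echo", "w") as fh:
            yaml.safe_dump(
                {
                    **{k: getattr(config, k) for k in _TOP_FIELDS},
                    "param_overrides": config.param_overrides,
                    "protocol_overrides": config.protocol_overrides,
                },
                fh, sort_keys=True,
            )
    if log_lines is not None:
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(log_lines) + "\n")
    return out
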