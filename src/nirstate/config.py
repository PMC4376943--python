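"""Flat YAML configuration loading for the CLI.

A config file is a flat key-value mapping; keys are matched against the
fields of :class:`~nirstate.simulate.SimulationConfig`,
:class:`~nirstate.macd.MacdConfig`, :class:`~nirstate.classifier.CvPlan`
and the experiment-level options.  Unknown keys are an error so typos do
not silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses

import yaml

from .classifier import CvPlan
from .macd import MacdConfig
from .pipeline import ExperimentConfig
from .simulate import SimulationConfig


def load_config(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must be a flat key-value mapping")
    return data


def _pick(data: dict, cls) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    out = {}
    for k in names & set(data.keys()):
        v = data[k]
        out[k] = tuple(v) if isinstance(v, list) else v
    return out


def sim_config_from_dict(data: dict, seed: int | None = None) -> SimulationConfig:
    kwargs = _pick(data, SimulationConfig)
    if seed is not None:
        kwargs["seed"] = seed
    return SimulationConfig(**kwargs)


def experiment_config_from_dict(data: dict, seed: int | None = None) -> ExperimentConfig:
    macd = MacdConfig(**_pick(data, MacdConfig))
    cv_kwargs = _pick(data, CvPlan)
    if seed is not None:
        cv_kwargs.setdefault("seed", seed)
    cv = CvPlan(**cv_kwargs)
    kwargs = _pick(data, ExperimentConfig)
    kwargs.pop("macd", None)
    kwargs.pop("cv", None)
    return ExperimentConfig(macd=macd, cv=cv, **kwargs)


def validate_keys(data: dict) -> None:
    known = set()
    for cls in (SimulationConfig, MacdConfig, CvPlan, ExperimentConfig):
        known |= {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
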