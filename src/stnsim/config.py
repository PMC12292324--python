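"""Flat YAML configuration round-trip for simulation runs.

The file format is a flat mapping whose keys mirror the
:class:`~stnsim.simulator.SimulationConfig` fields, with nested neuron
and STDP constants flattened under ``neuron.*`` and ``stdp.*`` keys.
``default_config()`` reproduces the packaged parameter set (the STN
membrane constants plus the synaptic and plasticity defaults).
"""

from __future__ import annotations

from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .model_core import NeuronParameters
from .plasticity import StdpParameters
from .simulator import SimulationConfig

__all__ = ["default_config", "config_to_dict", "config_from_dict",
           "load_config", "save_config"]


def default_config() -> SimulationConfig:
    return SimulationConfig()


def config_to_dict(cfg: SimulationConfig) -> dict:
    out = {}
    for f in fields(cfg):
        if f.name in ("neuron", "stdp", "external_current"):
            continue
        out[f.name] = getattr(cfg, f.name)
    for key, value in asdict(cfg.neuron).items():
        out[f"neuron.{key}"] = value
    for key, value in asdict(cfg.stdp).items():
        out[f"stdp.{key}"] = value
    return out


def config_from_dict(data: dict) -> SimulationConfig:
    neuron_kwargs = {}
    stdp_kwargs = {}
    top = {}
    for key, value in data.items():
        if key.startswith("neuron."):
            neuron_kwargs[key.split(".", 1)[1]] = value
        elif key.startswith("stdp."):
            stdp_kwargs[key.split(".", 1)[1]] = value
        else:
            top[key] = value
    known = {f.name for f in fields(SimulationConfig)}
    unknown = set(top) - known
    if unknown:
        raise KeyError(f"unknown config keys: {sorted(unknown)}")
    return SimulationConfig(
        neuron=NeuronParameters(**neuron_kwargs),
        stdp=StdpParameters(**stdp_kwargs),
        **top,
    )


def load_config(path) -> SimulationConfig:
    with Path(path).open() as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(cfg: SimulationConfig, path) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
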