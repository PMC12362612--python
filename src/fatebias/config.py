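"""Run configuration files (YAML or JSON) for the command-line interface.

A config carries a model name, kinetic parameter overrides (keys exactly the
:class:`~fatebias.params.KineticParams` field names), an optional controller
block (:class:`~fatebias.models.ControllerConfig` field names), and optional
scan/simulation/output blocks. Unknown keys anywhere are an error — silent
typos in rate constants are worse than a crash.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .models import (ControllerConfig, ModelSpec, ModelError,
                     default_tristable_config, make_controlled_mutual_activation,
                     make_controlled_toggle, make_controlled_tristable,
                     make_mutual_activation, make_toggle,
                     make_toggle_selfactivation)
from .params import KineticParams, ParameterError, nominal_params, tristable_params


class ConfigError(ValueError):
    """Invalid run configuration."""


_PARAM_KEYS = {f.name for f in dataclasses.fields(KineticParams)}
_CONTROLLER_KEYS = {f.name for f in dataclasses.fields(ControllerConfig)}
_TOP_KEYS = {"model", "params", "controller", "scan", "simulation", "output"}
_SCAN_KEYS = {"parameter", "grid"}
_SIM_KEYS = {"n", "t_end", "omega", "seed", "x0", "mode"}

MODEL_NAMES = ("toggle", "controlled_toggle", "toggle_selfactivation",
               "mutual_activation", "controlled_mutual_activation",
               "controlled_tristable")


@dataclass
class RunConfig:
    """Validated contents of one configuration file."""

    model: str
    params: KineticParams
    controller: ControllerConfig | None = None
    scan: dict = field(default_factory=dict)
    simulation: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)

    def build_spec(self) -> ModelSpec:
        return build_model(self.model, self.params, self.controller)


def _check_keys(block: dict, allowed: set, where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) in {where}: {sorted(unknown)}")


def load_config(path) -> RunConfig:
    """Read and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")
    return parse_config(data)


def parse_config(data: dict) -> RunConfig:
    _check_keys(data, _TOP_KEYS, "config")
    model = data.get("model")
    if model not in MODEL_NAMES:
        raise ConfigError(f"model must be one of {MODEL_NAMES}, got {model!r}")
    pblock = data.get("params", {}) or {}
    _check_keys(pblock, _PARAM_KEYS, "params")
    base = tristable_params if model in ("toggle_selfactivation",
                                         "controlled_tristable") else nominal_params
    try:
        params = base(**pblock)
    except (ParameterError, TypeError) as exc:
        raise ConfigError(f"invalid params: {exc}") from exc
    controller = None
    if "controller" in data and data["controller"] is not None:
        cblock = dict(data["controller"])
        _check_keys(cblock, _CONTROLLER_KEYS, "controller")
        try:
            controller = ControllerConfig(**cblock)
        except ModelError as exc:
            raise ConfigError(f"invalid controller block: {exc}") from exc
    scan = data.get("scan", {}) or {}
    _check_keys(scan, _SCAN_KEYS, "scan")
    sim = data.get("simulation", {}) or {}
    _check_keys(sim, _SIM_KEYS, "simulation")
    return RunConfig(model=model, params=params, controller=controller,
                     scan=scan, simulation=sim, output=data.get("output", {}) or {})


def build_model(name: str, params: KineticParams,
                controller: ControllerConfig | None = None) -> ModelSpec:
    """Instantiate a named model variant."""
    try:
        if name == "toggle":
            return make_toggle(params)
        if name == "controlled_toggle":
            return make_controlled_toggle(params, controller)
        if name == "toggle_selfactivation":
            return make_toggle_selfactivation(params, double=True)
        if name == "mutual_activation":
            return make_mutual_activation(params)
        if name == "controlled_mutual_activation":
            return make_controlled_mutual_activation(params, controller)
        if name == "controlled_tristable":
            if params.beta_prime is None:
                params = params.replace(beta_prime=params.beta)  # β′=β default
            if controller is not None:
                cfg2 = controller.mirrored()
                return make_controlled_tristable(params, controller, cfg2)
            return make_controlled_tristable(params)
    except (ModelError, ParameterError) as exc:
        raise ConfigError(str(exc)) from exc
    raise ConfigError(f"unknown model {name!r}")
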