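"""Declarative simulation configuration.

A configuration is a plain dict (loadable from JSON) mirroring the
simulator's constructor; :func:`build_simulator` turns it into a
configured :class:`~brainsim.simulator.Simulator`.  Example::

    {
      "connectome": {"synthetic": {"n_regions": 74, "weight_levels": 4, "seed": 42}},
      "model": {"name": "generic2d", "params": {"d": 0.62}},
      "coupling": {"kind": "linear", "a": 0.05},
      "integrator": {"scheme": "heun", "dt": 0.25, "stochastic": false},
      "monitors": [{"kind": "temporal_average", "period": 1.0}],
      "stimulus": {"weighting": [...], "temporal": {"kind": "pulse_train",
                    "onset": 100, "width": 5, "period": 1000, "amplitude": 1}},
      "simulation_length": 1000,
      "seed": 1
    }

Connectomes come either from a ZIP archive (``{"zip": path}``), an inline
synthetic recipe, or are passed pre-built through ``build_simulator``'s
``connectome`` argument.
"""

from __future__ import annotations

import copy
import json

import numpy as np

from .connectome import Connectome, generate_synthetic_connectome, read_connectome_zip
from .coupling import COUPLING_REGISTRY
from .exceptions import ConfigurationError
from .integrators import build_integrator
from .models import MODEL_REGISTRY
from .monitors import (
    MONITOR_REGISTRY,
    BalloonParams,
    ProjectionMatrix,
    SensorProjectionMonitor,
    BoldMonitor,
)
from .noise import ColoredNoise, WhiteNoise
from .simulator import Simulator
from .stimulus import PulseTrain, region_stimulus

__all__ = ["load_config", "build_simulator", "set_config_value"]


def load_config(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _build_connectome(section) -> Connectome:
    if isinstance(section, Connectome):
        return section
    if "zip" in section:
        c = read_connectome_zip(section["zip"])
    elif "synthetic" in section:
        c = generate_synthetic_connectome(**section["synthetic"])
    else:
        raise ConfigurationError("connectome section needs 'zip' or 'synthetic'")
    if "speed" in section:
        c.speed = float(section["speed"])
        if c.speed <= 0:
            raise ConfigurationError("connectome.speed must be positive")
    return c


def _build_model(section):
    name = section.get("name")
    if name not in MODEL_REGISTRY:
        raise ConfigurationError(
            f"unknown model {name!r}; available: {sorted(MODEL_REGISTRY)}"
        )
    return MODEL_REGISTRY[name](**section.get("params", {}))


def _build_coupling(section):
    section = dict(section or {"kind": "linear"})
    kind = section.pop("kind", "linear")
    if kind not in COUPLING_REGISTRY:
        raise ConfigurationError(f"unknown coupling kind {kind!r}")
    return COUPLING_REGISTRY[kind](**section)


def _build_noise(section):
    if section is None:
        return WhiteNoise()
    section = dict(section)
    color = section.pop("color", "white")
    if color == "white":
        return WhiteNoise(**section)
    if color == "colored":
        return ColoredNoise(**section)
    raise ConfigurationError(f"unknown noise color {color!r}")


def _build_integrator(section):
    section = dict(section or {})
    noise = _build_noise(section.pop("noise", None)) if section.get("stochastic") else None
    return build_integrator(
        scheme=section.get("scheme", "heun"),
        dt=float(section.get("dt", 0.0625)),
        stochastic=bool(section.get("stochastic", False)),
        noise=noise,
    )


def _build_monitor(section):
    section = dict(section)
    kind = section.pop("kind")
    if kind not in MONITOR_REGISTRY:
        raise ConfigurationError(f"unknown monitor kind {kind!r}")
    if kind == "projection":
        gain = np.asarray(section.pop("gain"))
        labels = section.pop("sensor_labels", None)
        return SensorProjectionMonitor(
            ProjectionMatrix(gain=gain, sensor_labels=labels), **section
        )
    if kind == "bold":
        params = section.pop("params", None)
        if params is not None:
            section["params"] = BalloonParams(**params)
        return BoldMonitor(**section)
    return MONITOR_REGISTRY[kind](**section)


def _build_temporal(section):
    section = dict(section)
    kind = section.pop("kind", "pulse_train")
    if kind != "pulse_train":
        raise ConfigurationError(f"unknown temporal equation {kind!r}")
    return PulseTrain(**section)


def _build_stimulus(section):
    if section is None:
        return None
    return region_stimulus(section["weighting"], _build_temporal(section["temporal"]))


def build_simulator(config: dict, connectome: Connectome | None = None) -> Simulator:
    """Build and configure a :class:`Simulator` from a configuration dict."""
    cfg = copy.deepcopy({k: v for k, v in config.items() if k != "connectome"})
    if connectome is None:
        connectome = _build_connectome(config.get("connectome", {}))
    sim = Simulator(
        connectome=connectome,
        model=_build_model(cfg.get("model", {"name": "generic2d"})),
        integrator=_build_integrator(cfg.get("integrator")),
        coupling=_build_coupling(cfg.get("coupling")),
        monitors=[_build_monitor(m) for m in cfg.get("monitors", [{"kind": "raw"}])],
        stimulus=_build_stimulus(cfg.get("stimulus")),
        initial_conditions=cfg.get("initial_conditions"),
        seed=cfg.get("seed"),
    )
    return sim.configure()


_SWEEPABLE_SECTIONS = ("model", "coupling", "connectome", "integrator", "noise")


def set_config_value(config: dict, dotted: str, value) -> dict:
    """Return a copy of ``config`` with one dotted parameter replaced.

    Recognised paths: ``model.<param>``, ``coupling.<attr>``,
    ``connectome.speed``, ``integrator.dt`` and ``noise.<attr>``; anything
    else raises :class:`ConfigurationError`.
    """
    section, _, name = dotted.partition(".")
    if section not in _SWEEPABLE_SECTIONS or not name:
        raise ConfigurationError(f"cannot resolve parameter path {dotted!r}")
    cfg = copy.deepcopy(config)
    if section == "model":
        model_cfg = cfg.setdefault("model", {"name": "generic2d"})
        defaults = MODEL_REGISTRY[model_cfg["name"]].parameter_defaults
        if name not in defaults:
            raise ConfigurationError(
                f"model {model_cfg['name']!r} has no parameter {name!r}"
            )
        model_cfg.setdefault("params", {})[name] = value
    elif section == "coupling":
        cfg.setdefault("coupling", {"kind": "linear"})[name] = value
    elif section == "connectome":
        if name != "speed":
            raise ConfigurationError("only connectome.speed is sweepable")
        cfg.setdefault("connectome", {})["speed"] = value
    elif section == "integrator":
        cfg.setdefault("integrator", {})[name] = value
    elif section == "noise":
        integ = cfg.setdefault("integrator", {})
        integ.setdefault("noise", {})[name] = value
    return cfg
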