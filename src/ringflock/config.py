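"""Configuration files and experiment presets.

Configs are flat TOML or JSON documents mirroring ``SimulationConfig``
(with ``coupling`` and ``targets`` as nested tables).  Unknown keys are
rejected so that typos fail loudly.  Presets bundle the parameter sets of
the study's standard experiments; presets whose problem size (population,
steps, neuron count) has been reduced to run quickly on one CPU carry
``reduced_scale=True`` and a note saying what was reduced.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .simulation import SimulationConfig, SocialCoupling, TargetSpec

__all__ = ["load_config", "save_config", "config_to_dict",
           "config_from_dict", "Preset", "PRESETS", "get_preset"]

_ARRAY_FIELDS = ("initial_positions", "initial_headings",
                 "initial_network_states")
_CONFIG_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_COUPLING_KEYS = {f.name for f in dataclasses.fields(SocialCoupling)}
_TARGET_KEYS = {f.name for f in dataclasses.fields(TargetSpec)}


def config_from_dict(data: dict) -> SimulationConfig:
    """Build a validated config from a plain mapping (rejecting unknown
    keys and naming the offending field on range violations)."""
    data = dict(data)
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "coupling" in data and isinstance(data["coupling"], dict):
        cdata = data["coupling"]
        bad = set(cdata) - _COUPLING_KEYS
        if bad:
            raise ValueError(f"unknown coupling keys: {sorted(bad)}")
        data["coupling"] = SocialCoupling(**cdata)
    if "targets" in data:
        targets = []
        for tdata in data["targets"]:
            if isinstance(tdata, dict):
                bad = set(tdata) - _TARGET_KEYS
                if bad:
                    raise ValueError(f"unknown target keys: {sorted(bad)}")
                tdata = dict(tdata)
                tdata["position"] = tuple(tdata["position"])
                tdata = TargetSpec(**tdata)
            targets.append(tdata)
        data["targets"] = targets
    for key in _ARRAY_FIELDS:
        if data.get(key) is not None:
            data[key] = np.asarray(data[key], dtype=float)
    cfg = SimulationConfig(**data)
    cfg.resolved()  # validate eagerly, with defaults filled
    return cfg


def config_to_dict(cfg: SimulationConfig) -> dict:
    """Plain-JSON-serializable mapping; inverse of ``config_from_dict``."""
    data = {}
    for f in dataclasses.fields(SimulationConfig):
        value = getattr(cfg, f.name)
        if f.name == "coupling":
            value = dataclasses.asdict(value)
        elif f.name == "targets":
            value = [dataclasses.asdict(t) for t in value]
        elif f.name in _ARRAY_FIELDS and value is not None:
            value = np.asarray(value).tolist()
        data[f.name] = value
    return data


def load_config(path) -> SimulationConfig:
    """Load a TOML or JSON config file into a validated SimulationConfig."""
    path = Path(path)
    if path.suffix.lower() == ".toml":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    elif path.suffix.lower() == ".json":
        with open(path) as fh:
            data = json.load(fh)
    else:
        raise ValueError(f"config file must be .toml or .json, got {path.name}")
    return config_from_dict(data)


def save_config(cfg: SimulationConfig, path):
    """Write the resolved config as JSON (round-trips via load_config)."""
    with open(path, "w") as fh:
        json.dump(config_to_dict(cfg), fh, indent=2)


# ---------------------------------------------------------------------------
# presets

@dataclass(frozen=True)
class Preset:
    name: str
    config: SimulationConfig
    note: str
    reduced_scale: bool = False


def _presets() -> dict:
    presets = {}

    def add(name, note, reduced=False, **kw):
        presets[name] = Preset(name, SimulationConfig(**kw), note, reduced)

    # single-agent free motion, spin model, deep ordered phase
    add("fig2-ego-ordered",
        "Single spin-model agent, egocentric frame, deep ordered phase: "
        "a frozen bump at a fixed egocentric deviation yields a circular "
        "orbit.",
        model="spin", frame_policy="ego", N=1, beta=10000.0, steps=2000)
    add("fig2-allo-ordered",
        "Single spin-model agent, allocentric frame, deep ordered phase: "
        "straight-line motion along the bump's world direction.",
        model="spin", frame_policy="allo", N=1, beta=10000.0, steps=2000)

    # single-agent target seeking, spin model
    add("fig3-static-target",
        "Spin-model agent seeking a static central target (h0 = 0.0025); "
        "run stops on reaching 5 units proximity.  Reduced: Ns = 100 "
        "instead of 400 and a 4000-step cap.",
        reduced=True,
        model="spin", frame_policy="allo", N=1, Ns=100, beta=50.0,
        steps=4000, stop_at_target_distance=5.0,
        targets=[TargetSpec(position=(500.0, 500.0), amplitude=0.0025)])
    add("fig3-moving-target",
        "Spin-model agent tracking a fast random-walk target "
        "(v_t = 4 per axis).  Reduced: Ns = 100 instead of 400, 3000 steps "
        "instead of 10000.",
        reduced=True,
        model="spin", frame_policy="allo", N=1, Ns=100, beta=400.0,
        steps=3000,
        targets=[TargetSpec(position=(500.0, 500.0), amplitude=0.0025,
                            motion="random_walk", v_t=4.0)])

    # spin-model collectives
    add("fig4-ego",
        "Spin-model collective, egocentric frames, collective-motion band "
        "of the social attraction.  Reduced: 2000 steps instead of 10000.",
        reduced=True,
        model="spin", frame_policy="ego", N=80, beta=400.0, steps=2000,
        coupling=SocialCoupling(h_t_s=0.16))
    add("fig4-allo",
        "Spin-model collective, allocentric frames, collective-motion band "
        "of the social attraction.  Reduced: 2000 steps instead of 10000.",
        reduced=True,
        model="spin", frame_policy="allo", N=80, beta=400.0, steps=2000,
        coupling=SocialCoupling(h_t_s=0.16))
    add("fig5-aggregation",
        "Spin-model egocentric collective at strong social attraction: "
        "dense, nearly stationary pack.  Reduced: 3000 steps instead of "
        "15000.",
        reduced=True,
        model="spin", frame_policy="ego", N=80, beta=400.0, steps=3000,
        coupling=SocialCoupling(h_t_s=0.4))

    # neural-field collectives
    add("fig9-ego",
        "Neural-field collective, egocentric frames.  Reduced: 8000 steps "
        "instead of 30000.",
        reduced=True,
        model="field", frame_policy="ego", N=80, steps=8000,
        coupling=SocialCoupling(h_t_s=0.24))
    add("fig9-allo",
        "Neural-field collective, allocentric frames, collective-motion "
        "band.  Reduced: 8000 steps instead of 30000.",
        reduced=True,
        model="field", frame_policy="allo", N=80, steps=8000,
        coupling=SocialCoupling(h_t_s=0.24))
    add("fig10-switch",
        "Neural-field collective with random frame switching at the "
        "high-order egocentric probability omega = 0.8.  Reduced: 8000 "
        "steps instead of 20000.",
        reduced=True,
        model="field", frame_policy="switch", omega=0.8, N=80, steps=8000,
        coupling=SocialCoupling(h_t_s=0.08))

    # zero-recurrence control
    add("sv19-zero-recurrence",
        "Neural-field collective without recurrent connections (J = 0), "
        "allocentric frames, small arena: agents coalesce into a slow "
        "aggregate.  Reduced: N = 20 instead of 80.",
        reduced=True,
        model="field", frame_policy="allo", N=20, beta=100.0, L=100.0,
        steps=8000, zero_recurrence=True,
        coupling=SocialCoupling(h_t_s=0.36))
    return presets


PRESETS = _presets()


def get_preset(name: str) -> Preset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None
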