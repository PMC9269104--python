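"""Structured YAML configuration with defaults, validation and echo.

The configuration tree mirrors the model components::

    skier:    body_mass, height, locked
    ski:      length, mass, sidecut_radius, n_rear, n_center, n_front, ...
    snow:     inclination_deg, point
    contact:  k_p, c_p, k_s, mu, v_eps, g_cap, d_eps
    boot:     neutral_angle_deg, k_linear, k_cubic, damping
    muscles:  set ('reduced' | 'full'), overrides
    tracking: w1, w2, w3, grf_weight, n_nodes, solver options
    seed:     master random seed

Unknown keys and invariant violations raise a :class:`ConfigError` naming
the offending key.  Angles are degrees in the file, radians internally.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

from .model_core import ModelError, SkiSpec, build_skier_model, build_ski_model, assemble_full_model
from .muscles import BootParams, default_muscle_set, full_muscle_layout
from .ski_snow import ContactParams, SnowPlane
from .system import SkiSystem

__all__ = ["ConfigError", "Config", "load_config", "default_config", "build_system"]


class ConfigError(ModelError):
    """Invalid configuration; the message names the key and constraint."""


_DEFAULTS = {
    "skier": {"body_mass": 75.0, "height": 1.78, "locked": []},
    "ski": {
        "length": 2.02, "mass": 2.1, "sidecut_radius": 32.0,
        "n_rear": 7, "n_center": 1, "n_front": 10, "waist_width": 0.065,
        "stiffness_center": 2000.0, "stiffness_tip": 300.0, "damping_ratio": 0.03,
    },
    "snow": {"inclination_deg": 15.0, "point": [0.0, 0.0, 0.0]},
    "contact": {
        "k_p": 3.0e4, "c_p": 0.2, "k_s": 4.0e5, "mu": 0.1,
        "v_eps": 0.05, "g_cap": 2.0, "d_eps": 1e-3,
    },
    "boot": {"neutral_angle_deg": 15.0, "k_linear": 15.0, "k_cubic": 4000.0,
             "damping": 1.5},
    "muscles": {"set": "reduced"},
    "tracking": {"w1": 1.0, "w2": 0.1, "w3": 1e-4, "grf_weight": 0.0,
                 "n_nodes": None, "max_iter": 150, "tol_feas": 1e-4},
    "seed": 0,
}

#: physical invariants checked after merging (key, predicate, description)
_CHECKS = [
    ("skier.body_mass", lambda v: v > 0, "must be > 0"),
    ("skier.height", lambda v: v > 0, "must be > 0"),
    ("ski.length", lambda v: v > 0, "must be > 0"),
    ("ski.mass", lambda v: v > 0, "must be > 0"),
    ("ski.sidecut_radius", lambda v: v > 2, "must exceed 2 m"),
    ("contact.mu", lambda v: v >= 0, "must be >= 0"),
    ("contact.k_p", lambda v: v >= 0, "must be >= 0"),
    ("contact.k_s", lambda v: v >= 0, "must be >= 0"),
    ("contact.v_eps", lambda v: v > 0, "must be > 0"),
    ("tracking.w1", lambda v: v >= 0, "must be >= 0"),
    ("tracking.w2", lambda v: v >= 0, "must be >= 0"),
    ("tracking.w3", lambda v: v > 0, "must be > 0"),
]


@dataclass
class Config:
    """A validated configuration tree."""

    tree: dict = field(default_factory=dict)

    def __getitem__(self, dotted: str):
        node = self.tree
        for part in dotted.split("."):
            node = node[part]
        return node

    @property
    def seed(self) -> int:
        return int(self.tree["seed"])

    def digest(self) -> str:
        """Stable hash of the effective configuration (for run metadata)."""
        return hashlib.sha256(
            json.dumps(self.tree, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _merge(defaults: dict, override: dict, prefix: str = "") -> dict:
    out = {}
    for key, dval in defaults.items():
        if isinstance(dval, dict):
            sub = override.get(key, {})
            if not isinstance(sub, dict):
                raise ConfigError(f"config key {prefix}{key}: expected a mapping")
            out[key] = _merge(dval, sub, f"{prefix}{key}.")
        else:
            out[key] = override.get(key, dval)
    for key in override:
        if key not in defaults:
            raise ConfigError(f"unknown config key {prefix}{key!r}")
    return out


def default_config() -> Config:
    return Config(_merge(_DEFAULTS, {}))


def load_config(path=None, overrides: dict | None = None) -> Config:
    """Load and validate a YAML config; missing keys take defaults."""
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
    if overrides:
        data = _merge_raw(data, overrides)
    cfg = Config(_merge(_DEFAULTS, data))
    for dotted, pred, msg in _CHECKS:
        val = cfg[dotted]
        if not pred(val):
            raise ConfigError(f"config key {dotted} = {val!r}: {msg}")
    return cfg


def _merge_raw(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge_raw(out[k], v)
        else:
            out[k] = v
    return out


def build_system(cfg: Config) -> SkiSystem:
    """Construct the full musculoskeletal system a config describes."""
    t = cfg.tree
    skier = build_skier_model(dict(t["skier"]))
    spec = SkiSpec(**t["ski"])
    model = assemble_full_model(skier, build_ski_model(spec), build_ski_model(spec))
    if t["muscles"]["set"] == "reduced":
        muscles = default_muscle_set(model)
    elif t["muscles"]["set"] == "full":
        muscles = full_muscle_layout(model)
    else:
        raise ConfigError(f"config key muscles.set: unknown set {t['muscles']['set']!r}")
    snow = SnowPlane.inclined(np.deg2rad(t["snow"]["inclination_deg"]),
                              t["snow"]["point"])
    contact = ContactParams(**t["contact"])
    boot = BootParams(
        neutral_angle=np.deg2rad(t["boot"]["neutral_angle_deg"]),
        k_linear=t["boot"]["k_linear"], k_cubic=t["boot"]["k_cubic"],
        damping=t["boot"]["damping"],
    )
    return SkiSystem(model, muscles, snow, contact, boot)
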