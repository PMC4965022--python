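"""Configuration loading and validation.

One YAML file describes a complete scenario: biochemical parameters,
materials, schedule, phantom geometry, resection plan and pipeline options.
User files are deep-merged over the versioned default parameter file shipped
with the package (``data/defaults.yaml``); every parameter is validated
against its type invariants and the homeostasis constraints are applied
(and logged) when the file supplies inconsistent rates.
"""

from __future__ import annotations

import copy
import hashlib
import logging
from importlib import resources
from pathlib import Path

import yaml

from .biology import BioParams
from .coupling import DAY, Schedule
from .mechanics import ActiveParams, Material, MaterialSet, SkinMaterial
from .mesh import ResectionPlan

__all__ = ["Config", "ConfigError", "load_config", "default_bio_params"]

log = logging.getLogger(__name__)

_KNOWN_TOP = {
    "biology", "materials", "schedule", "phantom", "resection", "mesh",
    "mechanics", "heal", "pose",
}


class ConfigError(ValueError):
    """Invalid configuration; the message lists every failure found."""


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _defaults() -> dict:
    text = resources.files("mammosim").joinpath("data/defaults.yaml").read_text()
    return yaml.safe_load(text)


class Config:
    """Validated parameter bundle for one scenario."""

    def __init__(self, raw: dict, source: str = "<defaults>"):
        unknown = set(raw) - _KNOWN_TOP
        errors = [f"unknown top-level key {k!r}" for k in sorted(unknown)]
        self.raw = raw
        self.source = source
        self.sha256 = hashlib.sha256(
            yaml.safe_dump(raw, sort_keys=True).encode()
        ).hexdigest()[:16]
        try:
            self.bio = BioParams(**raw["biology"])
        except (TypeError, ValueError) as exc:
            errors.append(f"biology: {exc}")
            self.bio = None
        try:
            mats = raw["materials"]
            self.materials = MaterialSet(
                adipose=Material(**mats["adipose"]),
                fibroglandular=Material(**mats["fibroglandular"]),
                wound=Material(**mats["wound"]),
                skin=SkinMaterial(**mats["skin"]),
                active=ActiveParams(**mats["active"]),
                damage_volumetric=bool(mats.get("damage_volumetric", False)),
            )
            self.materials.validate()
        except (TypeError, ValueError, KeyError) as exc:
            errors.append(f"materials: {exc!r}")
            self.materials = None
        try:
            sch = raw["schedule"]
            self.schedule = Schedule(
                dt_bio=float(sch["dt_bio"]),
                dt_mech=float(sch["dt_mech_days"]) * DAY,
                t_end=float(sch["t_end_days"]) * DAY,
                cfl_safety=float(sch.get("cfl_safety", 0.5)),
                scale=float(sch.get("scale", 1.0)),
            )
        except (TypeError, ValueError, KeyError) as exc:
            errors.append(f"schedule: {exc!r}")
            self.schedule = None
        try:
            res = raw["resection"]
            self.resection = ResectionPlan(
                axis_point=tuple(res["axis_point"]),
                axis_direction=tuple(res["axis_direction"]),
                radius=float(res["radius"]),
            )
        except (TypeError, ValueError, KeyError) as exc:
            errors.append(f"resection: {exc!r}")
            self.resection = None
        self.phantom = dict(raw.get("phantom", {}))
        self.mesh_opts = dict(raw.get("mesh", {}))
        self.mechanics = dict(raw.get("mechanics", {}))
        self.heal = dict(raw.get("heal", {}))
        self.pose = dict(raw.get("pose", {}))
        if errors:
            raise ConfigError(
                f"invalid configuration ({source}):\n  " + "\n  ".join(errors)
            )

    def make_phantom(self, seed: int | None = None):
        from .mesh import generate_phantom

        kw = dict(self.phantom)
        if seed is not None:
            kw["seed"] = seed
        kw.setdefault("skin_thickness", self.mesh_opts.get("skin_thickness", 1.5e-3))
        return generate_phantom(**kw)

    def heal_gravity(self):
        from .pipeline import pose_vector

        return pose_vector(
            self.heal.get("gravity", "none"),
            float(self.mechanics.get("gravity_magnitude", 9.81)),
        )


def load_config(path: str | Path | None = None) -> Config:
    """Load and validate a scenario file (merged over the packaged defaults)."""
    raw = _defaults()
    source = "<defaults>"
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        user = yaml.safe_load(p.read_text()) or {}
        if not isinstance(user, dict):
            raise ConfigError(f"config file {p} is not a mapping")
        raw = _deep_merge(raw, user)
        source = str(p)
    return Config(raw, source)


def default_bio_params() -> BioParams:
    """The versioned default biochemical parameter set."""
    return BioParams(**_defaults()["biology"])
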