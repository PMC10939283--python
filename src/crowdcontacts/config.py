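"""YAML serialization of location configurations.

Schema (one document per area, or a mapping of areas)::

    name: workplace
    zone: personal              # intimate | personal | social
    duration_h: 8.0
    demographic_weights: [w0, ..., w15]        # sum to 1
    speed_dist:    {mean: [...16], sd: [...16]}  # m/s per age bin
    distance_dist: {mean: [...16], sd: [...16]}  # m per age bin
    mass_dist: {mean: 70.0, sd: 12.0}            # kg, area level
    mass_range: [30.0, 130.0]
    radius: 0.2                                  # m
    relaxation_time: 0.5                         # s
    force: {a_soc: 700.0, beta_soc: 0.08, gamma: 0.2,
            a_obs: 2000.0, beta_obs: 0.08, d_obs: 0.5}   # N / m / -
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .population import (
    ForceParams,
    GaussianSpec,
    LocationConfig,
    PROXEMIC_ZONES,
)

__all__ = ["location_to_dict", "location_from_dict", "save_configs", "load_configs"]


def location_to_dict(cfg: LocationConfig) -> dict:
    return {
        "name": cfg.name,
        "zone": cfg.zone.name,
        "duration_h": cfg.duration_h,
        "demographic_weights": [float(w) for w in cfg.demographic_weights],
        "speed_dist": {
            "mean": [g.mean for g in cfg.speed_dist],
            "sd": [g.sd for g in cfg.speed_dist],
        },
        "distance_dist": {
            "mean": [g.mean for g in cfg.distance_dist],
            "sd": [g.sd for g in cfg.distance_dist],
        },
        "mass_dist": {"mean": cfg.mass_dist.mean, "sd": cfg.mass_dist.sd},
        "mass_range": list(cfg.mass_range),
        "radius": cfg.radius,
        "relaxation_time": cfg.relaxation_time,
        "force": {
            "a_soc": cfg.force.a_soc,
            "beta_soc": cfg.force.beta_soc,
            "gamma": cfg.force.gamma,
            "a_obs": cfg.force.a_obs,
            "beta_obs": cfg.force.beta_obs,
            "d_obs": cfg.force.d_obs,
        },
    }


def location_from_dict(d: dict) -> LocationConfig:
    def gaussians(block):
        return tuple(GaussianSpec(float(m), float(s)) for m, s in zip(block["mean"], block["sd"]))

    return LocationConfig(
        name=d["name"],
        zone=PROXEMIC_ZONES[d["zone"]],
        duration_h=float(d["duration_h"]),
        demographic_weights=tuple(float(w) for w in d["demographic_weights"]),
        speed_dist=gaussians(d["speed_dist"]),
        distance_dist=gaussians(d["distance_dist"]),
        mass_dist=GaussianSpec(float(d["mass_dist"]["mean"]), float(d["mass_dist"]["sd"])),
        mass_range=tuple(d.get("mass_range", (30.0, 130.0))),
        radius=float(d.get("radius", 0.2)),
        relaxation_time=float(d.get("relaxation_time", 0.5)),
        force=ForceParams(**d.get("force", {})),
    )


def save_configs(configs: dict[str, LocationConfig], path: str | Path) -> None:
    data = {name: location_to_dict(cfg) for name, cfg in configs.items()}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def load_configs(path: str | Path) -> dict[str, LocationConfig]:
    data = yaml.safe_load(Path(path).read_text())
    return {name: location_from_dict(d) for name, d in data.items()}
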