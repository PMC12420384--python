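"""Pipeline configuration: YAML loading, validation and normalization.

One YAML file configures every stage.  Validation reports *all* violations
at once (unknown keys, type errors, cross-field constraints) rather than
failing at the first, and fills documented defaults for anything omitted;
omitted per-stage seeds are filled and warned about so every stochastic
stage is explicitly reproducible.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigValidationError", "validate_config", "DEFAULT_CONFIG"]


class ConfigValidationError(ValueError):
    """Carries the full list of validation errors."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))


DEFAULT_CONFIG: dict = {
    "output_dir": "occuscale_out",
    "landscape": {
        "extent_km": [40.0, 40.0],
        "pixel_size_km": 2.0,
        "n_regions": 2,
        "n_topo_units": 2,
        "elevation_range_m": [0.0, 3500.0],
        "n_ridges": 3,
    },
    "species": {
        "n_species": 150,
        "n_families": 30,
        "endemic_fraction": 0.3,
    },
    "design": {
        "n_cluster_pairs": 40,
        "points_per_cluster": 3,
        "n_visits": 4,
        "n_observers": 3,
    },
    "model": {
        "reduced": True,
        "method": "laplace",
        "n_draws": 100,
        "maxiter": 1000,
    },
    "sensitivity": {
        "tau": 0.2,
        "quantiles": [0.25, 0.5, 0.75],
        "n_sequences": 1000,
        "n_draws": 100,
    },
    "scaling": {
        "areas_km2": [290.0, 860.0, 2600.0, 7800.0, 23000.0, 70000.0],
        "tau": 0.2,
        "quantile": 0.5,
        "regrid_per_draw": True,
    },
    "gdm": {
        "response": "sorensen",
        "n_bootstrap": 400,
        "detection_corrected": False,
        "site_predictors": ["elevation_m", "annual_precip_mm"],
        "pair_predictors": ["geo_km", "valley_m", "mountain_m"],
    },
    "stages": {
        "simulate": True,
        "features": True,
        "fit": True,
        "sensitivity": True,
        "scaling": True,
        "gdm": True,
    },
    "seeds": {
        "simulate": 1,
        "fit": 2,
        "sensitivity": 3,
        "scaling": 4,
        "gdm": 5,
    },
}


@dataclass
class PipelineConfig:
    """Validated, fully-defaulted configuration."""

    data: dict
    warnings: list = field(default_factory=list)

    def __getitem__(self, key):
        return self.data[key]

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return validate_config(yaml.safe_load(Path(path).read_text()) or {})


def _merge(defaults: dict, user: dict, prefix: str, errors: list) -> dict:
    out = copy.deepcopy(defaults)
    for key, val in user.items():
        if key not in defaults:
            errors.append(f"unknown key {prefix + key!r}")
            continue
        if isinstance(defaults[key], dict):
            if not isinstance(val, dict):
                errors.append(f"{prefix + key!r} must be a mapping")
            else:
                out[key] = _merge(defaults[key], val, prefix + key + ".", errors)
        else:
            out[key] = val
    return out


def _check_number(cfg, section, key, errors, lo=None, hi=None, open_bounds=False):
    v = cfg[section][key]
    if not isinstance(v, (int, float)) or isinstance(v, bool):
        errors.append(f"{section}.{key} must be a number, got {v!r}")
        return
    if lo is not None and (v <= lo if open_bounds else v < lo):
        errors.append(f"{section}.{key} = {v} violates the bound > {lo}" if open_bounds
                      else f"{section}.{key} = {v} violates the bound >= {lo}")
    if hi is not None and (v >= hi if open_bounds else v > hi):
        errors.append(f"{section}.{key} = {v} violates the bound < {hi}" if open_bounds
                      else f"{section}.{key} = {v} violates the bound <= {hi}")


def validate_config(user: dict | None = None) -> PipelineConfig:
    """Normalize and validate a configuration mapping.

    Raises :class:`ConfigValidationError` listing every violation; returns
    a :class:`PipelineConfig` whose ``warnings`` list notes filled-in seeds.
    """
    user = user or {}
    errors: list = []
    warnings: list = []
    if not isinstance(user, dict):
        raise ConfigValidationError(["configuration root must be a mapping"])
    cfg = _merge(DEFAULT_CONFIG, user, "", errors)

    user_seeds = user.get("seeds", {}) if isinstance(user.get("seeds", {}), dict) else {}
    for stage, default in DEFAULT_CONFIG["seeds"].items():
        if stage not in user_seeds:
            warnings.append(f"seeds.{stage} omitted; using default {default}")

    _check_number(cfg, "sensitivity", "tau", errors, lo=0, hi=1, open_bounds=True)
    _check_number(cfg, "scaling", "tau", errors, lo=0, hi=1, open_bounds=True)
    _check_number(cfg, "scaling", "quantile", errors, lo=0, hi=1, open_bounds=True)
    _check_number(cfg, "species", "n_species", errors, lo=1)
    _check_number(cfg, "design", "n_cluster_pairs", errors, lo=1)
    _check_number(cfg, "gdm", "n_bootstrap", errors, lo=1)
    _check_number(cfg, "sensitivity", "n_sequences", errors, lo=1)

    areas = cfg["scaling"]["areas_km2"]
    if not isinstance(areas, (list, tuple)) or not areas:
        errors.append("scaling.areas_km2 must be a non-empty list")
    else:
        if any((not isinstance(a, (int, float))) or a <= 0 for a in areas):
            errors.append("scaling.areas_km2 entries must be positive numbers")
        elif list(areas) != sorted(areas):
            errors.append("scaling.areas_km2 must be sorted ascending")

    if cfg["gdm"]["response"] not in ("sorensen", "simpson"):
        errors.append("gdm.response must be 'sorensen' or 'simpson'")
    if cfg["model"]["method"] not in ("map", "laplace", "emcee"):
        errors.append("model.method must be one of map/laplace/emcee")
    for stage, flag in cfg["stages"].items():
        if not isinstance(flag, bool):
            errors.append(f"stages.{stage} must be a boolean")
    for stage, sd in cfg["seeds"].items():
        if not isinstance(sd, int) or isinstance(sd, bool):
            errors.append(f"seeds.{stage} must be an integer")

    if errors:
        raise ConfigValidationError(errors)
    return PipelineConfig(data=cfg, warnings=warnings)
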