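"""Structured YAML configuration for the synthetic experiments.

A config file has sections ``design``, ``species`` (with ``AC`` and ``BM``
subsections), ``irrigation``, ``noise`` and a top-level ``seed`` and
``experiment``; every default is overridable.  Missing sections fall back
to the package defaults for the chosen experiment.
"""

from __future__ import annotations

import copy
from dataclasses import asdict
from pathlib import Path
from typing import Any, Mapping

import yaml

from .generate import (
    ExperimentDesign,
    NoiseModel,
    resilience_design,
    resistance_design,
)
from .growth import SpeciesParams, default_species_params


def default_config(experiment: str) -> dict[str, Any]:
    """The full default configuration for one experiment, as plain data."""
    species = {sid: asdict(p) for sid, p in default_species_params().items()}
    if experiment == "resistance":
        design = {"n_blocks": 4, "harvest_day": 50}
        irrigation = {
            "evaporation_daily": 0.055,
            "transpiration_onset": 21,
            "transpiration_slope": 0.004,
            "transpiration_cap": 0.08,
        }
    elif experiment == "resilience":
        design = {"n_blocks": 5, "harvest_days": [23, 37, 44, 58, 72]}
        irrigation = {
            "pre_event_total": 0.98,
            "event_start": 23,
            "event_days": 14,
            "event_fraction": 0.33,
            "post_event_daily": 0.09,
        }
    else:
        raise ValueError("experiment must be 'resistance' or 'resilience'")
    return {
        "experiment": experiment,
        "design": design,
        "species": species,
        "irrigation": irrigation,
        "noise": {"sd_block": 0.10, "cv_pot": 0.07},
        "seed": None,
    }


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None, experiment: str | None = None) -> dict[str, Any]:
    """Load a YAML config merged over the defaults.

    The experiment label comes from the file unless overridden by
    ``experiment``; with no file at all, the defaults are returned.
    """
    user: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            user = yaml.safe_load(fh) or {}
        if not isinstance(user, dict):
            raise ValueError(f"config file {path} must contain a mapping")
    exp = experiment or user.get("experiment")
    if exp is None:
        raise ValueError("config must state the experiment ('resistance' or 'resilience')")
    cfg = _deep_merge(default_config(exp), user)
    cfg["experiment"] = exp
    return cfg


def build_from_config(cfg: Mapping[str, Any]):
    """Materialize (design, species params, noise, seed) from a config dict."""
    exp = cfg["experiment"]
    species = {
        sid: SpeciesParams(**params) for sid, params in cfg["species"].items()
    }
    noise = NoiseModel(**cfg["noise"])
    seed = cfg.get("seed")
    d = cfg["design"]
    irr = cfg["irrigation"]
    if exp == "resistance":
        design = resistance_design(
            n_blocks=int(d["n_blocks"]),
            harvest_day=int(d["harvest_day"]),
            seed=seed,
            **irr,
        )
    else:
        design = resilience_design(
            n_blocks=int(d["n_blocks"]),
            harvest_days=tuple(int(x) for x in d["harvest_days"]),
            seed=seed,
            **irr,
        )
    return design, species, noise, seed
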