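"""Run configuration: TOML loading, validation, provenance records."""

from __future__ import annotations

import hashlib
import json
import tomllib
from pathlib import Path

from .pipeline import DEFAULT_PARAMS

_KNOWN_SECTIONS = {
    "paths": {"output_dir", "sections", "records", "rois", "overview"},
    "channels": None,  # free plane-index → label mapping
    "params": set(DEFAULT_PARAMS),
    "phantom": {
        "image_size_px", "pixel_size_um", "vessels", "endfeet", "wall_gap_arcs",
        "gaussian_sd", "poisson_scale", "background_level", "stage_position_um", "seed",
    },
    "cohort": {
        "animals_per_group", "vessels_per_animal_level", "samples_per_vessel",
        "median_width_um", "sigma_within", "sigma_vessel", "animal_sigma",
        "effect_group", "effect_level", "effect_multiplier", "effect_quintiles",
    },
    "overrides": {"vessel_include", "vessel_exclude", "endfoot_include",
                  "endfoot_exclude", "endfoot_manual_ids"},
    "alignment": {"residual_um"},
    "map": {"group", "reference_label"},
}


def load_config(path: str | Path) -> dict:
    """Load and validate a TOML run config; unknown keys are rejected."""
    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    unknown_sections = set(cfg) - set(_KNOWN_SECTIONS)
    if unknown_sections:
        raise ValueError(f"unknown config section(s): {sorted(unknown_sections)}")
    for section, keys in _KNOWN_SECTIONS.items():
        if keys is None or section not in cfg:
            continue
        unknown = set(cfg[section]) - keys
        if unknown:
            raise ValueError(f"unknown key(s) in [{section}]: {sorted(unknown)}")
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def write_provenance(output_dir: str | Path, cfg: dict, seed: int | None, command: str) -> None:
    """Drop a provenance record next to the outputs (reproducibility contract)."""
    from . import __version__

    record = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "config_hash": config_hash(cfg),
        "config": cfg,
    }
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"provenance_{command}.json", "w") as fh:
        json.dump(record, fh, indent=1, default=str)
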