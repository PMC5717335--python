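"""YAML pipeline configuration with strict schema validation.

Unknown keys anywhere in the file are rejected before any stage runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Any

import yaml

from kinquant.segmentation import SegmentationParams
from kinquant.simulate import SimImageParams


class ConfigError(ValueError):
    pass


_TOP_KEYS = {"seed", "output_dir", "simulate", "segmentation", "quantify", "compare", "volcano"}
_SIMULATE_KEYS = {"n_cells_per_group", "depleted_fraction", "image"}
_QUANTIFY_KEYS = {"manifest", "channels", "summary_method", "reference_condition"}
_COMPARE_KEYS = {"cells_csv", "group_by", "alpha_normality", "bonferroni"}
_VOLCANO_KEYS = {"lfq_table", "alpha", "min_valid_per_group", "annotations", "column_map", "sign_sensitive"}


def _check_keys(section: dict, allowed: set[str], where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown keys in {where}: {sorted(unknown)}")


def _dataclass_keys(cls) -> set[str]:
    return {f.name for f in dataclasses.fields(cls)}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a pipeline config file."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"{path}: invalid YAML: {exc}") from exc
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    _check_keys(raw, _TOP_KEYS, "top level")

    cfg: dict[str, Any] = {
        "seed": int(raw.get("seed", 0)),
        "output_dir": Path(raw.get("output_dir", "kinquant_out")),
    }

    sim = raw.get("simulate", {}) or {}
    _check_keys(sim, _SIMULATE_KEYS, "simulate")
    image = dict(sim.get("image", {}) or {})
    _check_keys(image, _dataclass_keys(SimImageParams), "simulate.image")
    for key in ("grid_dims", "voxel_size", "channels", "nuclear_center_um", "nuclear_semiaxes_um"):
        if key in image and image[key] is not None:
            image[key] = tuple(image[key])
    try:
        cfg["simulate"] = {
            "n_cells_per_group": int(sim.get("n_cells_per_group", 10)),
            "depleted_fraction": float(sim.get("depleted_fraction", 0.0)),
            "image": SimImageParams(**image),
        }
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"simulate section invalid: {exc}") from exc

    seg = raw.get("segmentation", {}) or {}
    _check_keys(seg, _dataclass_keys(SegmentationParams), "segmentation")
    try:
        cfg["segmentation"] = SegmentationParams(**seg)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"segmentation section invalid: {exc}") from exc

    quant = raw.get("quantify", {}) or {}
    _check_keys(quant, _QUANTIFY_KEYS, "quantify")
    cfg["quantify"] = {
        "manifest": quant.get("manifest"),
        "channels": list(quant.get("channels", [])),
        "summary_method": quant.get("summary_method", "mean"),
        "reference_condition": quant.get("reference_condition"),
    }

    comp = raw.get("compare", {}) or {}
    _check_keys(comp, _COMPARE_KEYS, "compare")
    cfg["compare"] = {
        "cells_csv": comp.get("cells_csv"),
        "group_by": comp.get("group_by", "condition"),
        "alpha_normality": float(comp.get("alpha_normality", 0.05)),
        "bonferroni": bool(comp.get("bonferroni", False)),
    }
    if cfg["compare"]["group_by"] not in ("condition", "phase"):
        raise ConfigError("compare.group_by must be 'condition' or 'phase'")

    vol = raw.get("volcano", {}) or {}
    _check_keys(vol, _VOLCANO_KEYS, "volcano")
    cfg["volcano"] = {
        "lfq_table": vol.get("lfq_table"),
        "alpha": float(vol.get("alpha", 0.05)),
        "min_valid_per_group": int(vol.get("min_valid_per_group", 2)),
        "annotations": vol.get("annotations"),
        "column_map": vol.get("column_map"),
        "sign_sensitive": bool(vol.get("sign_sensitive", True)),
    }
    cfg["_hash"] = hashlib.sha256(path.read_bytes()).hexdigest()
    return cfg


def provenance_record(cfg: dict[str, Any], stage: str, counts: dict[str, Any]) -> dict[str, Any]:
    """Machine-readable run record: config hash, seed, versions, stage counts."""
    import numpy
    import pandas
    import scipy
    import skimage

    import kinquant

    return {
        "stage": stage,
        "config_sha256": cfg.get("_hash"),
        "seed": cfg.get("seed"),
        "versions": {
            "kinquant": kinquant.__version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "scikit-image": skimage.__version__,
        },
        "counts": counts,
    }


def write_provenance(record: dict[str, Any], path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(record, indent=2, default=str) + "\n")
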