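"""Scenario configuration files, profile CSV output, metrics JSON.

Config files are JSON or YAML with one scenario per file. Keys carry units
in their names (``dose_mg``, ``perfusion_ml_min_100g``, ...) to keep unit
errors loud, and unknown keys are rejected. A config either spells out the
whole scenario or names a packaged fixture plus overrides::

    {"fixture": "arl_im_400", "overrides": {"icl": {"enabled": false}}}

Every field that falls back to a package default is logged with its source.
"""

from __future__ import annotations

import json
import logging
from dataclasses import fields as dc_fields
from pathlib import Path
from typing import Any, Mapping, Optional

import numpy as np
import yaml

from .depot import DepotPhysiology, Scenario, SimulationResult
from .dissolution import DissolutionSettings, ParticleSizeDistribution
from .drugs import DispositionParams, DrugProperties, FormulationDose
from .fixtures import build_scenario
from .icl import ICLParams
from .metrics import PKMetrics

__all__ = ["load_scenario", "scenario_from_dict", "write_profile", "write_metrics"]

log = logging.getLogger("depotsim")

# config key -> (dataclass field, block class) maps; unit suffixes are part
# of the external contract, internal field names stay terse
_BLOCKS: dict[str, tuple[type, dict[str, str]]] = {
    "drug": (
        DrugProperties,
        {
            "name": "name",
            "mw_g_mol": "mw",
            "logp": "logp",
            "pka": "pka",
            "rbp": "rbp",
            "fup": "fup",
            "s_ref_mg_ml": "s_ref",
            "ph_ref": "ph_ref",
            "solubility_factor": "solubility_factor",
            "d_aq_cm2_s": "d_aq_override",
        },
    ),
    "parent": (DrugProperties, None),  # same key map as drug
    "disposition": (
        DispositionParams,
        {
            "vc_l_kg": "vc",
            "clh_l_h_kg": "clh",
            "k12_1_h": "k12",
            "k21_1_h": "k21",
            "k13_1_h": "k13",
            "k31_1_h": "k31",
            "body_weight_kg": "body_weight",
        },
    ),
    "dose": (
        FormulationDose,
        {
            "ar_equivalent_dose_mg": "ar_equivalent_dose",
            "route": "route",
            "is_prodrug": "is_prodrug",
            "injection_volume_ml": "injection_volume",
            "infusion_duration_h": "infusion_duration",
        },
    ),
    "depot": (
        DepotPhysiology,
        {
            "kp": "kp",
            "fut": "fut",
            "perfusion_ml_min_100g": "perfusion",
            "ecf_fraction": "ecf_fraction",
            "v_depot_ml": "v_depot",
            "site_ph": "site_ph",
        },
    ),
    "psd": (
        ParticleSizeDistribution,
        {
            "mean_radius_um": "mean_radius_um",
            "sd_radius_um": "sd_radius_um",
            "n_bins": "n_bins",
            "dv10_um": "dv10_um",
            "dv50_um": "dv50_um",
            "dv90_um": "dv90_um",
            "density_g_cm3": "density",
        },
    ),
    "dissolution": (
        DissolutionSettings,
        {"h_uwl_um": "h_uwl_um", "h_rule": "h_rule", "d_aq_cm2_s": "d_aq"},
    ),
    "icl": (
        ICLParams,
        {
            "a_cm_h": "a",
            "b_1_h": "b",
            "t_lag_h": "t_lag",
            "surface_area_cm2": "surface_area",
            "d_icl_cm2_s": "d_icl",
            "fu_icl": "fu_icl",
            "kappa": "kappa",
            "enabled": "enabled",
        },
    ),
}
_BLOCKS["parent"] = (DrugProperties, _BLOCKS["drug"][1])

_TOP_KEYS = {
    "name": "name",
    "horizon_h": "horizon_h",
    "output_dt_h": "output_dt_h",
    "rtol": "rtol",
    "atol": "atol",
}


def _build_block(block: str, data: Mapping[str, Any]):
    cls, keymap = _BLOCKS[block]
    unknown = set(data) - set(keymap)
    if unknown:
        raise ValueError(f"unknown keys in '{block}' block: {sorted(unknown)}")
    kwargs = {keymap[k]: v for k, v in data.items()}
    obj = cls(**kwargs)
    given = set(kwargs)
    for f in dc_fields(cls):
        source = "user" if f.name in given else "default"
        log.debug("config %s.%s = %r (%s)", block, f.name, getattr(obj, f.name), source)
    return obj


def scenario_from_dict(data: Mapping[str, Any]) -> Scenario:
    """Build a validated :class:`Scenario` from a config mapping."""
    if "fixture" in data:
        extra = set(data) - {"fixture", "overrides"}
        if extra:
            raise ValueError(
                f"unknown keys beside 'fixture'/'overrides': {sorted(extra)}"
            )
        scenario = build_scenario(data["fixture"])
        for block, over in (data.get("overrides") or {}).items():
            if block in _TOP_KEYS:
                setattr(scenario, _TOP_KEYS[block], over)
                continue
            if block not in _BLOCKS:
                raise ValueError(f"unknown override block '{block}'")
            cls, keymap = _BLOCKS[block]
            target = getattr(scenario, block)
            if target is None:
                raise ValueError(f"fixture has no '{block}' block to override")
            unknown = set(over) - set(keymap)
            if unknown:
                raise ValueError(f"unknown keys in '{block}' override: {sorted(unknown)}")
            for k, v in over.items():
                setattr(target, keymap[k], v)
                log.debug("override %s.%s = %r (user)", block, keymap[k], v)
        scenario.__post_init__()
        return scenario

    unknown = set(data) - set(_BLOCKS) - set(_TOP_KEYS)
    if unknown:
        raise ValueError(f"unknown top-level keys: {sorted(unknown)}")
    required = {"drug", "disposition", "dose"}
    missing = required - set(data)
    if missing:
        raise ValueError(f"missing required blocks: {sorted(missing)}")
    kwargs: dict[str, Any] = {}
    for block in data.keys() & _BLOCKS.keys():
        kwargs[block] = _build_block(block, data[block])
    for key in data.keys() & _TOP_KEYS.keys():
        kwargs[_TOP_KEYS[key]] = data[key]
    return Scenario(**kwargs)


def load_scenario(path: str | Path) -> Scenario:
    """Parse and validate a scenario config file (JSON or YAML)."""
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        required = "drug, disposition, dose (or fixture)"
        raise ValueError(f"empty config {path}; required blocks: {required}")
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"config {path} must contain a mapping")
    return scenario_from_dict(data)


def write_profile(result: SimulationResult, path: str | Path, stride: int = 1) -> Path:
    """Write the simulated profile as CSV, round-trippable to 12 digits.

    ``stride`` subsamples the dense output grid (every ``stride``-th point;
    the final point is always kept).
    """
    path = Path(path)
    n = len(result.t)
    idx = np.unique(np.r_[np.arange(0, n, max(stride, 1)), n - 1]) if n else []
    cols = np.column_stack(
        [
            result.t[idx],
            result.cp[idx],
            result.icl_thickness_cm[idx] * 1e4,  # cm -> um
            result.solid_mg[idx],
            result.dissolved_mg[idx],
            result.absorbed_mg[idx],
        ]
    )
    header = "time_h,cp_ng_per_mL,icl_thickness_um,solid_mg,dissolved_mg,absorbed_mg"
    np.savetxt(path, cols, delimiter=",", header=header, comments="", fmt="%.12g")
    return path


def write_metrics(metrics: PKMetrics, path: str | Path, extra: Optional[Mapping] = None) -> Path:
    """Write PK metrics (and optional extras such as fold errors) as JSON."""
    path = Path(path)
    payload = {
        "cmax_ng_ml": metrics.cmax,
        "tmax_h": metrics.tmax,
        "auc0t_ng_h_ml": metrics.auc0t,
        "t_last_h": metrics.t_last,
    }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
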