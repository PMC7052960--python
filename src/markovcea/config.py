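"""Configuration: defaults, YAML loading and object construction.

A single nested-mapping config drives every CLI command.  User files
override defaults key by key; CLI flags override config keys.
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .lifetable import LifeTable, default_life_table, load_life_table
from .model import CostSet, ModelConfig, Strategy, TransitionParams, UtilitySet

__all__ = ["default_config", "load_config", "config_digest", "ModelBundle", "build_bundle"]

_IMAGING_COSTS = {"NaF": 302.0, "FCH": 881.0, "DW-MRI": 112.0}

_ACCURACY = {
    "onsite": {"NaF": (5 / 7, 44 / 48), "FCH": (3 / 7, 48 / 48), "DW-MRI": (4 / 7, 40 / 48)},
    "central": {"NaF": (6 / 7, 45 / 48), "FCH": (4 / 7, 47 / 48), "DW-MRI": (3 / 7, 45 / 48)},
}


def default_config() -> dict:
    """Full default configuration; every parameter is overridable."""
    tp = TransitionParams()
    cs = CostSet()
    us = UtilitySet()
    strategies = {
        reading: [
            {
                "name": name,
                "se": se,
                "sp": sp,
                "imaging_cost": _IMAGING_COSTS[name],
                "n_positive": 7,
                "n_negative": 48,
            }
            for name, (se, sp) in table.items()
        ]
        for reading, table in _ACCURACY.items()
    }
    return {
        "model": {
            "start_age": 70,
            "cohort_size": 10_000,
            "discount_rate": 0.04,
            "horizon": None,
            "counting_method": "life-table",
            "fp_policy": "persistent-m1",
            "fp_cost": "m1bcr_subsequent",
            "fn_cost": "m0bcr_first_year",
            "fn_tunnel": "m1-row",
            "joint_progression": "combine",
            "discount_first_cycle": False,
            "on_invalid_row": "error",
        },
        "prevalence": 7 / 55,
        "transitions": {
            "p_m0bcr_m1bcr": tp.p_m0bcr_m1bcr,
            "p_m0bcr_m0crpc": tp.p_m0bcr_m0crpc,
            "p_m0crpc_m1crpc": tp.p_m0crpc_m1crpc,
            "p_m1bcr_m1crpc": tp.p_m1bcr_m1crpc,
            "excess_death_m0crpc": tp.excess_death_m0crpc,
            "excess_death_m1bcr": tp.excess_death_m1bcr,
            "excess_death_m1crpc": tp.excess_death_m1crpc,
            "cis": {k: list(v) for k, v in tp.cis.items()},
        },
        "utilities": {
            "u_m0bcr": us.u_m0bcr,
            "u_m1bcr": us.u_m1bcr,
            "u_m0crpc": us.u_m0crpc,
            "u_m1crpc": us.u_m1crpc,
            "sds": dict(us.sds),
        },
        "costs": {
            "m0bcr_first_year": cs.m0bcr_first_year,
            "m0bcr_subsequent": cs.m0bcr_subsequent,
            "m1bcr_first_year": cs.m1bcr_first_year,
            "m1bcr_subsequent": cs.m1bcr_subsequent,
            "m0crpc_annual": cs.m0crpc_annual,
            "m1crpc_annual": cs.m1crpc_annual,
            "cis": {k: list(v) for k, v in cs.cis.items()},
        },
        "strategies": strategies,
        "lifetable": None,  # path; None = bundled calibrated stand-in table
        "comparator_pair": ["DW-MRI", "FCH"],
        "psa": {"iterations": 1000, "seed": 0},
        "ceac": {"wtp_max": 20_000.0, "wtp_step": 100.0},
    }


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def load_config(path: Optional[Union[str, Path]] = None) -> dict:
    """Defaults, overlaid with the YAML file at ``path`` when given."""
    cfg = default_config()
    if path is None:
        return cfg
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, Mapping):
        raise ValueError(f"config file {path} must hold a mapping at top level")
    return _deep_merge(cfg, user)


def config_digest(cfg: Mapping[str, Any]) -> str:
    """Stable SHA-256 over the canonical JSON form of the configuration."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


class ModelBundle:
    """Constructed model objects for one configuration."""

    def __init__(self, cfg: Mapping[str, Any], lifetable_path: Optional[str] = None):
        self.raw = cfg
        m = cfg["model"]
        self.model_config = ModelConfig(
            start_age=m["start_age"],
            cohort_size=m["cohort_size"],
            discount_rate=m["discount_rate"],
            horizon=m.get("horizon"),
            counting_method=m["counting_method"],
            fp_policy=m["fp_policy"],
            fp_cost=m["fp_cost"],
            fn_cost=m["fn_cost"],
            fn_tunnel=m["fn_tunnel"],
            joint_progression=m["joint_progression"],
            discount_first_cycle=m["discount_first_cycle"],
            on_invalid_row=m["on_invalid_row"],
        )
        t = dict(cfg["transitions"])
        t["cis"] = {k: tuple(v) for k, v in t.get("cis", {}).items()}
        self.transitions = TransitionParams(**t)
        u = dict(cfg["utilities"])
        u["sds"] = dict(u.get("sds", {}))
        self.utilities = UtilitySet(**u)
        c = dict(cfg["costs"])
        c["cis"] = {k: tuple(v) for k, v in c.get("cis", {}).items()}
        self.costs = CostSet(**c)
        self.prevalence = float(cfg["prevalence"])
        self.strategies = {
            reading: [Strategy(**spec) for spec in specs]
            for reading, specs in cfg["strategies"].items()
        }
        self.comparator_pair = tuple(cfg["comparator_pair"])
        path = lifetable_path or cfg.get("lifetable")
        if path is None:
            self.life_table: LifeTable = default_life_table()
        else:
            p = Path(path)
            if not p.exists():
                raise FileNotFoundError(
                    f"life table not found at the configured path: {p}"
                )
            self.life_table = load_life_table(p)

    def strategy_set(self, reading: str) -> list[Strategy]:
        try:
            return self.strategies[reading]
        except KeyError:
            raise KeyError(
                f"no strategies for reading {reading!r}; "
                f"available: {sorted(self.strategies)}"
            ) from None


def build_bundle(
    config_path: Optional[Union[str, Path]] = None,
    lifetable_path: Optional[str] = None,
) -> ModelBundle:
    return ModelBundle(load_config(config_path), lifetable_path=lifetable_path)
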