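"""Configuration schema and loading.

A single YAML mapping drives every stage of the pipeline: the synthetic-world
generators, the intake projection, the weight model, mortality, and the
uncertainty propagation. :func:`default_config` returns the full schema with
its defaults; user files only need to state overrides, which are deep-merged.

Two profiles are provided: ``test`` (n = 2000 individuals, R = 50 bootstrap
replicates, desk-scale) and ``paper`` (n = 26854, R = 1000, the scale of the
survey analytic sample the synthetic cohort emulates).
"""

from __future__ import annotations

import copy
import hashlib
import json
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    """A configuration value failed schema validation; names the field."""


#: Profile presets applied on top of the defaults (explicit overrides win).
PROFILES = {
    "test": {"cohort": {"n": 2000}, "uncertainty": {"replicates": 50}},
    "paper": {"cohort": {"n": 26854}, "uncertainty": {"replicates": 1000}},
}


def default_config() -> dict:
    """Full configuration with defaults (test profile)."""
    return {
        "seed": 20210,
        "profile": "test",
        "years": {"start": 2021, "end": 2040, "decompose_start": 2026},
        "cohort": {
            "n": 2000,
            "female_share": 0.52,
            "age": {"min": 20, "max": 100, "decay": 0.03},
            "height": {
                "female_mean": 156.0, "female_sd": 6.0,
                "male_mean": 167.0, "male_sd": 7.0,
                "min": 130.0, "max": 200.0,
            },
            "bmi": {
                "female_sigma": 0.17, "male_sigma": 0.15,
                "obesity_target": 0.38,
                "min": 10.0, "max": 59.0,
            },
            "pal": {"mean": 1.55, "sd": 0.10, "min": 1.30, "max": 2.00},
            "population_total": 89.0e6,
            "wave_divisor": 3.0,
            "weight_sigma": 0.5,
            "strata": 30,
            "psus_per_stratum": 10,
        },
        "diet": {
            "fraction": 0.1523,  # SFFQ-style subsample share of the cohort
            "ssb_mean": 150.0, "ssb_sigma": 0.8,
            "nedf_mean": 140.0, "nedf_sigma": 0.8,
            "tei_mean": 2100.0, "tei_sigma": 0.2,
        },
        "tei_series": {"intercept_2000": 1950.0, "slope": 7.0, "noise_sd": 15.0},
        "mortality": {
            "gompertz_a": 8.2e-5, "gompertz_b": 0.08, "q_cap": 0.99,
            "decompose_method": "hazard",
        },
        "tax": {
            "ssb_price_increase": 0.10,
            "nedf_price_increase": 0.08,
            "ssb_cut": 0.076,
            "nedf_cut": 0.060,
            "tei_reduction": None,  # None -> computed from the diet subsample
            "tei_reduction_ui": [0.0072, 0.0115],
            "phase_in_years": 2,
        },
        "scenarios": {"mode": "nordpred", "impl_years": [2025, 2030, 2035]},
        "hall": {},  # overrides of taxdelay.hall.HallParameters fields
        "uncertainty": {"replicates": 50},
        "raking": {"age_band_edges": [20, 40, 60, 80], "max_iter": 200, "tol": 1e-8},
        "outcomes": {"a_frac": 0.5, "l_convention": "start"},
    }


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def make_config(overrides: Mapping | None = None) -> dict:
    """Defaults + profile preset + explicit overrides, validated."""
    overrides = dict(overrides or {})
    cfg = default_config()
    profile = overrides.get("profile", cfg["profile"])
    if profile not in PROFILES:
        raise ConfigError(f"profile: unknown profile {profile!r}")
    cfg = _deep_merge(cfg, PROFILES[profile])
    cfg = _deep_merge(cfg, overrides)
    cfg["profile"] = profile
    validate_config(cfg)
    return cfg


def load_config(path: str | Path | None = None) -> dict:
    """Load a YAML config file (or defaults when *path* is None)."""
    if path is None:
        return make_config()
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("top level: config file must be a mapping")
    return make_config(data)


def _require(cond: bool, field: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{field}: {msg}")


def validate_config(cfg: Mapping) -> None:
    """Raise :class:`ConfigError` naming the offending field."""
    years = cfg["years"]
    _require(years["start"] < years["end"], "years.start", "must precede years.end")
    _require(
        years["start"] <= years["decompose_start"] <= years["end"] + 1,
        "years.decompose_start", "must lie within the simulation horizon",
    )
    c = cfg["cohort"]
    _require(int(c["n"]) >= 1, "cohort.n", "must be a positive integer")
    _require(0.0 < c["female_share"] < 1.0, "cohort.female_share", "must be in (0, 1)")
    _require(c["age"]["min"] >= 20 and c["age"]["max"] <= 100,
             "cohort.age", "must lie within [20, 100]")
    _require(c["bmi"]["min"] >= 10.0 and c["bmi"]["max"] <= 59.0,
             "cohort.bmi", "bounds must lie within [10, 59]")
    _require(0.0 < c["bmi"]["obesity_target"] < 1.0,
             "cohort.bmi.obesity_target", "must be in (0, 1)")
    _require(c["population_total"] > 0, "cohort.population_total", "must be positive")
    _require(int(c["strata"]) >= 1 and int(c["psus_per_stratum"]) >= 2,
             "cohort.psus_per_stratum", "need >= 2 PSUs per stratum for the bootstrap")
    d = cfg["diet"]
    _require(0.0 < d["fraction"] <= 1.0, "diet.fraction", "must be in (0, 1]")
    t = cfg["tei_series"]
    _require(t["intercept_2000"] > 0, "tei_series.intercept_2000", "must be positive")
    m = cfg["mortality"]
    _require(m["gompertz_a"] > 0 and m["gompertz_b"] > 0,
             "mortality.gompertz_a", "Gompertz parameters must be positive")
    _require(m["decompose_method"] in ("hazard", "proportional"),
             "mortality.decompose_method", "must be 'hazard' or 'proportional'")
    tax = cfg["tax"]
    for key in ("ssb_cut", "nedf_cut"):
        _require(0.0 <= tax[key] < 1.0, f"tax.{key}", "must be in [0, 1)")
    if tax["tei_reduction"] is not None:
        _require(0.0 <= tax["tei_reduction"] < 1.0, "tax.tei_reduction", "must be in [0, 1)")
    lo, hi = tax["tei_reduction_ui"]
    _require(0.0 <= lo <= hi, "tax.tei_reduction_ui", "must be an ordered pair")
    _require(int(tax["phase_in_years"]) >= 0, "tax.phase_in_years", "must be >= 0")
    s = cfg["scenarios"]
    _require(s["mode"] in ("nordpred", "linear"), "scenarios.mode",
             "must be 'nordpred' or 'linear'")
    for y in s["impl_years"]:
        _require(years["start"] < y <= years["end"], "scenarios.impl_years",
                 f"implementation year {y} outside the horizon")
    _require(int(cfg["uncertainty"]["replicates"]) >= 0,
             "uncertainty.replicates", "must be >= 0")
    o = cfg["outcomes"]
    _require(0.0 <= o["a_frac"] <= 1.0, "outcomes.a_frac", "must be in [0, 1]")
    _require(o["l_convention"] in ("start", "midyear"), "outcomes.l_convention",
             "must be 'start' or 'midyear'")


def config_hash(cfg: Mapping) -> str:
    """Stable SHA-256 of a config mapping (for run manifests)."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def save_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
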