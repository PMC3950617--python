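"""Scenario loading/validation, bundled fixtures, and result serialization.

Scenario files are YAML (JSON is a YAML subset) with the schema::

    name: ...
    arrivals:
      ctas_1: ... ctas_5: patients/hour, most acute first
      total:        optional; must equal the sum of the levels
      direct_iu:    direct inpatient admissions, patients/hour
      iu_from_ed:   optional ED->IU admission rate; yields the transfer fraction
      iu_total:     optional; must equal direct_iu + iu_from_ed
    transfer_fraction: alternative to arrivals.iu_from_ed
    ed_service: {lower, mode, upper, unit: hours|days}
    iu_los:     {lower, mode, upper, unit: hours|days}
    beds: {ed: c1, iu: c2}
    options: {wait_metric, bondi_scaling}           # optional
    fast_track: {enabled, fraction, literal_eq14}   # optional

All times are normalised to hours at load time.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Optional, Union

import numpy as np
import pandas as pd
import yaml

from .coupling import Scenario
from .distributions import TriangularDist, tri_moments
from .fast_track import FastTrackConfig
from .planner import CapacityCurve, WaitTargets

__all__ = [
    "ScenarioFile",
    "ScenarioError",
    "load_scenario",
    "load_scenario_file",
    "load_targets",
    "bundled_scenario_path",
    "write_results",
    "read_results",
    "make_fixture",
]

log = logging.getLogger("edq")

_TOTAL_TOL = 1e-6


class ScenarioError(ValueError):
    """Scenario-file validation failure; the message names the field."""


@dataclass(frozen=True)
class ScenarioFile:
    scenario: Scenario
    fast_track: Optional[FastTrackConfig]
    name: str
    description: str
    config_hash: str


def _require(mapping: dict, key: str, where: str):
    if key not in mapping:
        raise ScenarioError(f"missing field '{where}.{key}'")
    return mapping[key]


def _num(value, where: str) -> float:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise ScenarioError(f"field '{where}' must be a number, got {value!r}")
    return float(value)


def _dist(block: dict, where: str) -> TriangularDist:
    if not isinstance(block, dict):
        raise ScenarioError(f"field '{where}' must be a mapping with lower/mode/upper")
    lower = _num(_require(block, "lower", where), f"{where}.lower")
    mode = _num(_require(block, "mode", where), f"{where}.mode")
    upper = _num(_require(block, "upper", where), f"{where}.upper")
    unit = block.get("unit", "hours")
    try:
        return TriangularDist.from_spec(lower, mode, upper, unit=unit)
    except ValueError as exc:
        raise ScenarioError(f"field '{where}': {exc}") from exc


def load_scenario_file(path: Union[str, Path]) -> ScenarioFile:
    """Load and validate a scenario file, normalising all times to hours."""
    path = Path(path)
    raw_bytes = path.read_bytes()
    cfg = yaml.safe_load(raw_bytes)
    if not isinstance(cfg, dict):
        raise ScenarioError("scenario file must contain a mapping")
    cfg_hash = hashlib.sha256(raw_bytes).hexdigest()[:16]

    arr = _require(cfg, "arrivals", "")
    rates = []
    for i in range(1, 6):
        key = f"ctas_{i}"
        r = _num(_require(arr, key, "arrivals"), f"arrivals.{key}")
        if r < 0:
            raise ScenarioError(f"field 'arrivals.{key}' must be non-negative")
        rates.append(r)
    lam_total = sum(rates)
    if "total" in arr:
        declared = _num(arr["total"], "arrivals.total")
        if abs(declared - lam_total) > _TOTAL_TOL:
            raise ScenarioError(
                f"field 'arrivals.total' ({declared}) does not match the per-level "
                f"sum ({lam_total:.6f}) within {_TOTAL_TOL}"
            )
    lam_d = _num(_require(arr, "direct_iu", "arrivals"), "arrivals.direct_iu")
    if lam_d < 0:
        raise ScenarioError("field 'arrivals.direct_iu' must be non-negative")

    if "iu_from_ed" in arr:
        from_ed = _num(arr["iu_from_ed"], "arrivals.iu_from_ed")
        if lam_total <= 0:
            raise ScenarioError("'arrivals.iu_from_ed' given but total ED arrivals are zero")
        x = from_ed / lam_total
        if "transfer_fraction" in cfg and cfg["transfer_fraction"] is not None:
            xf = _num(cfg["transfer_fraction"], "transfer_fraction")
            if abs(xf - x) > 1e-3:
                raise ScenarioError(
                    "fields 'transfer_fraction' and 'arrivals.iu_from_ed' disagree"
                )
        if "iu_total" in arr:
            declared = _num(arr["iu_total"], "arrivals.iu_total")
            if abs(declared - (from_ed + lam_d)) > _TOTAL_TOL:
                raise ScenarioError(
                    f"field 'arrivals.iu_total' ({declared}) does not match "
                    f"iu_from_ed + direct_iu ({from_ed + lam_d:.6f})"
                )
    elif "transfer_fraction" in cfg and cfg["transfer_fraction"] is not None:
        x = _num(cfg["transfer_fraction"], "transfer_fraction")
    else:
        raise ScenarioError("need 'transfer_fraction' or 'arrivals.iu_from_ed'")
    if not 0.0 <= x <= 1.0:
        raise ScenarioError(f"transfer fraction {x:.4f} outside [0, 1]")

    beds = _require(cfg, "beds", "")
    c1 = _require(beds, "ed", "beds")
    c2 = _require(beds, "iu", "beds")
    if not isinstance(c1, int) or not isinstance(c2, int) or c1 < 1 or c2 < 1:
        raise ScenarioError("fields 'beds.ed' and 'beds.iu' must be integers >= 1")

    opts = cfg.get("options", {}) or {}
    try:
        scenario = Scenario(
            arrival_rates=tuple(rates),
            lambda_direct=lam_d,
            transfer_fraction=x,
            ed_service=_dist(_require(cfg, "ed_service", ""), "ed_service"),
            iu_los=_dist(_require(cfg, "iu_los", ""), "iu_los"),
            c1=c1, c2=c2,
            wait_metric=opts.get("wait_metric", "queueing_delay"),
            bondi_scaling=opts.get("bondi_scaling", "scaled"),
            name=str(cfg.get("name", path.stem)),
        )
    except ValueError as exc:
        raise ScenarioError(str(exc)) from exc

    ft_cfg = None
    ft = cfg.get("fast_track")
    if ft and ft.get("enabled", False):
        ft_cfg = FastTrackConfig(
            fraction_fast=_num(_require(ft, "fraction", "fast_track"), "fast_track.fraction"),
            literal_eq14=bool(ft.get("literal_eq14", False)),
        )

    log.info("loaded scenario %s (hash %s): lambda=%.4f/h, c1=%d, c2=%d",
             scenario.name, cfg_hash, lam_total, c1, c2)
    return ScenarioFile(
        scenario=scenario, fast_track=ft_cfg,
        name=scenario.name, description=str(cfg.get("description", "")),
        config_hash=cfg_hash,
    )


def load_scenario(path: Union[str, Path]) -> Scenario:
    return load_scenario_file(path).scenario


def bundled_scenario_path(name: str = "table2_baseline") -> Path:
    """Path of a fixture shipped with the package."""
    return Path(resources.files("edq").joinpath(f"data/{name}.yaml"))


def load_targets(path: Union[str, Path, None] = None) -> WaitTargets:
    """Load CTAS wait targets (minutes) from YAML; default = bundled guideline."""
    if path is None:
        path = bundled_scenario_path("ctas_targets")
    cfg = yaml.safe_load(Path(path).read_text())
    t = cfg.get("targets", cfg)
    minutes = tuple(_num(_require(t, f"ctas_{i}", "targets"), f"targets.ctas_{i}")
                    for i in range(1, 6))
    return WaitTargets(minutes=minutes)


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _to_jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return obj


def write_results(report: Any, path: Union[str, Path], format: str = "json") -> Path:
    """Serialize a report: JSON for structured reports, CSV for tabular ones.

    Field ordering is deterministic (dataclass declaration order); numbers
    keep full double precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        if isinstance(report, CapacityCurve):
            report.to_frame().to_csv(path, index=False)
        elif isinstance(report, pd.DataFrame):
            report.to_csv(path, index=False)
        else:
            raise ValueError(f"no CSV layout for {type(report).__name__}; use json")
    elif format == "json":
        payload = {"type": type(report).__name__, "payload": _to_jsonable(report)}
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    else:
        raise ValueError("format must be 'csv' or 'json'")
    return path


def read_results(path: Union[str, Path]) -> Any:
    """Read back a serialized report (JSON -> dict, CSV -> DataFrame)."""
    path = Path(path)
    if path.suffix == ".csv":
        return pd.read_csv(path)
    return json.loads(path.read_text())


_REGIMES = {"light": (0.05, 0.3), "moderate": (0.3, 0.7),
            "congested": (0.7, 0.95), "unstable": (1.05, 1.5)}


def make_fixture(seed: int, regime: str = "moderate") -> Scenario:
    """Random valid scenario with ED load targeted to the named regime.

    Regimes (aggregate raw ED load lambda/(c1*mu1)): light < 0.3,
    moderate 0.3-0.7, congested 0.7-0.95, unstable > 1.  IU load is drawn
    to stay clearly subcritical (and light for the light regime, so that
    blocking is negligible there).  The same seed returns the same scenario.
    """
    if regime not in _REGIMES:
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    lo, hi = _REGIMES[regime]
    rho_target = float(rng.uniform(lo, hi))

    c1 = int(rng.integers(3, 31))
    a = float(rng.uniform(0.05, 0.5))
    b = a + float(rng.uniform(0.2, 1.5))
    m = float(rng.uniform(a, b))
    ed = TriangularDist(a, m, b)
    mu1 = 1.0 / tri_moments(ed).mean

    lam_total = rho_target * c1 * mu1
    mix = rng.dirichlet(np.ones(5))
    rates = tuple(float(lam_total * w) for w in mix)

    c2 = int(rng.integers(10, 200))
    lo_d = float(rng.uniform(10, 40))
    hi_d = lo_d + float(rng.uniform(24, 150))
    mo_d = float(rng.uniform(lo_d, hi_d))
    iu = TriangularDist(lo_d, mo_d, hi_d)
    mu_i = 1.0 / tri_moments(iu).mean

    x = float(rng.uniform(0.02, 0.2))
    rho_iu = float(rng.uniform(0.2, 0.5)) if regime == "light" else float(rng.uniform(0.3, 0.8))
    # split the targeted IU flow budget between transfers and direct
    # admissions; cap x so transfers alone cannot overshoot the budget
    flow = rho_iu * c2 * mu_i
    lam_eff = min(lam_total, c1 * mu1)
    if lam_eff > 0:
        x = min(x, 0.9 * flow / lam_eff)
    lam_d = max(0.0, flow - x * lam_eff)

    return Scenario(
        arrival_rates=rates, lambda_direct=lam_d, transfer_fraction=x,
        ed_service=ed, iu_los=iu, c1=c1, c2=c2,
        name=f"fixture-{regime}-{seed}",
    )
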