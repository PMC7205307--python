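"""Scenario configuration, bundled fixtures, and result serialization."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .model_core import GAMMA_P_REF, PARAM_KEYS, NondimParams, table1
from .stochastic import CellGeometry
from .variants import CircuitVariant

__all__ = ["Scenario", "RunRecord", "load_config", "fixture_scenarios",
           "write_results"]

log = logging.getLogger("xapswitch")

_VARIANT_KEYS = ("xapA_removed", "xapB_removed", "promoter_sites",
                 "inducer_sites_per_TF", "deps_coop_override", "active_policy")
_SIM_KEYS = ("t_end_tau", "n_runs", "base_seed", "algorithm")
_GEOM_KEYS = ("volume_L", "K_a")


@dataclass(frozen=True)
class Scenario:
    """A fully specified model configuration plus simulation settings."""

    name: str
    params: NondimParams
    variant: CircuitVariant = CircuitVariant()
    geometry: CellGeometry = CellGeometry()
    t_end_tau: float = 500.0
    n_runs: int = 200
    base_seed: int = 0
    algorithm: str = "hybrid"
    note: str = ""

    def __post_init__(self) -> None:
        if self.t_end_tau <= 0:
            raise ValueError("t_end_tau must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.algorithm not in ("direct", "hybrid"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def t_end_seconds(self) -> float:
        """Horizon in seconds at the reference gamma_p = 5e-4 1/s."""
        return self.t_end_tau / GAMMA_P_REF

    def to_dict(self) -> dict:
        d: dict = {"name": self.name, "note": self.note,
                   "params": self.params.to_dict()}
        d["variant"] = asdict(self.variant)
        d["geometry"] = {"volume_L": self.geometry.volume_L,
                         "K_a": self.geometry.K_a}
        d["simulation"] = {"t_end_tau": self.t_end_tau, "n_runs": self.n_runs,
                           "base_seed": self.base_seed,
                           "algorithm": self.algorithm}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        errors: list[str] = []
        known_top = {"name", "note", "params", "variant", "geometry",
                     "simulation"}
        for key in set(d) - known_top:
            errors.append(f"unknown top-level key {key!r}")

        pdict = dict(d.get("params") or {})
        for key in set(pdict) - set(PARAM_KEYS):
            errors.append(f"unknown parameter key {key!r}")
            pdict.pop(key)
        params = table1()
        for key, val in pdict.items():
            try:
                params = params.with_(**{key: float(val)})
            except (TypeError, ValueError) as exc:
                errors.append(f"params.{key}: {exc}")

        vdict = dict(d.get("variant") or {})
        for key in set(vdict) - set(_VARIANT_KEYS):
            errors.append(f"unknown variant key {key!r}")
            vdict.pop(key)
        variant = CircuitVariant()
        try:
            variant = replace(variant, **vdict)
        except (TypeError, ValueError) as exc:
            errors.append(f"variant: {exc}")

        gdict = dict(d.get("geometry") or {})
        for key in set(gdict) - set(_GEOM_KEYS):
            errors.append(f"unknown geometry key {key!r}")
            gdict.pop(key)
        geometry = CellGeometry()
        try:
            geometry = replace(geometry, **{k: float(v) for k, v in gdict.items()})
        except (TypeError, ValueError) as exc:
            errors.append(f"geometry: {exc}")

        sdict = dict(d.get("simulation") or {})
        for key in set(sdict) - set(_SIM_KEYS):
            errors.append(f"unknown simulation key {key!r}")
            sdict.pop(key)

        if errors:
            raise ValueError("invalid scenario configuration:\n  "
                             + "\n  ".join(errors))
        return cls(name=str(d.get("name", "scenario")),
                   params=params, variant=variant, geometry=geometry,
                   note=str(d.get("note", "")), **sdict)


@dataclass(frozen=True)
class RunRecord:
    """Provenance of one computation: scenario, version, seeds, outputs."""

    scenario: Scenario
    outputs: dict = field(default_factory=dict)
    toolkit_version: str = ""
    timestamp: str = ""
    seeds: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        from . import __version__

        return {"scenario": self.scenario.to_dict(),
                "toolkit_version": self.toolkit_version or __version__,
                "timestamp": self.timestamp or time.strftime("%Y-%m-%dT%H:%M:%S"),
                "seeds": list(self.seeds),
                "outputs": self.outputs}


def load_config(path) -> Scenario:
    """Load and validate a YAML/JSON scenario file.

    Unknown keys are rejected and all schema violations are reported
    together; missing fields fall back to the reference defaults.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    if "name" not in data:
        data["name"] = Path(path).stem
    return Scenario.from_dict(data)


def fixture_scenarios() -> dict[str, Scenario]:
    """Named scenarios for the study conditions of the reference figures."""
    t1 = table1()
    scen = {
        "fig5_bistable": Scenario("fig5_bistable", t1,
                                  note="reference bistable scenario, c_a=13"),
        "fig6a": Scenario("fig6a", t1.with_(c_a=7.0),
                          note="monostable low expression"),
        "fig6b": Scenario("fig6b", t1.with_(c_a=40.0),
                          note="monostable high expression"),
        "fig7a": Scenario("fig7a", t1, CircuitVariant(xapA_removed=True),
                          note="XapA ablated: bistability retained"),
        "fig7b": Scenario("fig7b", t1, CircuitVariant(xapB_removed=True),
                          note="XapB ablated: bistability lost"),
        # rho is adjusted through rho_m (rho = rho_m * rho_p / gamma_mp)
        "fig8a": Scenario("fig8a", t1.with_(rho_m=0.07 * t1.gamma_mp / t1.rho_p,
                                            c_a=6.0),
                          CircuitVariant(inducer_sites_per_TF=1),
                          note="single inducer site, rho=0.07, c_a=6"),
        "fig8b": Scenario("fig8b", t1.with_(rho_m=0.13 * t1.gamma_mp / t1.rho_p,
                                            c_a=3.0),
                          CircuitVariant(promoter_sites=1),
                          note="single promoter site, rho=0.13, c_a=3"),
        "fig8c": Scenario("fig8c", t1.with_(rho_m=0.1 * t1.gamma_mp / t1.rho_p,
                                            XapR_R=5.0),
                          CircuitVariant(inducer_sites_per_TF=1,
                                         promoter_sites=1),
                          note="no cooperativity anywhere: monostable"),
        "fig9a": Scenario("fig9a", t1.with_(c_a=12.0), t_end_tau=500.0,
                          note="unimodal low endpoint distribution"),
        "fig9b": Scenario("fig9b", t1.with_(c_a=18.5), t_end_tau=500.0,
                          note="bimodal endpoint distribution"),
        "fig9c": Scenario("fig9c", t1.with_(c_a=25.0), t_end_tau=500.0,
                          note="unimodal high endpoint distribution"),
        "fig10": Scenario("fig10", t1.with_(c_a=25.0), t_end_tau=250.0,
                          n_runs=1000,
                          note="adaptation-time protocol, 5e5 s horizon"),
        "fig11": Scenario("fig11", t1, t_end_tau=500.0,
                          note="bifurcation diagram with dual-init ensembles"),
    }
    return scen


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_results(records, outputs: dict, directory) -> dict:
    """Write result artifacts plus a manifest with content hashes.

    ``outputs`` maps file names to payloads: a pandas DataFrame (written
    as CSV), a dict/list (JSON), or raw text.  Returns the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    for name, payload in outputs.items():
        path = directory / name
        if hasattr(payload, "to_csv"):
            # %.17g round-trips float64 exactly
            payload.to_csv(path, index=False, float_format="%.17g")
        elif isinstance(payload, (dict, list)):
            path.write_text(json.dumps(payload, indent=1, default=_jsonify))
        else:
            path.write_text(str(payload))
        written[name] = _sha256(path)
        log.info("wrote %s (%s)", path, written[name][:12])
    if not isinstance(records, (list, tuple)):
        records = [records]
    manifest = {"files": written,
                "records": [r.to_dict() for r in records]}
    (directory / "manifest.json").write_text(
        json.dumps(manifest, indent=1, default=_jsonify))
    return manifest


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)!r}")
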