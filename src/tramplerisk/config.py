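"""Run configuration: one YAML file drives simulate and analyze.

Defaults are the study constants: 50-m cells, 6.25 m^2 inclusion threshold,
alpha 0.05, 0.8 livestock units per young animal, 14-day trial periods and
a 24-day incubation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace
from datetime import date
from pathlib import Path

import yaml

from .synthetic import SimConfig, TrueDoseResponse


@dataclass(frozen=True)
class RunConfig:
    outdir: str = "trample_out"
    fixes_path: str | None = None      # default: <outdir>/fixes.csv
    geometry_path: str | None = None   # default: <outdir>/marsh.geojson
    trials_path: str | None = None     # default: <outdir>/trials.csv
    cell_size_m: float = 50.0
    inclusion_threshold_m2: float = 6.25
    alpha: float = 0.05
    lsu_coefficient: float = 0.8
    incubation_days: int = 24
    period_days: int = 14
    n_plots: int = 30
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def __post_init__(self) -> None:
        if self.inclusion_threshold_m2 <= 0 or self.cell_size_m <= 0:
            raise ValueError("grid thresholds must be positive")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def path(self, name: str) -> Path:
        explicit = getattr(self, f"{name}_path")
        if explicit:
            return Path(explicit)
        default = {"fixes": "fixes.csv", "geometry": "marsh.geojson",
                   "trials": "trials.csv"}[name]
        return Path(self.outdir) / default

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sim"]["week1_start_date"] = self.sim.week1_start_date.isoformat()
        if self.sim.collar_dropout:
            d["sim"]["collar_dropout"] = {
                k: v.isoformat() for k, v in self.sim.collar_dropout.items()
            }
        return d

    def config_hash(self) -> str:
        """Hash of the scientific settings only (paths excluded, so the same
        analysis writes byte-identical tables wherever it is run)."""
        d = self.to_dict()
        for key in ("outdir", "fixes_path", "geometry_path", "trials_path"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim_d = dict(d.pop("sim", {}))
        if "week1_start_date" in sim_d and isinstance(sim_d["week1_start_date"], str):
            sim_d["week1_start_date"] = date.fromisoformat(sim_d["week1_start_date"])
        if sim_d.get("collar_dropout"):
            sim_d["collar_dropout"] = {
                k: date.fromisoformat(v) if isinstance(v, str) else v
                for k, v in sim_d["collar_dropout"].items()
            }
        if "zone_band_widths_m" in sim_d:
            sim_d["zone_band_widths_m"] = tuple(sim_d["zone_band_widths_m"])
        if "attraction_point" in sim_d and sim_d["attraction_point"] is not None:
            sim_d["attraction_point"] = tuple(sim_d["attraction_point"])
        tdr = sim_d.pop("true_dose_response", None)
        if isinstance(tdr, dict):
            sim_d["true_dose_response"] = TrueDoseResponse(**tdr)
        known = {f.name for f in fields(SimConfig)}
        sim = SimConfig(**{k: v for k, v in sim_d.items() if k in known})
        known_run = {f.name for f in fields(cls)} - {"sim"}
        return cls(sim=sim, **{k: v for k, v in d.items() if k in known_run})

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def with_seed(self, seed: int) -> "RunConfig":
        return replace(self, seed=seed, sim=replace(self.sim, rng_seed=seed))
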