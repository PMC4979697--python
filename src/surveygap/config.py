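"""Run configuration: a YAML-backed description of one audit or simulation.

The config is a plain nested mapping so it round-trips exactly through
write -> read.  Sections:

``seed``
    Master integer seed; every random substream derives from it.
``grid``
    ``origin: [lon0, lat0]``, ``n_lon``, ``n_lat``, ``cell_size`` and an
    optional ``mask`` path (text file, one cell id per line).
``simulate``
    ``landscape`` (LandscapeParams fields), ``pool`` (n_species, sad,
    theta, niche), ``effort`` (EffortModel fields or ``preset:
    opportunistic|systematic``).
``datasets``
    For audits: list of ``{name, records: path, filters:
    gbif|systematic}`` entries.
``gradients``
    Path to a per-cell gradient table (e.g. the written landscape).
``thresholds``
    Optional tier overrides: ``{low: {min_records, min_completeness,
    max_slope}, moderate: ..., high: ...}``.
``output_dir``
    Where outputs and the manifest land.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .completeness import ThresholdSet, Tier
from .grid import GridSpec
from .synth import EffortModel, LandscapeParams, NicheSpec


@dataclass
class RunConfig:
    seed: int
    output_dir: str = "surveygap_out"
    grid: dict = field(default_factory=dict)
    simulate: dict = field(default_factory=dict)
    datasets: list = field(default_factory=list)
    gradients: str | None = None
    thresholds: dict | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise ValueError("config must set an integer seed")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "grid": self.grid,
            "simulate": self.simulate,
            "datasets": self.datasets,
            "gradients": self.gradients,
            "thresholds": self.thresholds,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    # -- section builders --------------------------------------------------

    def build_grid(self) -> GridSpec:
        g = dict(self.grid)
        origin = g.get("origin", [-110.0, 30.0])
        n_lon = int(g.get("n_lon", 20))
        n_lat = int(g.get("n_lat", 10))
        size = float(g.get("cell_size", 0.1))
        mask = None
        if g.get("mask"):
            ids = [int(line) for line in Path(g["mask"]).read_text().split()]
            mask = frozenset(ids)
        return GridSpec(
            lon_min=float(origin[0]),
            lat_min=float(origin[1]),
            lon_max=float(origin[0]) + n_lon * size,
            lat_max=float(origin[1]) + n_lat * size,
            cell_size=size,
            mask=mask,
        )

    def build_landscape_params(self) -> LandscapeParams:
        return LandscapeParams(**self.simulate.get("landscape", {}))

    def build_niche(self) -> NicheSpec:
        n = dict(self.simulate.get("pool", {}).get("niche", {}))
        if "optimum_range" in n:
            n["optimum_range"] = tuple(n["optimum_range"])
        if "breadth_range" in n:
            n["breadth_range"] = tuple(n["breadth_range"])
        return NicheSpec(**n)

    def build_effort(self, seed: int) -> EffortModel:
        e = dict(self.simulate.get("effort", {}))
        preset = e.pop("preset", "opportunistic")
        if "temporal_weights" in e:
            e["temporal_weights"] = tuple(e["temporal_weights"])
        e["seed"] = seed
        if preset == "systematic":
            return EffortModel.systematic_survey(**e)
        if preset == "opportunistic":
            return EffortModel.opportunistic(**e)
        raise ValueError(f"unknown effort preset: {preset!r}")

    def build_thresholds(self) -> ThresholdSet:
        if not self.thresholds:
            return ThresholdSet()
        tiers = {}
        for name in ("low", "moderate", "high"):
            t = self.thresholds.get(name)
            if t:
                tiers[name] = Tier(
                    int(t["min_records"]),
                    float(t["min_completeness"]),
                    float(t["max_slope"]),
                )
        return ThresholdSet(**tiers)
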