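"""Pipeline configuration (YAML-backed) with embedded defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from ..model_core import ModelParams
from ..scenario_synth import SCENARIOS, DEFAULT_DEPTH_LEVELS

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything needed for a full reproducible pipeline run."""

    n_lat: int = 18
    n_lon: int = 36
    depth_levels: tuple = DEFAULT_DEPTH_LEVELS
    scenarios: tuple = ("ssp126", "ssp585")
    years: tuple = (1990, 2099)
    baseline_window: tuple = (1990, 2013)
    scenario_window: tuple = (2076, 2099)
    seed: int = 0
    anomaly_frac: float = 0.05
    noise_frac: float = 0.03
    noise_rho: float = 0.5
    biomass_mode: str = "steady"       # steady | prescribed
    biomass_cap: float = 50.0          # mmol C m-3, for the steady solve
    obs_sigma: float = 0.3
    obs_missing_frac: float = 0.2
    model_params: dict = field(default_factory=dict)
    out_dir: str = "results"
    verbose: bool = False

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_window
        s0, s1 = self.scenario_window
        if not (b0 <= b1 < s0 <= s1):
            raise ValueError("windows must be ordered and non-overlapping")
        y0, y1 = self.years
        if not (y0 <= b0 and s1 <= y1):
            raise ValueError("analysis windows must lie inside the simulated years")
        for s in self.scenarios:
            if s not in SCENARIOS:
                raise ValueError(f"unknown scenario id {s!r}")
        if self.biomass_mode not in ("steady", "prescribed"):
            raise ValueError("biomass_mode must be 'steady' or 'prescribed'")

    def params(self) -> ModelParams:
        return ModelParams(**self.model_params)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("depth_levels", "scenarios", "years", "baseline_window", "scenario_window"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key, val in data.items():
            if isinstance(val, tuple):
                data[key] = list(val)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
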