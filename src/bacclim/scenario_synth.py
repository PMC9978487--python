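"""Seeded synthetic generator for gridded scenario forcing and observations.

Produces reduced-resolution (year, depth, lat, lon) fields of temperature,
organic carbon pools, oxygen and plankton biomass that carry prescribed
regional baselines, linear 2015-2099 trends toward per-scenario targets,
a smooth spatial anomaly and AR(1) interannual noise — a stand-in for an
Earth-system-model archive.  Station and gridded "observations" of bacterial
abundance and thymidine incorporation are sampled from a truth field with
lognormal error and seeded gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Grid",
    "ScenarioSpec",
    "FieldSet",
    "SCENARIOS",
    "VERTICAL_SHAPES",
    "build_grid",
    "default_scenario_spec",
    "generate_scenario_fields",
    "generate_station_obs",
    "generate_gridded_obs",
]

logger = logging.getLogger(__name__)

SCENARIOS = ("historical", "ssp126", "ssp245", "ssp370", "ssp585")

#: e-folding depth (m) of the surface-intensified vertical shape
SURFACE_SCALE = 150.0

RAMP_START = 2015
RAMP_END = 2099

DEFAULT_DEPTH_LEVELS = (0.0, 10.0, 20.0, 30.0, 50.0, 70.0, 85.0, 100.0, 107.0, 130.0)


@dataclass(frozen=True)
class Grid:
    """Regular lat/lon/depth grid with cos-latitude area weights."""

    lat: np.ndarray               # degrees, ascending centers
    lon: np.ndarray               # degrees, centers
    depth: np.ndarray             # level centers (m), increasing
    depth_interfaces: np.ndarray  # level interfaces (m), len(depth) + 1
    area_weights: np.ndarray      # (lat, lon), sums to 1 over ocean cells
    ocean_mask: np.ndarray        # (lat, lon) boolean

    def __post_init__(self) -> None:
        if np.any(np.diff(self.depth) <= 0) or np.any(np.diff(self.depth_interfaces) <= 0):
            raise ValueError("depth levels and interfaces must be strictly increasing")
        if np.count_nonzero((self.depth >= 0) & (self.depth <= 107)) < 2:
            raise ValueError("need at least 2 depth levels within 0-107 m")
        if np.any(self.area_weights < 0):
            raise ValueError("area weights must be >= 0")
        total = self.area_weights[self.ocean_mask].sum()
        if not np.isclose(total, 1.0, rtol=1e-10):
            raise ValueError("area weights must sum to 1 over ocean cells")

    @property
    def shape(self):
        return (len(self.lat), len(self.lon))


def build_grid(n_lat: int = 18, n_lon: int = 36, depth_levels=None) -> Grid:
    """Build an all-ocean grid with cos-latitude area weights.

    Latitude centers are placed at the middles of ``n_lat`` equal bands of
    [-90, 90]; a configuration with an empty latitudinal band is rejected.
    """
    if n_lat < 6:
        raise ValueError("n_lat must be >= 6 so every latitudinal band is populated")
    if n_lon < 1:
        raise ValueError("n_lon must be >= 1")
    if depth_levels is None:
        depth_levels = DEFAULT_DEPTH_LEVELS
    depth = np.asarray(depth_levels, dtype=float)
    if depth.ndim != 1 or len(depth) < 2:
        raise ValueError("need at least 2 depth levels")
    if depth.max() < 107:
        raise ValueError("depth levels must span at least 107 m")
    mids = 0.5 * (depth[:-1] + depth[1:])
    interfaces = np.concatenate([[max(0.0, depth[0] - (depth[1] - depth[0]) / 2)], mids,
                                 [depth[-1] + (depth[-1] - depth[-2]) / 2]])

    lat = -90.0 + (np.arange(n_lat) + 0.5) * 180.0 / n_lat
    lon = -180.0 + (np.arange(n_lon) + 0.5) * 360.0 / n_lon
    mask = np.ones((n_lat, n_lon), dtype=bool)
    w = np.cos(np.deg2rad(lat))[:, None] * np.ones((1, n_lon))
    w = np.where(mask, w, 0.0)
    w = w / w.sum()

    # every latitudinal band must hold at least one ocean cell
    from .composites import region_for_lat, REGION_BANDS

    labels = region_for_lat(lat)
    for band in REGION_BANDS:
        if not np.any(labels == band):
            raise ValueError(f"latitudinal band {band} has no grid cells")
    return Grid(lat=lat, lon=lon, depth=depth, depth_interfaces=interfaces,
                area_weights=w, ocean_mask=mask)


@dataclass(frozen=True)
class ScenarioSpec:
    """Prescription of one scenario's regional means and noise structure.

    ``region_values`` maps variable name to ``{region: (baseline, target)}``
    where values are column stocks (mmol m-2 over the upper 107 m layer) for
    column variables and layer means for average variables (T, DO).  Targets
    are reached linearly over the ramp window; historical years carry no
    trend.
    """

    scenario: str
    region_values: Mapping[str, Mapping[str, tuple]]
    kinds: Mapping[str, str]          # variable -> {column | average}
    shapes: Mapping[str, str]         # variable -> {uniform | surface_exp}
    units: Mapping[str, str]
    ramp: tuple = (RAMP_START, RAMP_END)
    target_window: tuple = (2076, 2099)   # window whose mean field equals the target
    anomaly_frac: float = 0.05        # spatial anomaly amplitude, fraction of baseline
    noise_frac: float = 0.03          # AR(1) sigma, fraction of baseline
    noise_rho: float = 0.5            # lag-1 autocorrelation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario id {self.scenario!r}; choose from {SCENARIOS}")
        if not 0 <= self.noise_rho < 1:
            raise ValueError("noise_rho must lie in [0, 1)")
        if self.noise_frac < 0 or self.anomaly_frac < 0:
            raise ValueError("noise and anomaly amplitudes must be >= 0")


VERTICAL_SHAPES = ("uniform", "surface_exp")

#: non-scenario variables: oxic oxygen everywhere; smooth microzooplankton and
#: phytoplankton columns with low-latitude minima (mmol C m-2)
DEFAULT_DO = 250.0
DEFAULT_Z_COLUMN = {"NH": 60.0, "NI": 50.0, "LL": 30.0, "SI": 50.0, "SO": 60.0}
DEFAULT_P_COLUMN = {"NH": 150.0, "NI": 120.0, "LL": 80.0, "SI": 120.0, "SO": 150.0}


def default_scenario_spec(scenario: str, seed: int = 0, **overrides) -> ScenarioSpec:
    """Scenario spec with regional baselines/targets drawn from the packaged
    composite table (T, DOC, POC, B) plus oxic DO and smooth Z/P fields."""
    from .io_cli.fixtures import load_fixture

    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario id {scenario!r}; choose from {SCENARIOS}")
    table1 = load_fixture("table1")
    target_scenario = "baseline" if scenario == "historical" else scenario
    var_map = {"T": "T", "DOC": "DOC", "POC": "POC", "B": "BB"}
    regions = ("NH", "NI", "LL", "SI", "SO")
    region_values: dict = {}
    for var, tvar in var_map.items():
        region_values[var] = {
            r: (table1.value(r, "baseline", tvar), table1.value(r, target_scenario, tvar))
            for r in regions
        }
    region_values["DO"] = {r: (DEFAULT_DO, DEFAULT_DO) for r in regions}
    region_values["Z"] = {r: (v, v) for r, v in DEFAULT_Z_COLUMN.items()}
    region_values["P"] = {r: (v, v) for r, v in DEFAULT_P_COLUMN.items()}

    kinds = {"T": "average", "DO": "average", "DOC": "column", "POC": "column",
             "B": "column", "Z": "column", "P": "column"}
    shapes = {"T": "uniform", "DO": "uniform", "DOC": "surface_exp",
              "POC": "surface_exp", "B": "surface_exp", "Z": "surface_exp",
              "P": "surface_exp"}
    units = {"T": "degC", "DO": "mmol O2 m-3", "DOC": "mmol C m-3",
             "POC": "mmol C m-3", "B": "mmol C m-3", "Z": "mmol C m-3",
             "P": "mmol C m-3"}
    kw = dict(scenario=scenario, region_values=region_values, kinds=kinds,
              shapes=shapes, units=units, seed=seed)
    kw.update(overrides)
    return ScenarioSpec(**kw)


@dataclass
class FieldSet:
    """Named gridded arrays over (year, depth, lat, lon) with units metadata."""

    grid: Grid
    years: np.ndarray
    data: dict = field(default_factory=dict)
    units: dict = field(default_factory=dict)
    scenario: str = "historical"

    def add(self, name: str, values: np.ndarray, units: str) -> None:
        expected = (len(self.years), len(self.grid.depth)) + self.grid.shape
        if values.shape != expected:
            raise ValueError(f"field {name}: shape {values.shape} != {expected}")
        self.data[name] = values
        self.units[name] = units

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[name]

    def __contains__(self, name: str) -> bool:
        return name in self.data

    def year_index(self, year: int) -> int:
        idx = np.where(self.years == year)[0]
        if len(idx) == 0:
            raise KeyError(f"year {year} not in field set")
        return int(idx[0])


def _vertical_shape(name: str, depth: np.ndarray) -> np.ndarray:
    if name == "uniform":
        return np.ones_like(depth)
    if name == "surface_exp":
        return np.exp(-depth / SURFACE_SCALE)
    raise ValueError(f"unknown vertical shape {name!r}")


def _shape_scale(kind: str, shape_name: str, grid: Grid) -> np.ndarray:
    """Per-level factor turning a regional spec value into concentrations.

    Column stocks (mmol m-2 over the 0-107 m layer) are divided by the
    trapezoidal integral of the vertical shape over that layer, so the
    depth-integrated concentration recovers the spec value exactly.  Average
    variables keep the spec value at every level (uniform shape).
    """
    from .composites import depth_reduce

    s = _vertical_shape(shape_name, grid.depth)
    if kind == "average":
        return s
    integral = depth_reduce(s, grid.depth, mode="integrate", layer=(0.0, 107.0))
    return s / integral


def _smooth_anomaly(grid: Grid, rng: np.random.Generator) -> np.ndarray:
    """Seeded smooth spatial pattern in [-1, 1] from low-order harmonics."""
    lat = np.deg2rad(grid.lat)[:, None]
    lon = np.deg2rad(grid.lon)[None, :]
    out = np.zeros(grid.shape)
    for k in range(1, 4):
        a, b, pa, pb = rng.uniform(-1, 1, 2).tolist() + rng.uniform(0, 2 * np.pi, 2).tolist()
        out += a * np.sin(k * lat + pa) + b * np.cos(k * lon + pb) * np.cos(lat)
    m = np.max(np.abs(out))
    return out / m if m > 0 else out


def generate_scenario_fields(spec: ScenarioSpec, grid: Grid, years) -> FieldSet:
    """Generate all forcing fields for one scenario (bit-reproducible).

    Per cell and level::

        value = baseline * shape + anomaly + ramp(year) * (target - baseline) * shape + AR(1)

    Stocks are clipped at zero (clip count logged).  The same spec and seed
    always produce identical output.
    """
    from .composites import regionalize

    years = np.asarray(years, dtype=int)
    if len(years) == 0:
        raise ValueError("years must be non-empty")
    labels = regionalize(grid)
    fs = FieldSet(grid=grid, years=years, scenario=spec.scenario)

    r0, r1 = spec.ramp
    ramp = np.clip((years - r0) / (r1 - r0), 0.0, 1.0)
    # normalize so the target-window MEAN (the table's end-century composite
    # semantics) recovers the prescribed target, not only the final year
    w0, w1 = spec.target_window
    wyears = np.arange(w0, w1 + 1)
    wmean = float(np.mean(np.clip((wyears - r0) / (r1 - r0), 0.0, 1.0)))
    if wmean > 0:
        ramp = ramp / wmean
    if spec.scenario == "historical":
        ramp = np.zeros_like(ramp, dtype=float)

    n_y, n_d = len(years), len(grid.depth)
    n_clip_total = 0
    for iv, var in enumerate(sorted(spec.region_values)):
        rng = np.random.default_rng([spec.seed, iv])
        values = spec.region_values[var]
        base2d = np.zeros(grid.shape)
        targ2d = np.zeros(grid.shape)
        for region, (b, t) in values.items():
            m = labels == region
            base2d[m] = b
            targ2d[m] = t
        scale = _shape_scale(spec.kinds[var], spec.shapes[var], grid)  # (depth,)
        base = base2d[None, :, :] * scale[:, None, None]               # (depth, lat, lon)
        trend = (targ2d - base2d)[None, :, :] * scale[:, None, None]

        anom = spec.anomaly_frac * base * _smooth_anomaly(grid, rng)[None, :, :]

        # AR(1) in time, per cell, stationary variance (noise_frac * base)^2
        sigma = spec.noise_frac * np.abs(base)
        noise = np.zeros((n_y, n_d) + grid.shape)
        if spec.noise_frac > 0:
            eps = rng.standard_normal((n_y, n_d) + grid.shape)
            noise[0] = sigma * eps[0]
            c = np.sqrt(1.0 - spec.noise_rho ** 2)
            for t in range(1, n_y):
                noise[t] = spec.noise_rho * noise[t - 1] + c * sigma * eps[t]

        out = base[None] + anom[None] + ramp[:, None, None, None] * trend[None] + noise
        if var != "T":
            n_clip = int(np.count_nonzero(out < 0))
            if n_clip:
                n_clip_total += n_clip
                out = np.clip(out, 0.0, None)
        fs.add(var, out, spec.units[var])
    if n_clip_total:
        logger.info("generate_scenario_fields[%s]: clipped %d negative stock value(s)",
                    spec.scenario, n_clip_total)
    return fs


def _locate(grid: Grid, lat: float, lon: float, depth: float):
    """Nearest grid cell and level; stations must fall inside the grid."""
    if not (-90 <= lat <= 90) or not (grid.lat.min() - 15 <= lat <= grid.lat.max() + 15):
        raise ValueError(f"station latitude {lat} outside grid")
    i = int(np.argmin(np.abs(grid.lat - lat)))
    # longitude is periodic: use wrapped angular distance
    dlon = np.abs((grid.lon - lon + 180.0) % 360.0 - 180.0)
    j = int(np.argmin(dlon))
    k = int(np.argmin(np.abs(grid.depth - depth)))
    return i, j, k


def _harmonic(months: np.ndarray, amplitude: float, phase_month: float) -> np.ndarray:
    """Sub-annual cycle with zero mean over 12 calendar months."""
    return 1.0 + amplitude * np.sin(2 * np.pi * (months - phase_month) / 12.0)


def generate_station_obs(
    truth: FieldSet,
    stations: Sequence[tuple],
    quantity: str = "abundance",
    sigma: float = 0.3,
    missing_frac: float = 0.2,
    harmonic_amplitude: float = 0.0,
    seed: int = 0,
    ccf: float = 10.0,
    tcf: float = 3.0e18,
) -> pd.DataFrame:
    """Monthly station records sampled from a truth field.

    ``stations`` is a sequence of ``(station_id, lat, lon, depth_m)``.
    Biomass truth (variable ``B``) is reported as abundance (cells L-1) via
    the inverse carbon conversion factor; production truth (variable ``BP``)
    as thymidine incorporation (pmol L-1 h-1) via the inverse thymidine
    conversion.  Values carry a multiplicative lognormal error ``exp(sigma*N)``
    and a seeded sub-annual harmonic; records are dropped independently with
    probability ``missing_frac``.
    """
    from .skill_eval import abundance_from_biomass, thymidine_from_production

    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if not 0 <= missing_frac < 1:
        raise ValueError("missing_frac must lie in [0, 1)")
    if quantity not in ("abundance", "thymidine"):
        raise ValueError("quantity must be 'abundance' or 'thymidine'")
    var = "B" if quantity == "abundance" else "BP"
    if var not in truth:
        raise ValueError(f"truth field set lacks variable {var!r}")

    rng = np.random.default_rng(seed)
    months = np.arange(1, 13)
    rows = []
    for sid, lat, lon, depth in stations:
        i, j, k = _locate(truth.grid, lat, lon, depth)
        phase = rng.uniform(0, 12)
        cycle = _harmonic(months, harmonic_amplitude, phase)
        for iy, year in enumerate(truth.years):
            base = truth[var][iy, k, i, j]
            err = np.exp(sigma * rng.standard_normal(12)) if sigma > 0 else np.ones(12)
            keep = rng.random(12) >= missing_frac
            vals = base * cycle * err
            if quantity == "abundance":
                vals = abundance_from_biomass(vals, ccf=ccf)
            else:
                vals = thymidine_from_production(vals, tcf=tcf, ccf=ccf)
            for m, v, k_ in zip(months, vals, keep):
                if k_:
                    rows.append((sid, int(year), int(m), float(depth), quantity, float(v)))
    return pd.DataFrame(rows, columns=["station", "year", "month", "depth_m", "quantity", "value"])


def generate_gridded_obs(
    truth: FieldSet,
    coverage: float = 0.1,
    sigma: float = 0.3,
    harmonic_amplitude: float = 0.0,
    seed: int = 0,
    ccf: float = 9.1,
    level: int = 0,
) -> pd.DataFrame:
    """Monthly climatological cell records with random spatial coverage.

    Each (cell, month) is retained independently with probability
    ``coverage``; retained records carry the multi-year mean of the truth
    field at the given level, a seeded harmonic, lognormal error, and are
    reported as abundance via the inverse carbon conversion factor.
    """
    from .skill_eval import abundance_from_biomass

    if not 0 < coverage <= 1:
        raise ValueError("coverage must lie in (0, 1]")
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if "B" not in truth:
        raise ValueError("truth field set lacks variable 'B'")

    rng = np.random.default_rng(seed)
    clim = truth["B"][:, level].mean(axis=0)       # (lat, lon)
    n_lat, n_lon = truth.grid.shape
    months = np.arange(1, 13)
    phase = rng.uniform(0, 12)
    cycle = _harmonic(months, harmonic_amplitude, phase)
    keep = rng.random((n_lat, n_lon, 12)) < coverage
    err = np.exp(sigma * rng.standard_normal((n_lat, n_lon, 12))) if sigma > 0 \
        else np.ones((n_lat, n_lon, 12))
    depth = float(truth.grid.depth[level])
    rows = []
    for i in range(n_lat):
        for j in range(n_lon):
            if not truth.grid.ocean_mask[i, j]:
                continue
            for im, m in enumerate(months):
                if keep[i, j, im]:
                    v = abundance_from_biomass(clim[i, j] * cycle[im] * err[i, j, im], ccf=ccf)
                    rows.append((f"r{i:02d}c{j:02d}", 0, int(m), depth, "abundance", float(v)))
    return pd.DataFrame(rows, columns=["station", "year", "month", "depth_m", "quantity", "value"])
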