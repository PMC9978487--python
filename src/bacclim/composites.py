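"""Depth reduction, latitudinal-band masking and area-weighted composites.

Bands are half-open and poleward-inclusive: NH (lat >= 50), NI (30 <= lat <
50), LL (-30 <= lat < 30), SI (-50 <= lat < -30), SO (lat < -50); ``global``
is the union of all ocean cells.  Stocks are trapezoidally depth-integrated
over 0-107 m, temperature is depth-averaged over 10-107 m.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "REGIONS",
    "REGION_BANDS",
    "RegionalSeries",
    "ChangeSummary",
    "region_for_lat",
    "regionalize",
    "depth_reduce",
    "composite_stats",
    "change_metrics",
]

REGION_BANDS = ("NH", "NI", "LL", "SI", "SO")
REGIONS = ("global",) + REGION_BANDS

TEMPERATURE_LAYER = (10.0, 107.0)
STOCK_LAYER = (0.0, 107.0)


@dataclass
class RegionalSeries:
    """Per-year area-weighted composite of one variable over one region."""

    region: str
    variable: str
    years: np.ndarray
    mean: np.ndarray   # area-weighted spatial mean per year
    se: np.ndarray     # spatial standard error per year (over cells)
    n: int             # number of cells in the region
    units: str = ""

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("region must contain at least one cell")
        if np.any(np.asarray(self.se) < 0):
            raise ValueError("standard errors must be >= 0")

    def window_mean(self, window) -> float:
        y0, y1 = window
        m = (self.years >= y0) & (self.years <= y1)
        if not np.any(m):
            raise ValueError(f"window {window} outside series span "
                             f"({self.years.min()}-{self.years.max()})")
        return float(np.mean(self.mean[m]))


@dataclass
class ChangeSummary:
    """Baseline-vs-scenario change metrics for one regional series."""

    region: str
    variable: str
    baseline_mean: float
    scenario_mean: float
    difference: float
    percent_change: float          # nan when baseline mean is 0
    trend_per_decade: float        # OLS slope of yearly means, per 10 years
    units: str = ""


def region_for_lat(lat):
    """Vectorized latitude -> band label (string array)."""
    lat = np.asarray(lat, dtype=float)
    out = np.empty(lat.shape, dtype=object)
    out[lat >= 50] = "NH"
    out[(lat >= 30) & (lat < 50)] = "NI"
    out[(lat >= -30) & (lat < 30)] = "LL"
    out[(lat >= -50) & (lat < -30)] = "SI"
    out[lat < -50] = "SO"
    return out


def regionalize(grid) -> np.ndarray:
    """Map every grid cell to its band; returns a (lat, lon) label array."""
    labels = region_for_lat(grid.lat)
    return np.broadcast_to(labels[:, None], grid.shape).copy()


def _interp_at(levels: np.ndarray, values: np.ndarray, z: float, axis: int) -> np.ndarray:
    """Linear interpolation of a profile to depth ``z`` along ``axis``."""
    k = int(np.searchsorted(levels, z))
    if levels[min(k, len(levels) - 1)] == z:
        return np.take(values, min(k, len(levels) - 1), axis=axis)
    lo, hi = k - 1, k
    zl, zh = levels[lo], levels[hi]
    vl = np.take(values, lo, axis=axis)
    vh = np.take(values, hi, axis=axis)
    w = (z - zl) / (zh - zl)
    return vl + w * (vh - vl)


def depth_reduce(profile, levels, mode: str = "integrate", layer=STOCK_LAYER, axis: int = 0):
    """Trapezoidal reduction of a profile over a depth layer.

    ``integrate`` returns the trapezoidal integral (e.g. mmol C m-2 from
    mmol C m-3); ``average`` divides by the layer thickness.  Levels
    straddling a layer boundary are linearly interpolated to the boundary.
    The layer is clamped to the sampled depth range; fewer than two levels
    intersecting the layer is an error.
    """
    if mode not in ("integrate", "average"):
        raise ValueError("mode must be 'integrate' or 'average'")
    levels = np.asarray(levels, dtype=float)
    values = np.asarray(profile, dtype=float)
    z_top, z_bot = float(layer[0]), float(layer[1])
    if z_bot <= z_top:
        raise ValueError("layer must satisfy z_top < z_bot")
    z_top = max(z_top, float(levels[0]))
    z_bot = min(z_bot, float(levels[-1]))
    if z_bot <= z_top:
        raise ValueError("layer does not intersect the sampled depth range")
    inside = (levels > z_top) & (levels < z_bot)
    n_nodes = int(np.count_nonzero(inside)) + 2  # interior levels + both boundaries
    if n_nodes < 2 or np.count_nonzero((levels >= z_top) & (levels <= z_bot)) < 2:
        raise ValueError("need at least 2 depth levels intersecting the layer")

    axis = axis % values.ndim
    nodes_z = [z_top] + list(levels[inside]) + [z_bot]
    nodes_v = [_interp_at(levels, values, z_top, axis)]
    for z in levels[inside]:
        nodes_v.append(np.take(values, int(np.where(levels == z)[0][0]), axis=axis))
    nodes_v.append(_interp_at(levels, values, z_bot, axis))
    stacked = np.stack(nodes_v, axis=axis)
    integral = np.trapezoid(stacked, x=np.asarray(nodes_z), axis=axis)
    if mode == "average":
        return integral / (z_bot - z_top)
    return integral


def composite_stats(field, grid, variable: str = "", units: str = "", years=None) -> dict:
    """Area-weighted regional composites of a depth-reduced field.

    ``field`` has shape (lat, lon) or (year, lat, lon).  The mean is the
    cos-latitude-weighted average over the region's ocean cells; the standard
    error is the unweighted spatial standard deviation across cells divided
    by sqrt(n) (cell-count semantics).  Returns ``{region: RegionalSeries}``
    for the five bands plus ``global``.
    """
    field = np.asarray(field, dtype=float)
    if field.ndim == 2:
        field = field[None]
        years_arr = np.array([0]) if years is None else np.asarray(years)
    else:
        years_arr = np.arange(field.shape[0]) if years is None else np.asarray(years)
    if field.shape[-2:] != grid.shape:
        raise ValueError("field shape does not match grid")
    if np.any(np.isnan(field[:, grid.ocean_mask])):
        raise ValueError("reduced field contains NaN over ocean cells")

    labels = regionalize(grid)
    out = {}
    for region in REGIONS:
        m = grid.ocean_mask if region == "global" else (labels == region) & grid.ocean_mask
        n = int(np.count_nonzero(m))
        if n == 0:
            raise ValueError(f"region {region} is empty")
        w = grid.area_weights[m]
        w = w / w.sum()
        vals = field[:, m]                       # (year, cells)
        mean = vals @ w
        if n > 1:
            se = vals.std(axis=1, ddof=1) / np.sqrt(n)
        else:
            se = np.zeros(field.shape[0])
        out[region] = RegionalSeries(region=region, variable=variable,
                                     years=years_arr, mean=mean, se=se, n=n,
                                     units=units)
    return out


def change_metrics(series: RegionalSeries,
                   baseline_window=(1990, 2013),
                   scenario_window=(2076, 2099)) -> ChangeSummary:
    """Difference, ratio percent change and OLS trend of a regional series."""
    base = series.window_mean(baseline_window)
    scen = series.window_mean(scenario_window)
    diff = scen - base
    pct = (scen / base - 1.0) * 100.0 if base != 0 else float("nan")
    slope = float(np.polyfit(series.years.astype(float), series.mean, 1)[0]) * 10.0
    return ChangeSummary(region=series.region, variable=series.variable,
                         baseline_mean=base, scenario_mean=scen, difference=diff,
                         percent_change=pct, trend_per_decade=slope,
                         units=series.units)
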