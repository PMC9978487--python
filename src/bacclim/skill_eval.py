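"""Model-observation matching, microbial unit conversions and skill scores.

Conversions: cell abundance (cells L-1) to carbon biomass (mmol C m-3) via a
carbon-per-cell factor, and thymidine incorporation (pmol L-1 h-1) to carbon
production (mmol C m-3 d-1) via a cells-per-mole thymidine factor.  Skill
metrics are the univariate set: bias (model minus observation), average
absolute error, RMSD with its bias/centered decomposition, Pearson
correlation, and a multiplicative reliability index RI = exp(rms(ln(O/P)))
under which about 68% of predictions fall within [O/RI, O*RI].
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConversionConstants",
    "SkillReport",
    "convert_abundance",
    "abundance_from_biomass",
    "convert_thymidine",
    "thymidine_from_production",
    "match_model_obs",
    "skill_scores",
    "tcf_sensitivity",
]

C_MOLAR_MASS = 12.011  # g mol-1


@dataclass(frozen=True)
class ConversionConstants:
    """Carbon and thymidine conversion factors with their sensitivity range."""

    ccf_station: float = 10.0       # fg C cell-1 (station time series)
    ccf_gridded: float = 9.1        # fg C cell-1 (gridded climatology)
    tcf: float = 3.0e18             # cells produced per mole thymidine
    tcf_min: float = 0.5e18
    tcf_max: float = 4.9e18
    c_molar_mass: float = C_MOLAR_MASS

    def __post_init__(self) -> None:
        for name in ("ccf_station", "ccf_gridded", "tcf", "tcf_min", "tcf_max", "c_molar_mass"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def convert_abundance(abundance, ccf: float = 10.0):
    """Cells L-1 -> mmol C m-3.

    L->m3 (1e3), fg C per cell, fg->g (1e-15), g->mol (/12.011), mol->mmol (1e3).
    """
    if ccf <= 0:
        raise ValueError("ccf must be positive")
    abundance = np.asarray(abundance, dtype=float)
    if np.any(abundance < 0):
        raise ValueError("abundance must be >= 0")
    out = abundance * 1e3 * ccf * 1e-15 / C_MOLAR_MASS * 1e3
    return float(out) if out.ndim == 0 else out


def abundance_from_biomass(biomass, ccf: float = 10.0):
    """Inverse of :func:`convert_abundance` (mmol C m-3 -> cells L-1)."""
    if ccf <= 0:
        raise ValueError("ccf must be positive")
    biomass = np.asarray(biomass, dtype=float)
    if np.any(biomass < 0):
        raise ValueError("biomass must be >= 0")
    out = biomass * C_MOLAR_MASS / (ccf * 1e-9)
    return float(out) if out.ndim == 0 else out


def convert_thymidine(tdr, tcf: float = 3.0e18, ccf: float = 10.0):
    """pmol L-1 h-1 -> mmol C m-3 d-1 via cells-per-mole and carbon-per-cell."""
    if tcf <= 0:
        raise ValueError("tcf must be positive")
    tdr = np.asarray(tdr, dtype=float)
    if np.any(tdr < 0):
        raise ValueError("thymidine incorporation must be >= 0")
    cells_per_l_per_day = tdr * 1e-12 * tcf * 24.0
    return convert_abundance(cells_per_l_per_day, ccf=ccf)


def thymidine_from_production(production, tcf: float = 3.0e18, ccf: float = 10.0):
    """Inverse of :func:`convert_thymidine` (mmol C m-3 d-1 -> pmol L-1 h-1)."""
    if tcf <= 0:
        raise ValueError("tcf must be positive")
    cells = abundance_from_biomass(production, ccf=ccf)
    out = np.asarray(cells, dtype=float) / (1e-12 * tcf * 24.0)
    return float(out) if out.ndim == 0 else out


def match_model_obs(
    model,
    obs: pd.DataFrame,
    mode: str = "monthly",
    variable: str = None,
    ccf: float = 10.0,
    tcf: float = 3.0e18,
) -> pd.DataFrame:
    """Pair converted observations with co-located model values.

    Observations (schema of the synthetic generators: station, year, month,
    depth_m, quantity, value) are converted to model units, then averaged to
    climatological monthly means per location (``monthly``) or to per-year
    means (``yearly``), and paired with the model value at the nearest cell
    and level averaged over the overlapping years.  Returns a data frame with
    columns location, period, obs, model.
    """
    if mode not in ("monthly", "yearly"):
        raise ValueError("mode must be 'monthly' or 'yearly'")
    if obs.empty:
        raise ValueError("no observations provided")
    quantities = set(obs["quantity"].unique())
    if len(quantities) > 1:
        raise ValueError("mixed observation quantities; pass one at a time")
    quantity = quantities.pop()
    if variable is None:
        variable = {"abundance": "B", "thymidine": "BP"}[quantity]

    obs = obs.copy()
    if quantity == "abundance":
        obs["converted"] = convert_abundance(obs["value"].to_numpy(), ccf=ccf)
    elif quantity == "thymidine":
        obs["converted"] = convert_thymidine(obs["value"].to_numpy(), tcf=tcf, ccf=ccf)
    else:
        raise ValueError(f"unknown observation quantity {quantity!r}")

    model_years = set(int(y) for y in model.years)
    obs_years = set(int(y) for y in obs["year"].unique())
    overlap = sorted(model_years & obs_years)
    # gridded climatologies carry year 0: compare against the full model span
    climatological = obs_years == {0}
    if not overlap and not climatological:
        raise ValueError("no overlapping years between model and observations")
    if not climatological:
        obs = obs[obs["year"].isin(overlap)]
    year_idx = [model.year_index(y) for y in (overlap if not climatological else model.years)]

    rows = []
    groups = obs.groupby(["station", "depth_m"])
    for (station, depth), g in groups:
        # station ids of gridded records encode the cell; others are located
        if isinstance(station, str) and station.startswith("r") and "c" in station[1:]:
            i = int(station[1:3])
            j = int(station[station.index("c") + 1:])
            k = int(np.argmin(np.abs(model.grid.depth - depth)))
        else:
            i, j, k = _station_cell(model, station, depth, obs)
        model_val = float(np.mean(model[variable][year_idx, k, i, j]))
        if mode == "monthly":
            clim = g.groupby("month")["converted"].mean()
            for month, o in clim.items():
                rows.append((station, int(month), float(o), model_val))
        else:
            if climatological:
                rows.append((station, 0, float(g["converted"].mean()), model_val))
            else:
                for year, o in g.groupby("year")["converted"].mean().items():
                    rows.append((station, int(year), float(o), model_val))
    if not rows:
        raise ValueError("no model-observation pairs could be formed")
    return pd.DataFrame(rows, columns=["location", "period", "obs", "model"])


#: station metadata registered by callers: {station_id: (lat, lon)}
STATION_LOCATIONS: dict = {}


def register_stations(stations) -> None:
    """Register ``(station_id, lat, lon, depth)`` tuples for pairing."""
    for sid, lat, lon, _depth in stations:
        STATION_LOCATIONS[sid] = (lat, lon)


def _station_cell(model, station, depth, obs):
    from .scenario_synth import _locate

    if station not in STATION_LOCATIONS:
        raise ValueError(
            f"unknown station {station!r}: register its location with register_stations()"
        )
    lat, lon = STATION_LOCATIONS[station]
    return _locate(model.grid, lat, lon, depth)


@dataclass
class SkillReport:
    """Univariate model-observation skill metrics."""

    n: int
    bias: float           # mean(model - obs)
    aae: float            # mean |model - obs|
    rmsd: float
    crmsd: float          # centered (unbiased) RMSD
    r: float              # Pearson correlation (nan if undefined)
    p_value: float
    ri: float             # reliability index (nan for non-positive data)
    units: str = ""

    def as_dict(self) -> dict:
        return {
            "n": self.n, "bias": self.bias, "aae": self.aae, "rmsd": self.rmsd,
            "crmsd": self.crmsd, "r": self.r, "p_value": self.p_value,
            "ri": self.ri, "units": self.units,
        }


def skill_scores(obs, model=None, units: str = "") -> SkillReport:
    """Compute the full univariate skill score set for paired series.

    Accepts either a pairs frame from :func:`match_model_obs` or two arrays
    (observations first).  The RMSD decomposition ``rmsd^2 = bias^2 +
    crmsd^2`` holds exactly; the correlation is flagged NaN for constant
    inputs or n < 2, the reliability index NaN when any value is
    non-positive.
    """
    if model is None:
        if not isinstance(obs, pd.DataFrame):
            raise TypeError("pass a pairs data frame or two arrays")
        O = obs["obs"].to_numpy(dtype=float)
        P = obs["model"].to_numpy(dtype=float)
    else:
        O = np.asarray(obs, dtype=float)
        P = np.asarray(model, dtype=float)
    if O.shape != P.shape or O.ndim != 1:
        raise ValueError("obs and model must be 1-d arrays of equal length")
    n = O.size
    if n < 1:
        raise ValueError("need at least one pair")

    diff = P - O
    bias = float(diff.mean())
    aae = float(np.abs(diff).mean())
    rmsd = float(np.sqrt(np.mean(diff ** 2)))
    crmsd = float(diff.std(ddof=0))  # population std => exact decomposition

    if n >= 2 and np.std(O) > 0 and np.std(P) > 0:
        import warnings as _warnings

        with _warnings.catch_warnings():
            # near-constant inputs: report NaN rather than an unstable r
            _warnings.simplefilter("ignore", stats.ConstantInputWarning)
            _warnings.simplefilter("ignore", getattr(stats, "NearConstantInputWarning",
                                                     stats.ConstantInputWarning))
            r_res = stats.pearsonr(O, P)
        r, p = float(r_res.statistic), float(r_res.pvalue)
    else:
        r, p = float("nan"), float("nan")

    if np.all(O > 0) and np.all(P > 0):
        ri = float(np.exp(np.sqrt(np.mean(np.log(O / P) ** 2))))
    else:
        ri = float("nan")
    return SkillReport(n=n, bias=bias, aae=aae, rmsd=rmsd, crmsd=crmsd,
                       r=r, p_value=p, ri=ri, units=units)


def tcf_sensitivity(baseline_ratio: float, tcf_alt: float, tcf_base: float) -> float:
    """Rescale a model/observation overestimation factor to another
    thymidine conversion factor (proportional rule)."""
    if baseline_ratio <= 0 or tcf_alt <= 0 or tcf_base <= 0:
        raise ValueError("all inputs must be positive")
    return baseline_ratio * tcf_alt / tcf_base
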