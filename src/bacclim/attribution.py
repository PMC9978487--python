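"""First-order Taylor attribution of changes in the specific DOC uptake rate.

The free-living specific uptake rate is a product ``mu_max * f_T * f_DOC`` of
a Q10 temperature factor and a cubic Monod DOC factor, so its change between
two period means splits exactly into a DOC-control term (change in the DOC
factor weighted by the baseline temperature factor), a temperature-control
term (change in the temperature factor weighted by the baseline DOC factor)
and a cross-term residual::

    total    = mu_max * (f_T' * f_DOC' - f_T * f_DOC)
    doc_term = mu_max * (f_DOC' - f_DOC) * f_T
    t_term   = mu_max * (f_T' - f_T) * f_DOC
    residual = total - doc_term - t_term  (= mu_max * df_T * df_DOC)

The attached-cell rate couples biomass into its own limitation factor and is
deliberately not decomposed.  A conventional Arrhenius regression of
production on inverse absolute temperature is provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .composites import REGIONS, STOCK_LAYER, composite_stats, depth_reduce
from .model_core import ModelParams, _cubic_sigmoid, temperature_factor

__all__ = [
    "GAS_CONSTANT",
    "DAYS_PER_YEAR",
    "DecompositionResult",
    "ArrheniusFit",
    "limitation_terms",
    "taylor_terms",
    "taylor_decompose",
    "arrhenius_fit",
]

GAS_CONSTANT = 8.314        # J mol-1 K-1
DAYS_PER_YEAR = 365.0
KELVIN_OFFSET = 273.15


@dataclass
class DecompositionResult:
    """Regional composite of the decomposition terms (column units, per year)."""

    region: str
    scenario: str
    total: float
    doc_term: float
    temp_term: float
    residual: float
    shares: dict = field(default_factory=dict)   # % of total per term
    units: str = "m yr-1 (column-integrated specific rate)"

    def __post_init__(self) -> None:
        closure = self.doc_term + self.temp_term + self.residual
        tol = 1e-10 * max(abs(self.total), 1e-30)
        if abs(closure - self.total) > tol:
            raise ValueError("decomposition terms do not add up to the total change")


@dataclass
class ArrheniusFit:
    """OLS fit of ln(production) on inverse absolute temperature."""

    Ea: float          # apparent activation energy (kJ mol-1)
    BP0: float         # pre-exponential production (input units)
    r_squared: float
    n: int
    gas_constant: float = GAS_CONSTANT


def limitation_terms(T, DOC, p: ModelParams):
    """Temperature and DOC limitation factors (shared with the box model)."""
    f_T = temperature_factor(T, p.Q10_B, p.T_ref)
    f_DOC = _cubic_sigmoid(DOC, p.X_DOC)
    return f_T, f_DOC


def taylor_terms(T_base, DOC_base, T_scen, DOC_scen, p: ModelParams) -> dict:
    """Cell-wise decomposition terms (d-1) between two period-mean states."""
    f_T0, f_D0 = limitation_terms(T_base, DOC_base, p)
    f_T1, f_D1 = limitation_terms(T_scen, DOC_scen, p)
    total = p.mu_max * (f_T1 * f_D1 - f_T0 * f_D0)
    doc_term = p.mu_max * (f_D1 - f_D0) * f_T0
    temp_term = p.mu_max * (f_T1 - f_T0) * f_D0
    residual = total - doc_term - temp_term
    return {"total": total, "doc": doc_term, "temp": temp_term, "residual": residual}


def _shares(total: float, doc: float, temp: float, resid: float) -> dict:
    if total == 0:
        return {"doc": float("nan"), "temp": float("nan"), "residual": float("nan")}
    return {"doc": 100.0 * doc / total,
            "temp": 100.0 * temp / total,
            "residual": 100.0 * resid / total}


def taylor_decompose(
    baseline: dict,
    scenario: dict,
    p: ModelParams,
    grid,
    scenario_id: str = "",
    order: str = "cellwise",
    annualize: bool = True,
) -> dict:
    """Regional composites of the Taylor decomposition.

    ``baseline`` and ``scenario`` map ``{"T": ..., "DOC": ...}`` to
    period-mean fields of shape (depth, lat, lon) on ``grid``.  With
    ``order="cellwise"`` (default) the decomposition is evaluated per cell
    and level, depth-integrated over the stock layer, then area-composited;
    ``order="composite_first"`` decomposes the regional composite means
    instead (sensitivity check).  Terms are multiplied by days-per-year when
    ``annualize`` is set.  Returns ``{region: DecompositionResult}``.
    """
    for d in (baseline, scenario):
        for key in ("T", "DOC"):
            if key not in d:
                raise ValueError(f"period means must provide {key!r}")
            if np.shape(d[key]) != (len(grid.depth),) + grid.shape:
                raise ValueError(f"period-mean field {key!r} does not match the grid")
    if order not in ("cellwise", "composite_first"):
        raise ValueError("order must be 'cellwise' or 'composite_first'")

    factor = DAYS_PER_YEAR if annualize else 1.0
    out = {}
    if order == "cellwise":
        terms = taylor_terms(baseline["T"], baseline["DOC"], scenario["T"], scenario["DOC"], p)
        reduced = {k: depth_reduce(v, grid.depth, mode="integrate", layer=STOCK_LAYER)
                   for k, v in terms.items()}
        stats_by_term = {k: composite_stats(v, grid, variable=k) for k, v in reduced.items()}
        for region in REGIONS:
            tot = float(stats_by_term["total"][region].mean[0]) * factor
            doc = float(stats_by_term["doc"][region].mean[0]) * factor
            tmp = float(stats_by_term["temp"][region].mean[0]) * factor
            res = tot - doc - tmp
            out[region] = DecompositionResult(region=region, scenario=scenario_id,
                                              total=tot, doc_term=doc, temp_term=tmp,
                                              residual=res,
                                              shares=_shares(tot, doc, tmp, res))
    else:
        # composite T (layer average) and DOC (column, back to a mean
        # concentration) first, then decompose the regional scalars
        comp = {}
        for name, d in (("base", baseline), ("scen", scenario)):
            t_red = depth_reduce(d["T"], grid.depth, mode="average", layer=(10.0, 107.0))
            c_red = depth_reduce(d["DOC"], grid.depth, mode="average", layer=STOCK_LAYER)
            comp[name] = {
                "T": composite_stats(t_red, grid),
                "DOC": composite_stats(c_red, grid),
            }
        thickness = STOCK_LAYER[1] - STOCK_LAYER[0]
        for region in REGIONS:
            t0 = float(comp["base"]["T"][region].mean[0])
            c0 = float(comp["base"]["DOC"][region].mean[0])
            t1 = float(comp["scen"]["T"][region].mean[0])
            c1 = float(comp["scen"]["DOC"][region].mean[0])
            terms = taylor_terms(t0, c0, t1, c1, p)
            tot = float(terms["total"]) * factor * thickness
            doc = float(terms["doc"]) * factor * thickness
            tmp = float(terms["temp"]) * factor * thickness
            res = tot - doc - tmp
            out[region] = DecompositionResult(region=region, scenario=scenario_id,
                                              total=tot, doc_term=doc, temp_term=tmp,
                                              residual=res,
                                              shares=_shares(tot, doc, tmp, res))
    return out


def arrhenius_fit(BP, T_celsius) -> ArrheniusFit:
    """Apparent activation energy from an Arrhenius plot.

    Ordinary least squares of ``ln(BP)`` on ``1/T`` (T absolute); the energy
    is the absolute slope times the gas constant, reported in kJ mol-1.
    """
    BP = np.asarray(BP, dtype=float)
    T = np.asarray(T_celsius, dtype=float) + KELVIN_OFFSET
    if BP.size < 3:
        raise ValueError("need at least 3 points for an Arrhenius fit")
    if np.any(BP <= 0):
        raise ValueError("production values must be positive")
    if np.unique(T).size < 2:
        raise ValueError("temperatures must not all be identical")
    res = stats.linregress(1.0 / T, np.log(BP))
    return ArrheniusFit(Ea=abs(res.slope) * GAS_CONSTANT / 1000.0,
                        BP0=float(np.exp(res.intercept)),
                        r_squared=float(res.rvalue ** 2),
                        n=int(BP.size))
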