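"""Exposure-response workability, population weighting, and the annual shock τ.

Three exposure standards translate hourly WBGT into workability — the
fraction of the hour a person can work (1 = unimpaired, 0 = no work):

* **ISO** and **NIOSH**: a clamped linear ramp between the workload-specific
  limit ``WBGT_lim(M)`` (workability 1) and the resting limit
  ``WBGT_lim(M_rest)`` (workability 0), with
  ``WBGT_lim,ISO = 34.9 − M/46`` and ``WBGT_lim,NIOSH = 56.7 − 11.5·log10 M``.
* **Hothaps**: the two-parameter logistic
  ``0.1 + 0.9 / (1 + (WBGT/α1)^α2)`` with a 10% floor (6 min of work per hour
  remain possible under any heat).

Workload classes carry metabolic rates M = 200/300/400 W (low/moderate/high);
the resting rate is 117 W. Outdoor sectors are evaluated against WBGT_sun,
indoor sectors against WBGT_shade.

Hourly workability is averaged over the working day (9–17 h, half-open: hours
9..16), aggregated to regions with population weights, and heatwave-day
losses (1 − workability) are annualised into the labour-productivity shock

    τ_rs = Σ_q w_qrs · (Σ_{heatwave working days d ∈ q} loss_rsd) / D_q,

where w_qrs are quarterly activity shares (Σ_q w_qrs = 1) and D_q counts the
calendar working days (Mon–Fri) of quarter q. Only heatwave days contribute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from shapely import contains_xy

from .errors import ConfigError, CoverageError
from .heatwaves import HeatwaveCatalogue
from .synthetic.regions import Region

#: metabolic rate per workload class, W
METABOLIC_RATES = {"low": 200.0, "moderate": 300.0, "high": 400.0}
#: resting metabolic rate, W
M_REST = 117.0
#: Hothaps logistic parameters (alpha1, alpha2) per workload class
HOTHAPS_PARAMS = {
    "low": (34.64, 22.72),
    "moderate": (32.93, 17.81),
    "high": (30.94, 16.64),
}
STANDARDS = ("ISO", "NIOSH", "Hothaps")
WORKING_HOURS = (9, 17)


def wbgt_lim(M: float, standard: str) -> float:
    """Workload-limit WBGT (°C) above which workability starts to fall."""
    if M <= 0:
        raise ConfigError("metabolic rate must be positive")
    if standard == "ISO":
        return 34.9 - M / 46.0
    if standard == "NIOSH":
        return 56.7 - 11.5 * np.log10(M)
    raise ConfigError(f"unknown standard {standard!r} (ISO or NIOSH)")


def workability(wbgt, workload: str, standard: str):
    """Hourly workability fraction for a workload class under a standard.

    Vectorised over ``wbgt``. ISO/NIOSH values lie in [0, 1]; Hothaps in
    [0.1, 1] (both bounds attained in the limits WBGT → ∓∞).
    """
    if workload not in METABOLIC_RATES:
        raise ConfigError(f"unknown workload class {workload!r}")
    w = np.asarray(wbgt, dtype=float)
    if standard in ("ISO", "NIOSH"):
        lim = wbgt_lim(METABOLIC_RATES[workload], standard)
        lim_rest = wbgt_lim(M_REST, standard)
        return np.clip((lim_rest - w) / (lim_rest - lim), 0.0, 1.0)
    if standard == "Hothaps":
        a1, a2 = HOTHAPS_PARAMS[workload]
        return np.where(w > 0, 0.1 + 0.9 / (1.0 + (np.maximum(w, 1e-12) / a1) ** a2), 1.0)
    raise ConfigError(f"unknown standard {standard!r}")


def daily_shift_workability(hourly: pd.Series | pd.DataFrame) -> pd.Series | pd.DataFrame:
    """Mean workability over the 8 working hours (9..16 h) of each day."""
    idx = pd.DatetimeIndex(hourly.index)
    h0, h1 = WORKING_HOURS
    work = hourly[(idx.hour >= h0) & (idx.hour < h1)]
    days = pd.DatetimeIndex(work.index).normalize()
    counts = work.groupby(days).size()
    if len(counts) == 0 or (counts != h1 - h0).any():
        raise CoverageError("working hours 9–17 not fully present")
    return work.groupby(days).mean()


def interpolate_population(pop: xr.DataArray, year: int) -> xr.DataArray:
    """Population linearly interpolated between snapshot years; clamped outside."""
    years = pop["year"].values
    y = float(np.clip(year, years.min(), years.max()))
    return pop.interp(year=y)


def population_regional_mean(
    field: xr.DataArray,
    pop: xr.DataArray,
    regions: list[Region],
    year: int | None = None,
) -> pd.DataFrame:
    """Population-weighted regional mean of a gridded (time, lat, lon) field.

    The climate field is regridded to the population grid by nearest
    neighbour; a region's value is Σ(pop·x)/Σ(pop) over population cells
    whose centers fall inside the region polygon. A region with zero
    population falls back to the unweighted mean (with a warning).
    """
    if year is not None and "year" in pop.dims:
        pop = interpolate_population(pop, year)
    on_pop = field.interp(lat=pop["lat"], lon=pop["lon"], method="nearest")
    lon2d, lat2d = np.meshgrid(pop["lon"].values, pop["lat"].values)
    vals = on_pop.transpose("time", "lat", "lon").values
    popv = pop.values
    out = {}
    for reg in regions:
        mask = contains_xy(reg.polygon, lon2d, lat2d)
        if not mask.any():
            raise ConfigError(f"region {reg.region_id} contains no grid cell centers")
        w = popv[mask]
        x = vals[:, mask]
        if w.sum() <= 0:
            warnings.warn(f"region {reg.region_id} has zero population; using unweighted mean")
            out[reg.region_id] = x.mean(axis=1)
        else:
            out[reg.region_id] = x @ (w / w.sum())
    return pd.DataFrame(out, index=pd.DatetimeIndex(field["time"].values))


@dataclass
class ProductivityShock:
    """Annual-equivalent labour-productivity reduction τ per region (rows) and sector (cols)."""

    tau: pd.DataFrame
    year: int

    def __post_init__(self):
        if ((self.tau < 0) | (self.tau >= 1)).any().any():
            raise ConfigError("tau must lie in [0, 1)")


def uniform_quarterly_weights(regions: list[str], sectors: list[str]) -> pd.DataFrame:
    """Flat seasonal pattern: w_qrs = 1/4 for every (region, sector)."""
    idx = pd.MultiIndex.from_product([regions, sectors], names=["region", "sector"])
    return pd.DataFrame(0.25, index=idx, columns=[1, 2, 3, 4])


def working_days_per_quarter(year: int) -> pd.Series:
    """Number of Mon–Fri days in each quarter of *year*."""
    days = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
    wd = days[days.weekday < 5]
    return pd.Series(wd.quarter).value_counts().sort_index()


def annualize_shock(
    daily_losses: pd.DataFrame,
    catalogue: HeatwaveCatalogue,
    weights: pd.DataFrame,
    year: int,
) -> ProductivityShock:
    """Annual-equivalent shock τ_rs from heatwave-day productivity losses.

    ``daily_losses``: daily (1 − workability), index = dates, columns =
    MultiIndex (region, sector). Only days that belong to a catalogued
    heatwave of the respective region — and are working days — contribute.
    ``weights``: quarterly activity shares, index (region, sector), columns
    1–4 summing to 1 per row.
    """
    if not np.allclose(weights.sum(axis=1), 1.0, atol=1e-9):
        raise ConfigError("quarterly weights must sum to 1 per (region, sector)")
    idx = pd.DatetimeIndex(daily_losses.index)
    dq = working_days_per_quarter(year)
    pairs = daily_losses.columns
    tau = {}
    for region, sector in pairs:
        hw_days = catalogue.event_days(region)
        sel = idx.isin(hw_days) & (idx.weekday < 5) & (idx.year == year)
        series = daily_losses[(region, sector)].to_numpy()[sel]
        quarters = idx[sel].quarter
        w = weights.loc[(region, sector)]
        total = 0.0
        for q in (1, 2, 3, 4):
            loss_q = series[quarters == q].sum()
            total += float(w[q]) * loss_q / float(dq[q])
        tau[(region, sector)] = min(total, 1.0 - 1e-12)
    frame = pd.Series(tau).unstack()
    frame.index.name, frame.columns.name = "region", "sector"
    return ProductivityShock(tau=frame, year=year)
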