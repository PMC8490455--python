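"""Synthetic hourly meteorology with a seasonal/diurnal cycle and injectable hot spells.

The generator produces the four WBGT input variables — near-surface air
temperature (``tas``, °C), dew-point temperature (``tdps``, °C), downwelling
solar radiation (``rsds``, W m⁻²) and wind speed (``sfcWind``, m s⁻¹) — on a
regular lat/lon grid at hourly resolution, as an :class:`xarray.Dataset`.

Structure of the temperature signal, per grid cell::

    tas(t) = base_mean + seasonal(doy) + daily_anomaly(day) + diurnal(hour) + hourly_noise

* ``seasonal``: sinusoid peaking in mid-July (northern hemisphere), amplitude
  ``seasonal_amplitude`` — so the July-minus-January monthly-mean difference
  is ≈ 2 × amplitude.
* ``daily_anomaly``: AR(1) process (lag-1 correlation ``anomaly_rho``) with
  stationary standard deviation ``noise_sd``; temporal persistence makes
  multi-day exceedance runs possible, as in real weather.
* ``diurnal``: sinusoid peaking at 15 h local time, amplitude
  ``diurnal_amplitude``.

Dew point is the air temperature minus a positive dew-point depression drawn
daily from a Gamma distribution, which guarantees ``tdps <= tas`` by
construction; the depression mean decreases with the ``maritime`` parameter
(1 = saturated maritime air, 0 = dry continental air).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr

from ..errors import ConfigError

HOURS_PER_DAY = 24
#: hour of day at which the diurnal cycle peaks
PEAK_HOUR = 15
#: day of year of the seasonal minimum (mid-January); the maximum falls ~half a year later
SEASONAL_MIN_DOY = 15


@dataclass
class SyntheticClimateConfig:
    """Configuration of the synthetic-climate generator.

    Parameters
    ----------
    grid_shape : (ny, nx) cells.
    years : inclusive (first, last) calendar year.
    base_mean : annual-mean temperature, °C. Scalar or (ny, nx) array.
    seasonal_amplitude : half peak-to-trough amplitude of the seasonal cycle, °C.
    diurnal_amplitude : half peak-to-trough amplitude of the diurnal cycle, °C.
    noise_sd : stationary s.d. of the AR(1) daily temperature anomaly, °C.
    anomaly_rho : lag-1 autocorrelation of the daily anomaly.
    maritime : in [0, 1]; controls mean dew-point depression
        ``max_depression * (1 - maritime)``.
    max_depression : dew-point depression mean for fully continental air, °C.
    wind_median, wind_sigma : lognormal wind-speed parameters (m s⁻¹, log-s.d.).
    solar_peak : clear-sky noon irradiance at the summer peak, W m⁻².
    seed : RNG seed; identical configs produce bit-identical output.
    """

    grid_shape: tuple[int, int] = (4, 4)
    years: tuple[int, int] = (2000, 2000)
    base_mean: float | np.ndarray = 14.0
    seasonal_amplitude: float = 10.0
    diurnal_amplitude: float = 5.0
    noise_sd: float = 2.0
    anomaly_rho: float = 0.7
    maritime: float = 0.5
    max_depression: float = 12.0
    wind_median: float = 2.0
    wind_sigma: float = 0.4
    solar_peak: float = 850.0
    lat0: float = 40.0
    lon0: float = 0.0
    dlat: float = 0.5
    dlon: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        ny, nx = self.grid_shape
        if ny <= 0 or nx <= 0:
            raise ConfigError(f"grid_shape must be positive, got {self.grid_shape}")
        if self.years[1] < self.years[0]:
            raise ConfigError(f"years span is empty: {self.years}")
        if self.diurnal_amplitude < 0:
            raise ConfigError("diurnal_amplitude must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if not (0.0 <= self.maritime <= 1.0):
            raise ConfigError("maritime must lie in [0, 1]")
        if not (0.0 <= self.anomaly_rho < 1.0):
            raise ConfigError("anomaly_rho must lie in [0, 1)")


@dataclass
class HeatwaveSpec:
    """A hot spell to superimpose on a generated field.

    ``amplitude`` °C is added to every hour of the affected days (hence to the
    daily maximum exactly), following the ``shape`` profile over the event:
    ``"block"`` (constant) or ``"triangle"`` (ramp up to the peak mid-event and
    back down, never below half the amplitude so detection-relevant days stay
    forced). ``cells`` restricts the injection to a list of (iy, ix) grid
    indices; ``None`` affects the whole grid.
    """

    start: str | pd.Timestamp = "2000-07-01"
    duration: int = 5
    amplitude: float = 8.0
    shape: str = "block"
    cells: list[tuple[int, int]] | None = None

    def profile(self) -> np.ndarray:
        if self.duration < 1:
            raise ConfigError("heatwave duration must be >= 1 day")
        if self.amplitude < 0:
            raise ConfigError("heatwave amplitude must be >= 0")
        if self.shape == "block":
            return np.full(self.duration, self.amplitude)
        if self.shape == "triangle":
            x = np.arange(self.duration)
            mid = (self.duration - 1) / 2.0
            ramp = 1.0 - np.abs(x - mid) / max(mid, 1.0)
            return self.amplitude * (0.5 + 0.5 * ramp)
        raise ConfigError(f"unknown heatwave shape {self.shape!r}")


def _seasonal(doy: np.ndarray, amplitude: float) -> np.ndarray:
    # minimum at SEASONAL_MIN_DOY, maximum half a year later
    return -amplitude * np.cos(2.0 * np.pi * (doy - SEASONAL_MIN_DOY) / 365.25)


def _diurnal(hour: np.ndarray, amplitude: float) -> np.ndarray:
    return amplitude * np.cos(2.0 * np.pi * (hour - PEAK_HOUR) / HOURS_PER_DAY)


def _daylight(doy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(half day length in hours, seasonal irradiance factor in (0, 1])."""
    s = -np.cos(2.0 * np.pi * (doy - SEASONAL_MIN_DOY) / 365.25)  # -1 winter .. +1 summer
    half_len = (12.0 + 4.0 * s) / 2.0
    factor = 0.55 + 0.45 * s
    return half_len, factor


def generate_meteo(config: SyntheticClimateConfig) -> xr.Dataset:
    """Generate the hourly meteorological field described by *config*.

    Returns an :class:`xarray.Dataset` with dimensions ``(time, lat, lon)``
    and variables ``tas``, ``tdps``, ``rsds``, ``sfcWind``. Solar radiation is
    zero at night; dew point never exceeds air temperature; output is
    bit-identical for identical configs (single seeded generator).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ny, nx = config.grid_shape

    t0 = pd.Timestamp(f"{config.years[0]}-01-01 00:00")
    t1 = pd.Timestamp(f"{config.years[1]}-12-31 23:00")
    time = pd.date_range(t0, t1, freq="h")
    n_hours = len(time)
    n_days = n_hours // HOURS_PER_DAY

    doy = time.dayofyear.to_numpy()
    hour = time.hour.to_numpy()
    day_index = np.arange(n_hours) // HOURS_PER_DAY

    base = np.broadcast_to(np.asarray(config.base_mean, dtype=float), (ny, nx))

    # AR(1) daily anomaly, stationary s.d. = noise_sd, per cell
    if config.noise_sd > 0:
        innov_sd = config.noise_sd * np.sqrt(1.0 - config.anomaly_rho**2)
        eps = rng.normal(0.0, innov_sd, size=(n_days, ny, nx))
        eps[0] = rng.normal(0.0, config.noise_sd, size=(ny, nx))
        anom = np.empty_like(eps)
        anom[0] = eps[0]
        for d in range(1, n_days):
            anom[d] = config.anomaly_rho * anom[d - 1] + eps[d]
    else:
        anom = np.zeros((n_days, ny, nx))

    tas = (
        base[None, :, :]
        + _seasonal(doy, config.seasonal_amplitude)[:, None, None]
        + _diurnal(hour, config.diurnal_amplitude)[:, None, None]
        + anom[day_index]
    )

    # dew-point depression: daily Gamma draw, mean decreasing with maritime
    mean_dep = config.max_depression * (1.0 - config.maritime)
    if mean_dep > 0:
        shape_k = 4.0
        dep_daily = rng.gamma(shape_k, mean_dep / shape_k, size=(n_days, ny, nx))
    else:
        dep_daily = np.zeros((n_days, ny, nx))
    # depression applied to the daily minimum of tas keeps tdps roughly flat
    # within the day; the final minimum enforces the invariant exactly
    daily_min = tas.reshape(n_days, HOURS_PER_DAY, ny, nx).min(axis=1)
    tdps = np.minimum((daily_min - dep_daily)[day_index], tas)

    half_len, factor = _daylight(doy)
    hour_angle = np.pi * (hour - 12.0) / (2.0 * half_len)
    elev = np.cos(hour_angle)
    elev[np.abs(hour - 12.0) >= half_len] = 0.0
    rsds = np.maximum(0.0, config.solar_peak * factor * elev)
    rsds = np.broadcast_to(rsds[:, None, None], (n_hours, ny, nx)).copy()

    wind = rng.lognormal(np.log(config.wind_median), config.wind_sigma, size=(n_hours, ny, nx))

    lat = config.lat0 + config.dlat * np.arange(ny)
    lon = config.lon0 + config.dlon * np.arange(nx)
    ds = xr.Dataset(
        {
            "tas": (("time", "lat", "lon"), tas, {"units": "degC", "long_name": "air temperature"}),
            "tdps": (("time", "lat", "lon"), tdps, {"units": "degC", "long_name": "dew point temperature"}),
            "rsds": (("time", "lat", "lon"), rsds, {"units": "W m-2", "long_name": "solar radiation"}),
            "sfcWind": (("time", "lat", "lon"), wind, {"units": "m s-1", "long_name": "wind speed"}),
        },
        coords={"time": time, "lat": lat, "lon": lon},
        attrs={"seed": config.seed, "source": "heatecon synthetic climate generator"},
    )
    return ds


def inject_heatwave(field: xr.Dataset, spec: HeatwaveSpec) -> xr.Dataset:
    """Return a copy of *field* with the hot spell of *spec* superimposed.

    Every hour of each affected day is raised by that day's profile amplitude,
    so the daily maximum rises by exactly the profile; other days are
    untouched. Dew point is left unchanged (raising ``tas`` preserves
    ``tdps <= tas``).
    """
    start = pd.Timestamp(spec.start)
    profile = spec.profile()
    days = pd.date_range(start.normalize(), periods=spec.duration, freq="D")
    tmin, tmax = pd.Timestamp(field.time.values[0]), pd.Timestamp(field.time.values[-1])
    if days[0] < tmin.normalize() or days[-1] > tmax.normalize():
        raise ConfigError(
            f"heatwave {days[0].date()}..{days[-1].date()} outside field span "
            f"{tmin.date()}..{tmax.date()}"
        )
    out = field.copy(deep=True)
    tas = out["tas"]
    day_of_time = pd.DatetimeIndex(out.time.values).normalize()
    bump = np.zeros(tas.sizes["time"])
    for d, amp in zip(days, profile):
        bump[day_of_time == d] = amp
    if spec.cells is None:
        tas += bump[:, None, None]
    else:
        arr = tas.values
        for iy, ix in spec.cells:
            arr[:, iy, ix] += bump
        tas.values = arr
    return out


def generate_daily_tmax(
    years: tuple[int, int],
    base_mean: float = 14.0,
    seasonal_amplitude: float = 10.0,
    noise_sd: float = 2.0,
    rng: np.random.Generator | None = None,
    seed: int | None = 0,
) -> pd.Series:
    """A single daily-maximum-temperature series with iid Gaussian noise.

    Lightweight companion to :func:`generate_meteo` for detector studies that
    need many long daily series: Tmax(d) = base + seasonal(doy) + N(0, noise_sd).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    dates = pd.date_range(f"{years[0]}-01-01", f"{years[1]}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    values = base_mean + _seasonal(doy, seasonal_amplitude) + rng.normal(0.0, noise_sd, len(dates))
    return pd.Series(values, index=dates, name="tmax")
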