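"""Wet Bulb Globe Temperature (WBGT), sun and shade variants, and the 4+4+4 hourly scheme.

The outdoor ("sun") index is the ISO 7243 weighting

    WBGT_sun = 0.7 · Tnwb + 0.2 · Tg + 0.1 · Ta

with the natural wet-bulb temperature ``Tnwb`` and globe temperature ``Tg``
obtained from steady-state energy balances; the indoor ("shade") index drops
the radiant term,

    WBGT_shade = 0.7 · Tnwb + 0.3 · Ta,

with ``Tnwb`` equal to the psychrometric wet bulb (no radiant load) at the
conventional fixed air movement of 1 m s⁻¹ (slow walk).

Energy-balance formulation (constants in ``WBGT_CONSTANTS``):

* Psychrometric wet bulb ``Tpwb`` solves
  ``es(T) − es(Td) = A · P · (Ta − T)`` with the Magnus saturation vapour
  pressure ``es`` and psychrometric coefficient ``A``.
* The sunlit wick absorbs a fraction of the solar irradiance, raising the
  balance to ``es(T) − es(Td) = A·P·(Ta − T) + γ_r · SR / (1 + c_w · WS)``;
  at SR = 0 the natural and psychrometric wet bulbs coincide.
* The globe balances absorbed shortwave against convective and longwave
  losses: ``a_g · SR = h_g(WS) · (Tg − Ta) + ε σ (Tg_K⁴ − Ta_K⁴)`` with
  ``h_g = 6.3 · max(WS, 0.1)^0.6``; at SR = 0, ``Tg = Ta``.

Both balances are strictly increasing and convex in the unknown temperature,
so the vectorised damped Newton iteration (tolerance 1e-4 °C, max 100
iterations) converges monotonically after the first step.

At saturation (Td = Ta) with no sun, every component equals Ta, so both
variants return the air temperature — the defining limit of a wet-bulb index.
"""

from __future__ import annotations

import numpy as np
import xarray as xr

from .errors import ConfigError, ConvergenceError

#: coefficient table of the energy-balance formulation (units in comments)
WBGT_CONSTANTS = {
    "pressure_hpa": 1013.25,  # standard surface pressure, hPa
    "psychro_A": 6.6e-4,  # psychrometric coefficient, K^-1 (ventilated wick)
    "magnus_a": 6.1094,  # hPa
    "magnus_b": 17.625,  # –
    "magnus_c": 243.04,  # °C
    "wick_solar_gamma": 0.015,  # hPa per W m^-2: solar forcing on the wet wick
    "wick_wind_damping": 0.8,  # – : ventilation reduction of the solar forcing
    "globe_absorptivity": 0.7,  # – : effective shortwave absorption of the globe
    "globe_emissivity": 0.95,  # –
    "globe_h_coeff": 6.3,  # W m^-2 K^-1 at 1 m/s (150 mm globe, forced convection)
    "globe_h_exponent": 0.6,  # – : wind-speed exponent of h_g
    "stefan_boltzmann": 5.670374419e-8,  # W m^-2 K^-4
    "shade_wind_speed": 1.0,  # m s^-1, fixed for the indoor variant
}

TOL = 1e-4  # °C
MAX_ITER = 100


def saturation_vapour_pressure(t: np.ndarray) -> np.ndarray:
    """Magnus saturation vapour pressure over water, hPa (t in °C)."""
    c = WBGT_CONSTANTS
    t = np.asarray(t, dtype=float)
    return c["magnus_a"] * np.exp(c["magnus_b"] * t / (c["magnus_c"] + t))


def _d_svp(t: np.ndarray) -> np.ndarray:
    c = WBGT_CONSTANTS
    return saturation_vapour_pressure(t) * c["magnus_b"] * c["magnus_c"] / (c["magnus_c"] + t) ** 2


def _check_humidity(ta: np.ndarray, td: np.ndarray) -> None:
    if np.any(td > ta + 1e-9):
        raise ConfigError("dew point exceeds air temperature")


def _solve_wet_bulb(ta: np.ndarray, ea: np.ndarray, forcing: np.ndarray) -> np.ndarray:
    """Newton solve of es(T) − ea = A·P·(ta − T) + forcing, vectorised."""
    c = WBGT_CONSTANTS
    ap = c["psychro_A"] * c["pressure_hpa"]
    shape = np.broadcast(ta, ea, forcing).shape
    t = np.broadcast_to(ta, shape).astype(float).copy()  # start at air temperature
    for _ in range(MAX_ITER):
        f = saturation_vapour_pressure(t) - ea - ap * (ta - t) - forcing
        df = _d_svp(t) + ap
        step = f / df
        t -= np.clip(step, -10.0, 10.0)  # damping against large first steps
        if np.max(np.abs(step)) < TOL:
            return t
    raise ConvergenceError(
        "wet-bulb iteration did not converge",
        residual=float(np.max(np.abs(f))),
        iterations=MAX_ITER,
    )


def psychrometric_wet_bulb(ta, td) -> np.ndarray:
    """Psychrometric (aspirated) wet-bulb temperature, °C."""
    ta, td = np.asarray(ta, dtype=float), np.asarray(td, dtype=float)
    _check_humidity(ta, td)
    return _solve_wet_bulb(ta, saturation_vapour_pressure(td), 0.0)


def natural_wet_bulb(ta, td, sr, ws) -> np.ndarray:
    """Natural wet-bulb temperature under solar load, °C."""
    ta, td = np.asarray(ta, dtype=float), np.asarray(td, dtype=float)
    sr, ws = np.asarray(sr, dtype=float), np.asarray(ws, dtype=float)
    _check_humidity(ta, td)
    if np.any(sr < 0) or np.any(ws < 0):
        raise ConfigError("solar radiation and wind speed must be non-negative")
    c = WBGT_CONSTANTS
    forcing = c["wick_solar_gamma"] * sr / (1.0 + c["wick_wind_damping"] * ws)
    return _solve_wet_bulb(ta, saturation_vapour_pressure(td), forcing)


def globe_temperature(ta, sr, ws) -> np.ndarray:
    """Globe temperature from the radiative–convective balance, °C."""
    ta = np.asarray(ta, dtype=float)
    sr, ws = np.asarray(sr, dtype=float), np.asarray(ws, dtype=float)
    c = WBGT_CONSTANTS
    h = c["globe_h_coeff"] * np.maximum(ws, 0.1) ** c["globe_h_exponent"]
    eps_sig = c["globe_emissivity"] * c["stefan_boltzmann"]
    absorbed = c["globe_absorptivity"] * sr
    ta_k4 = (ta + 273.15) ** 4
    shape = np.broadcast(ta, sr, ws).shape
    t = np.broadcast_to(ta, shape).astype(float).copy()
    for _ in range(MAX_ITER):
        tk = t + 273.15
        f = h * (t - ta) + eps_sig * (tk**4 - ta_k4) - absorbed
        df = h + 4.0 * eps_sig * tk**3
        step = f / df
        t -= np.clip(step, -20.0, 20.0)
        if np.max(np.abs(step)) < TOL:
            return t
    raise ConvergenceError(
        "globe-temperature iteration did not converge",
        residual=float(np.max(np.abs(f))),
        iterations=MAX_ITER,
    )


def wbgt_sun(ta, td, sr, ws) -> np.ndarray:
    """Outdoor WBGT = 0.7·Tnwb + 0.2·Tg + 0.1·Ta (°C); inputs scalar or array."""
    tnwb = natural_wet_bulb(ta, td, sr, ws)
    tg = globe_temperature(ta, sr, ws)
    return 0.7 * tnwb + 0.2 * tg + 0.1 * np.asarray(ta, dtype=float)


def wbgt_shade(ta, td) -> np.ndarray:
    """Indoor WBGT = 0.7·Tnwb + 0.3·Ta (°C) at fixed 1 m s⁻¹ air movement."""
    return 0.7 * psychrometric_wet_bulb(ta, td) + 0.3 * np.asarray(ta, dtype=float)


def wbgt_field(met: xr.Dataset, variant: str = "sun") -> xr.DataArray:
    """WBGT over an hourly meteorological Dataset (tas, tdps, rsds, sfcWind)."""
    if variant == "sun":
        vals = wbgt_sun(met["tas"].values, met["tdps"].values, met["rsds"].values, met["sfcWind"].values)
    elif variant == "shade":
        vals = wbgt_shade(met["tas"].values, met["tdps"].values)
    else:
        raise ConfigError(f"unknown WBGT variant {variant!r}")
    return xr.DataArray(
        vals,
        dims=met["tas"].dims,
        coords=met["tas"].coords,
        name=f"wbgt_{variant}",
        attrs={"units": "degC", "variant": variant},
    )


# hour blocks of the 4+4+4 daytime reconstruction (half-open hour intervals)
_BLOCK_MAX = range(12, 16)
_BLOCK_MEAN = list(range(8, 10)) + list(range(18, 20))
_BLOCK_MID = list(range(10, 12)) + list(range(16, 18))


def approx_hourly_444(daily_mean: float, daily_max: float) -> np.ndarray:
    """Hourly WBGT (24 values) from daily mean and max via the 4+4+4 scheme.

    The daily maximum is assumed over the hottest hours 12–16 h, the daily
    mean over 8–10 h and 18–20 h, and the midpoint of the two over 10–12 h
    and 16–18 h. Hours outside 8–20 h are set to the daily mean, which keeps
    the full-24 h profile bounded by [mean, max] without affecting the 9–17 h
    working day beyond hour 8.
    """
    if daily_max < daily_mean:
        raise ConfigError("daily max WBGT below daily mean")
    out = np.full(24, float(daily_mean))
    out[list(_BLOCK_MAX)] = daily_max
    out[_BLOCK_MID] = 0.5 * (daily_mean + daily_max)
    return out
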