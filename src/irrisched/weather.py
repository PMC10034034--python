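"""Micrometeorology: vapor pressure deficit, heat units, and the
energy-balance upper/lower canopy-temperature-differential limits used
by the crop water stress index (CWSI).

The CWSI places the observed canopy-minus-air temperature differential
between two theoretical limits computed from weather alone: the lower
limit ``dT_ll`` (a well-watered, freely transpiring canopy) and the
upper limit ``dT_ul`` (a non-transpiring canopy).  The limits follow
the classical one-layer energy-balance form

    dT_ul = ra * (Rn - G) / (rho * cp)
    dT_ll = dT_ul * g* / (D + g*)  -  VPD / (D + g*)
    g*    = gamma * (1 + rc_p / ra)

with ``ra`` the aerodynamic resistance, ``rc_p`` the canopy resistance
at potential transpiration, ``D`` the slope of the saturation vapor
pressure curve at air temperature, and ``gamma`` the psychrometric
constant.  Saturation vapor pressure uses the Tetens form throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime

import numpy as np
import pandas as pd

__all__ = [
    "MinuteWeather",
    "DailyWeather",
    "StressLimits",
    "EnergyBalanceParams",
    "saturation_vapor_pressure",
    "svp_slope",
    "vapor_pressure_deficit",
    "heat_units",
    "net_radiation_minus_g",
    "stress_limits",
    "read_minute_weather_csv",
    "read_daily_weather_csv",
]

#: Default base temperature for cotton degree-days, degC.
COTTON_BASE_TEMP = 15.6

#: Default fraction of solar irradiance available as Rn - G over a crop
#: canopy around midday (dimensionless); overridable per site.
DEFAULT_RN_G_COEFF = 0.65


class ValidationError(ValueError):
    """Raised when an input record violates a physical invariant."""


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MinuteWeather:
    """One-minute micrometeorological record.

    Attributes
    ----------
    timestamp : datetime
        Minute-resolution observation time.
    t_air : float
        Air temperature, degC.
    rh : float
        Relative humidity, percent (0-100).
    solar : float
        Solar irradiance, W m-2.
    wind : float
        Wind speed, m s-1.
    """

    timestamp: datetime
    t_air: float
    rh: float
    solar: float
    wind: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rh <= 100.0:
            raise ValidationError(f"rh must be in [0, 100], got {self.rh}")
        if self.solar < 0:
            raise ValidationError(f"solar must be >= 0, got {self.solar}")
        if self.wind < 0:
            raise ValidationError(f"wind must be >= 0, got {self.wind}")


@dataclass(frozen=True)
class DailyWeather:
    """Daily weather summary: temperature extremes and precipitation."""

    date: _date
    t_max: float
    t_min: float
    precip: float = 0.0

    def __post_init__(self) -> None:
        if self.t_max < self.t_min:
            raise ValidationError(
                f"t_max ({self.t_max}) < t_min ({self.t_min}) on {self.date}"
            )
        if self.precip < 0:
            raise ValidationError(f"precip must be >= 0, got {self.precip}")


@dataclass(frozen=True)
class StressLimits:
    """Canopy-minus-air temperature differential limits, K.

    ``dt_ll`` is the well-watered (lower) limit, ``dt_ul`` the
    non-transpiring (upper) limit; a canopy at ``dt_ll`` scores CWSI 0
    and at ``dt_ul`` scores 1.
    """

    dt_ll: float
    dt_ul: float

    def __post_init__(self) -> None:
        if self.dt_ul < self.dt_ll:
            raise ValidationError(
                f"dt_ul ({self.dt_ul}) < dt_ll ({self.dt_ll})"
            )


@dataclass(frozen=True)
class EnergyBalanceParams:
    """Site parameters for the theoretical CWSI limits.

    Attributes
    ----------
    ra : float
        Aerodynamic resistance, s m-1.
    rcp : float
        Canopy resistance at potential transpiration, s m-1.
    gamma : float
        Psychrometric constant, kPa K-1.
    rho_cp : float
        Volumetric heat capacity of air, J m-3 K-1.
    rn_g_coeff : float
        Linear coefficient mapping solar irradiance (W m-2) to net
        radiation minus soil heat flux when no explicit Rn - G is given.
    rn_minus_g : float or None
        Constant Rn - G (W m-2) overriding the solar-derived value.
    """

    ra: float = 10.0
    rcp: float = 50.0
    gamma: float = 0.066
    rho_cp: float = 1200.0
    rn_g_coeff: float = DEFAULT_RN_G_COEFF
    rn_minus_g: float | None = None

    def __post_init__(self) -> None:
        for name in ("ra", "rcp", "gamma", "rho_cp"):
            v = getattr(self, name)
            if not v > 0:
                raise ValidationError(f"{name} must be > 0, got {v}")


# ---------------------------------------------------------------------------
# psychrometrics
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(t_air):
    """Saturation vapor pressure (kPa) at air temperature ``t_air`` (degC).

    Tetens form: ``es = 0.6108 exp(17.27 T / (T + 237.3))``.
    Accepts scalars or arrays.
    """
    t = np.asarray(t_air, dtype=float)
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return es if es.ndim else float(es)


def svp_slope(t_air):
    """Slope of the saturation vapor pressure curve, kPa K-1.

    Analytic derivative of the Tetens form at ``t_air`` (degC).
    """
    t = np.asarray(t_air, dtype=float)
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    d = es * 17.27 * 237.3 / (t + 237.3) ** 2
    return d if d.ndim else float(d)


def vapor_pressure_deficit(t_air, rh):
    """Vapor pressure deficit (kPa) from air temperature (degC) and RH (%).

    ``VPD = es(t_air) * (1 - rh/100)``; zero at saturation.

    Raises
    ------
    ValidationError
        If ``rh`` falls outside [0, 100].
    """
    rh_arr = np.asarray(rh, dtype=float)
    if np.any(rh_arr < 0) or np.any(rh_arr > 100):
        raise ValidationError(f"rh must be in [0, 100], got {rh}")
    vpd = saturation_vapor_pressure(t_air) * (1.0 - rh_arr / 100.0)
    out = np.asarray(vpd)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# heat units
# ---------------------------------------------------------------------------

def heat_units(day: DailyWeather, t_base: float = COTTON_BASE_TEMP) -> float:
    """Daily heat units (growing degree-days, degC d).

    ``max(0, (t_max + t_min)/2 - t_base)`` — the conventional
    mean-temperature degree-day with negative values clamped to zero.
    The default base temperature is 15.6 degC, typical for cotton in
    the Texas High Plains.
    """
    return max(0.0, (day.t_max + day.t_min) / 2.0 - t_base)


# ---------------------------------------------------------------------------
# stress limits
# ---------------------------------------------------------------------------

def net_radiation_minus_g(solar, p: EnergyBalanceParams):
    """Rn - G (W m-2): the configured constant, else ``rn_g_coeff * solar``."""
    if p.rn_minus_g is not None:
        return p.rn_minus_g
    s = np.asarray(solar, dtype=float) * p.rn_g_coeff
    return s if s.ndim else float(s)


def stress_limits(w: MinuteWeather, p: EnergyBalanceParams) -> StressLimits:
    """Theoretical CWSI limits for one minute of weather.

    Upper limit (non-transpiring canopy): ``ra (Rn-G) / rho_cp``.
    Lower limit (potential transpiration): the upper limit damped by
    ``g*/(D+g*)`` minus the evaporative term ``VPD/(D+g*)``, where
    ``g* = gamma (1 + rcp/ra)`` and ``D`` is the Tetens slope at air
    temperature.  With non-negative radiation and deficit the upper
    limit always sits at or above the lower limit.
    """
    rn_g = net_radiation_minus_g(w.solar, p)
    dt_ul = p.ra * rn_g / p.rho_cp
    gamma_star = p.gamma * (1.0 + p.rcp / p.ra)
    delta = svp_slope(w.t_air)
    vpd = vapor_pressure_deficit(w.t_air, w.rh)
    dt_ll = dt_ul * gamma_star / (delta + gamma_star) - vpd / (delta + gamma_star)
    return StressLimits(dt_ll=dt_ll, dt_ul=dt_ul)


def stress_limits_series(
    t_air: np.ndarray,
    rh: np.ndarray,
    solar: np.ndarray,
    p: EnergyBalanceParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized stress limits: arrays of (dt_ll, dt_ul) for minute series."""
    rn_g = net_radiation_minus_g(solar, p)
    dt_ul = p.ra * np.asarray(rn_g, dtype=float) / p.rho_cp
    gamma_star = p.gamma * (1.0 + p.rcp / p.ra)
    delta = np.asarray(svp_slope(t_air))
    vpd = np.asarray(vapor_pressure_deficit(t_air, rh))
    dt_ll = dt_ul * gamma_star / (delta + gamma_star) - vpd / (delta + gamma_star)
    dt_ul = np.broadcast_to(np.asarray(dt_ul, dtype=float), dt_ll.shape).copy()
    return dt_ll, dt_ul


# ---------------------------------------------------------------------------
# CSV readers
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")


def read_minute_weather_csv(path) -> pd.DataFrame:
    """Read a one-minute weather CSV.

    Columns: ``timestamp`` (ISO-8601), ``t_air``, ``rh``, ``solar``,
    ``wind``.  Timestamps must be strictly increasing; RH must lie in
    [0, 100]; solar and wind must be non-negative.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["timestamp", "t_air", "rh", "solar", "wind"], path)
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    bad = np.flatnonzero(np.diff(df["timestamp"].to_numpy()) <= np.timedelta64(0))
    if bad.size:
        raise ValidationError(
            f"{path}: timestamps not strictly increasing at line {bad[0] + 3}"
        )
    if ((df["rh"] < 0) | (df["rh"] > 100)).any():
        line = int((df["rh"].lt(0) | df["rh"].gt(100)).idxmax()) + 2
        raise ValidationError(f"{path}: rh outside [0, 100] at line {line}")
    if (df["solar"] < 0).any() or (df["wind"] < 0).any():
        raise ValidationError(f"{path}: negative solar or wind value")
    return df


def read_daily_weather_csv(path) -> pd.DataFrame:
    """Read a daily weather CSV with ``date, t_max, t_min, precip``."""
    df = pd.read_csv(path)
    _require_columns(df, ["date", "t_max", "t_min", "precip"], path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    if (df["t_max"] < df["t_min"]).any():
        line = int((df["t_max"] < df["t_min"]).idxmax()) + 2
        raise ValidationError(f"{path}: t_max < t_min at line {line}")
    if (df["precip"] < 0).any():
        raise ValidationError(f"{path}: negative precipitation")
    return df
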