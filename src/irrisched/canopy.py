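"""Canopy thermal sensing: reference-curve construction, one-time-of-day
scaling to diurnal series, minute-level CWSI, and the daily integrated
index (iCWSI).

A moving infrared-thermometer network sees each management zone only
once per day, as the pivot lateral passes over it.  Stationary
thermometers over well-watered reference plots record full diurnal
canopy-temperature curves; averaging those gives a reference curve, and
anchored-ratio scaling stretches it through the single moving-sensor
observation to estimate the zone's own diurnal canopy temperature.
Minute-by-minute CWSI values over 09:00-19:00 are then summed into the
daily stress dose, iCWSI, on a 0-600 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as _date
from datetime import datetime, time, timedelta

import numpy as np
import pandas as pd

from .weather import StressLimits, ValidationError

__all__ = [
    "ReferenceCurve",
    "CanopyScan",
    "ICWSIResult",
    "build_reference_curve",
    "scale_one_time_of_day",
    "cwsi_minute",
    "integrate_icwsi",
    "read_canopy_csv",
    "INTEGRATION_START",
    "INTEGRATION_END",
    "INTEGRATION_MINUTES",
]

log = logging.getLogger(__name__)

#: Daily integration window for the stress dose (end exclusive).
INTEGRATION_START = time(9, 0)
INTEGRATION_END = time(19, 0)
INTEGRATION_MINUTES = 600

#: Largest gap (minutes) the reference-curve builder will interpolate.
MAX_REF_GAP_MIN = 10

#: Largest missing fraction integrate_icwsi will interpolate over.
MAX_MISSING_FRACTION = 0.05


@dataclass(frozen=True)
class ReferenceCurve:
    """Well-watered reference canopy temperature curve for one day.

    ``series`` is indexed by minute-resolution timestamps and must cover
    at least the 09:00-19:00 integration window.
    """

    date: _date
    series: pd.Series

    def __post_init__(self) -> None:
        idx = self.series.index
        if len(idx) == 0:
            raise ValidationError("empty reference curve")
        if not self.series.notna().all():
            raise ValidationError("reference curve contains missing values")
        start = datetime.combine(self.date, INTEGRATION_START)
        end = datetime.combine(self.date, INTEGRATION_END) - timedelta(minutes=1)
        if idx[0] > start or idx[-1] < end:
            raise ValidationError(
                "reference curve must cover 09:00-19:00 at one-minute resolution"
            )

    def at(self, when: datetime) -> float:
        """Reference temperature at ``when`` (must be a covered minute)."""
        try:
            return float(self.series.loc[when])
        except KeyError:
            raise ValidationError(
                f"time {when} outside reference-curve span"
            ) from None


@dataclass(frozen=True)
class CanopyScan:
    """One zone's one-time-of-day canopy observation and its scaled series."""

    zone_id: str
    obs_time: datetime
    t_obs: float
    scaled: pd.Series | None = None


@dataclass(frozen=True)
class ICWSIResult:
    """Daily integrated CWSI for one zone: a stress dose on a 0-600 scale."""

    zone_id: str
    date: _date
    icwsi: float
    n_minutes: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.icwsi <= self.n_minutes + 1e-9:
            raise ValidationError(
                f"icwsi {self.icwsi} outside [0, {self.n_minutes}]"
            )


# ---------------------------------------------------------------------------
# reference curve
# ---------------------------------------------------------------------------

def build_reference_curve(
    series_list: list[pd.Series], date: _date | None = None
) -> ReferenceCurve:
    """Average stationary reference-plot series into one reference curve.

    All input series must share a time base; the result is the pointwise
    arithmetic mean.  Minutes missing from every series are linearly
    interpolated provided the gap does not exceed 10 minutes; longer
    gaps are an error naming the gap.
    """
    if not series_list:
        raise ValidationError("build_reference_curve: no input series")
    base = series_list[0].index
    for s in series_list[1:]:
        if not s.index.equals(base):
            raise ValidationError("reference series have unequal time bases")
    mean = pd.concat(series_list, axis=1).mean(axis=1)

    full = pd.date_range(base[0], base[-1], freq="1min")
    mean = mean.reindex(full)
    if mean.isna().any():
        isna = mean.isna().to_numpy()
        # locate the longest run of consecutive missing minutes
        run, longest, gap_start = 0, 0, None
        for i, m in enumerate(isna):
            run = run + 1 if m else 0
            if run > longest:
                longest, gap_start = run, full[i - run + 1]
        if longest > MAX_REF_GAP_MIN:
            raise ValidationError(
                f"reference curve gap of {longest} min starting {gap_start} "
                f"exceeds {MAX_REF_GAP_MIN} min"
            )
        mean = mean.interpolate(method="linear", limit_area="inside")
        if mean.isna().any():
            raise ValidationError("reference curve missing at series edge")
    d = date if date is not None else full[0].date()
    return ReferenceCurve(date=d, series=mean)


# ---------------------------------------------------------------------------
# one-time-of-day scaling
# ---------------------------------------------------------------------------

def scale_one_time_of_day(
    t_obs: float,
    obs_time: datetime,
    ref: ReferenceCurve,
    t_anchor: float,
) -> pd.Series:
    """Scale a single canopy observation into a full diurnal series.

    Anchored-ratio scaling: every reference temperature's excursion
    above the anchor is multiplied by the ratio of the observed
    excursion to the reference excursion at the observation minute,

        T_s(t) = t_anchor + (ref(t) - t_anchor) *
                 (t_obs - t_anchor) / (ref(obs_time) - t_anchor)

    so the scaled series reproduces ``t_obs`` at ``obs_time`` exactly.
    The anchor is conventionally the day's pre-dawn minimum air
    temperature.

    Raises
    ------
    ValidationError
        If ``obs_time`` lies outside the reference span or the reference
        equals the anchor at the observation minute (degenerate ratio).
    """
    ref_at_obs = ref.at(obs_time)
    denom = ref_at_obs - t_anchor
    if denom == 0:
        raise ValidationError(
            f"reference equals anchor ({t_anchor}) at {obs_time}: "
            "scaling ratio undefined"
        )
    ratio = (t_obs - t_anchor) / denom
    scaled = t_anchor + (ref.series - t_anchor) * ratio
    scaled.loc[obs_time] = t_obs  # exact at the observation minute
    return scaled


# ---------------------------------------------------------------------------
# CWSI
# ---------------------------------------------------------------------------

def cwsi_minute(t_s, t_air, lim: StressLimits):
    """One-minute CWSI: normalized canopy-minus-air differential.

    ``clamp(((t_s - t_air) - dt_ll) / (dt_ul - dt_ll), 0, 1)`` — 0 at
    the well-watered lower limit, 1 at the non-transpiring upper limit.
    Accepts scalars or arrays (with ``lim`` fields scalar or arrays of
    matching shape via ``cwsi_minute_series``).
    """
    if not lim.dt_ul > lim.dt_ll:
        raise ValidationError(
            f"dt_ul ({lim.dt_ul}) must exceed dt_ll ({lim.dt_ll})"
        )
    raw = ((np.asarray(t_s, dtype=float) - t_air) - lim.dt_ll) / (
        lim.dt_ul - lim.dt_ll
    )
    out = np.clip(raw, 0.0, 1.0)
    return out if out.ndim else float(out)


def cwsi_minute_series(
    t_s: np.ndarray,
    t_air: np.ndarray,
    dt_ll: np.ndarray,
    dt_ul: np.ndarray,
) -> np.ndarray:
    """Vectorized minute CWSI; minutes where dt_ul <= dt_ll yield NaN.

    Degenerate limits occur at night or under zero radiation load; the
    09:00-19:00 integration window rarely contains them, and NaNs are
    handled by ``integrate_icwsi``'s missing-minute policy.
    """
    span = dt_ul - dt_ll
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = ((t_s - t_air) - dt_ll) / span
    raw = np.where(span > 0, raw, np.nan)
    return np.clip(raw, 0.0, 1.0)


def integrate_icwsi(
    minute_cwsi: pd.Series,
    zone_id: str = "",
    date: _date | None = None,
) -> ICWSIResult:
    """Integrate one-minute CWSI values over 09:00-19:00 into the iCWSI.

    A left-Riemann sum at one-minute steps: 600 terms for a complete
    window, so a fully stressed day scores 600 and an unstressed day 0.
    Up to 5% missing minutes are linearly interpolated (logged); more
    is an error.
    """
    idx = minute_cwsi.index
    if len(idx) == 0:
        raise ValidationError("integrate_icwsi: empty series")
    d = date if date is not None else idx[0].date()
    start = datetime.combine(d, INTEGRATION_START)
    full = pd.date_range(start, periods=INTEGRATION_MINUTES, freq="1min")
    window = minute_cwsi.reindex(full)
    n_missing = int(window.isna().sum())
    if n_missing > MAX_MISSING_FRACTION * INTEGRATION_MINUTES:
        raise ValidationError(
            f"{n_missing} of {INTEGRATION_MINUTES} minutes missing "
            f"(> {MAX_MISSING_FRACTION:.0%}) for zone {zone_id!r} on {d}"
        )
    if n_missing:
        log.info(
            "interpolating %d missing minute(s) for zone %s on %s",
            n_missing, zone_id, d,
        )
        window = window.interpolate(method="linear", limit_direction="both")
    icwsi = float(window.sum())  # 1-minute step width
    return ICWSIResult(
        zone_id=zone_id, date=d, icwsi=icwsi, n_minutes=INTEGRATION_MINUTES
    )


# ---------------------------------------------------------------------------
# CSV reader
# ---------------------------------------------------------------------------

def read_canopy_csv(path) -> pd.DataFrame:
    """Read a canopy-temperature CSV: ``timestamp, zone_id, t_canopy``.

    Timestamps must be strictly increasing within each zone.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("timestamp", "zone_id", "t_canopy") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    for zone, grp in df.groupby("zone_id"):
        t = grp["timestamp"].to_numpy()
        bad = np.flatnonzero(np.diff(t) <= np.timedelta64(0))
        if bad.size:
            raise ValidationError(
                f"{path}: non-increasing timestamps for zone {zone!r} "
                f"at row {grp.index[bad[0] + 1] + 2}"
            )
    return df
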