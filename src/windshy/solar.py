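"""Sunrise/sunset from standard solar geometry.

Implements the NOAA low-precision solar equations (fractional-year Fourier
series for the equation of time and solar declination, hour-angle inversion
at a zenith of 90.833 degrees, i.e. sun centre at -0.833 deg altitude which
folds in atmospheric refraction and the solar semi-diameter).  Accuracy is
about one minute at mid latitudes, which is ample for a roosting/daylight
filter on GPS fixes.

All functions accept scalars or numpy arrays and return times in UTC.
Longitudes are positive east, latitudes positive north (WGS84 degrees).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from datetime import date, datetime, timedelta, timezone

import numpy as np

#: solar altitude at geometric rise/set, degrees (refraction + semi-diameter)
RISE_SET_ALTITUDE_DEG = -0.833


class DayType(enum.Enum):
    NORMAL = "normal"
    POLAR_DAY = "polar_day"
    POLAR_NIGHT = "polar_night"


@dataclass(frozen=True)
class SolarTimes:
    """Sunrise/sunset for one location and calendar date (UTC)."""

    sunrise: datetime | None
    sunset: datetime | None
    day_type: DayType


def _fractional_year(doy: np.ndarray, hour: np.ndarray) -> np.ndarray:
    return 2.0 * np.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)

def _equation_of_time_min(g: np.ndarray) -> np.ndarray:
    return 229.18 * (
        0.000075
        + 0.001868 * np.cos(g)
        - 0.032077 * np.sin(g)
        - 0.014615 * np.cos(2 * g)
        - 0.040849 * np.sin(2 * g)
    )

def _declination_rad(g: np.ndarray) -> np.ndarray:
    return (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )


def sunrise_sunset_minutes(
    lat: np.ndarray, lon: np.ndarray, doy: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised sunrise/sunset as minutes after 00:00 UTC.

    Parameters
    ----------
    lat, lon : array-like, degrees
    doy : array-like, day of year (1-based)

    Returns
    -------
    (sunrise_min, sunset_min)
        NaN marks polar night; -inf/+inf mark polar day (sun never sets).
    """
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    doy = np.asarray(doy, dtype=float)
    if np.any(np.abs(lat) > 90.0):
        raise ValueError("latitude must lie in [-90, 90] degrees")

    g = _fractional_year(doy, np.full_like(doy, 12.0))
    eqt = _equation_of_time_min(g)
    decl = _declination_rad(g)
    latr = np.deg2rad(lat)

    cos_ha = (
        np.cos(np.deg2rad(90.0 - RISE_SET_ALTITUDE_DEG))
        / (np.cos(latr) * np.cos(decl))
        - np.tan(latr) * np.tan(decl)
    )
    with np.errstate(invalid="ignore"):
        ha_deg = np.rad2deg(np.arccos(np.clip(cos_ha, -1.0, 1.0)))

    sunrise = 720.0 - 4.0 * (lon + ha_deg) - eqt
    sunset = 720.0 - 4.0 * (lon - ha_deg) - eqt

    polar_night = cos_ha > 1.0
    polar_day = cos_ha < -1.0
    sunrise = np.where(polar_night, np.nan, np.where(polar_day, -np.inf, sunrise))
    sunset = np.where(polar_night, np.nan, np.where(polar_day, np.inf, sunset))
    return sunrise, sunset


def solar_times(lat: float, lon: float, day: date) -> SolarTimes:
    """Sunrise and sunset (UTC) for one location and date.

    Returns ``SolarTimes`` with ``None`` times and ``POLAR_NIGHT`` when the
    sun never reaches -0.833 deg, and ``None`` times with ``POLAR_DAY`` when
    it never drops below it.
    """
    doy = day.timetuple().tm_yday
    sr, ss = sunrise_sunset_minutes(lat, lon, doy)
    sr, ss = float(sr), float(ss)
    midnight = datetime(day.year, day.month, day.day, tzinfo=timezone.utc)
    if np.isnan(sr):
        return SolarTimes(None, None, DayType.POLAR_NIGHT)
    if np.isinf(sr):
        return SolarTimes(None, None, DayType.POLAR_DAY)
    return SolarTimes(
        midnight + timedelta(minutes=sr),
        midnight + timedelta(minutes=ss),
        DayType.NORMAL,
    )


def is_daylight(
    lat: np.ndarray, lon: np.ndarray, ts_utc: np.ndarray
) -> np.ndarray:
    """Boolean mask: is each instant between sunrise and sunset (inclusive)?

    ``ts_utc`` is an array of ``numpy.datetime64`` (interpreted as UTC).
    Fixes exactly at the sunrise/sunset instants count as daylight.
    """
    ts = np.asarray(ts_utc, dtype="datetime64[s]")
    days = ts.astype("datetime64[D]")
    minute_of_day = (ts - days).astype("timedelta64[s]").astype(float) / 60.0
    doy = (days - days.astype("datetime64[Y]")).astype(int) + 1
    sr, ss = sunrise_sunset_minutes(lat, lon, doy)
    out = np.zeros(ts.shape, dtype=bool)
    normal = np.isfinite(sr)
    out[normal] = (minute_of_day[normal] >= sr[normal]) & (
        minute_of_day[normal] <= ss[normal]
    )
    out[np.isinf(sr)] = True  # polar day
    # polar night (NaN) stays False
    return out
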