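"""Solar geometry for diel-activity analysis.

Computes sun event times (sunrise/sunset at solar altitude -0.833 deg,
nautical dawn/dusk at -12 deg) from the NOAA solar-position equations,
classifies timestamps into the day/twilight/night partition, and maps
clock time onto the sun-anchored circle used for activity analysis
(double anchoring: sunrise -> pi/2, sunset -> 3*pi/2, so pi is solar
noon and 0 == 2*pi is solar midnight).

Timestamps are interpreted as site-local civil time; the UTC offset is
resolved from longitude (round(lon/15) hours). Internally times are
minutes from local civil midnight.

At high latitudes a requested crossing may not exist (midnight sun /
polar night); sun event functions then return NaN / ``None`` and the
classification and anchoring transforms raise :class:`PolarDayNightError`
rather than guessing.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date, datetime, timedelta
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "SunTimes",
    "PolarDayNightError",
    "sun_times",
    "classify_diel",
    "anchor_to_sun",
    "sun_to_clock",
    "timezone_offset_hours",
    "SUNRISE_ZENITH_DEG",
    "NAUTICAL_ZENITH_DEG",
]

# Zenith angles defining the crossings. 90.833 deg includes atmospheric
# refraction and the solar radius; 102 deg is the nautical twilight limit
# (sun centre 12 deg below the horizon).
SUNRISE_ZENITH_DEG = 90.833
NAUTICAL_ZENITH_DEG = 102.0

DIEL_CATEGORIES = ("day", "twilight", "night")


class PolarDayNightError(ValueError):
    """Raised when a sun crossing needed for the computation does not exist."""


def timezone_offset_hours(longitude: float) -> int:
    """Nominal civil UTC offset for a site, resolved from longitude."""
    return int(np.round(longitude / 15.0))


def _julian_centuries(ordinal: np.ndarray, minutes_utc: np.ndarray) -> np.ndarray:
    # proleptic-Gregorian ordinal 1 == 0001-01-01; JD of that midnight is 1721424.5
    jd = ordinal + 1721424.5 + minutes_utc / 1440.0
    return (jd - 2451545.0) / 36525.0


def _equation_of_time_and_declination(t: np.ndarray):
    """NOAA (Meeus-derived) equation of time [minutes] and solar declination [rad]."""
    deg = np.pi / 180.0
    l0 = np.remainder(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    m_rad = m * deg
    eq_ctr = (
        np.sin(m_rad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * m_rad) * (0.019993 - 0.000101 * t)
        + np.sin(3 * m_rad) * 0.000289
    )
    true_long = l0 + eq_ctr
    omega = (125.04 - 1934.136 * t) * deg
    app_long = (true_long - 0.00569 - 0.00478 * np.sin(omega)) * deg
    mean_obliq = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    obliq = (mean_obliq + 0.00256 * np.cos(omega)) * deg
    decl = np.arcsin(np.sin(obliq) * np.sin(app_long))
    y = np.tan(obliq / 2.0) ** 2
    l0_rad = l0 * deg
    eqtime = 4.0 / deg * (
        y * np.sin(2 * l0_rad)
        - 2.0 * ecc * np.sin(m_rad)
        + 4.0 * ecc * y * np.sin(m_rad) * np.cos(2 * l0_rad)
        - 0.5 * y * y * np.sin(4 * l0_rad)
        - 1.25 * ecc * ecc * np.sin(2 * m_rad)
    )
    return eqtime, decl


def _crossing_minutes(
    latitude: np.ndarray,
    longitude: np.ndarray,
    ordinal: np.ndarray,
    zenith_deg: float,
    rising: bool,
    tz_minutes: np.ndarray,
) -> np.ndarray:
    """Local-civil minutes of the requested solar-zenith crossing (NaN if none).

    Vectorised over broadcastable array inputs. Two fixed-point iterations
    (evaluate the ephemeris at the current estimate of the event time) are
    enough for well under a second of residual error.
    """
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    lon = np.asarray(longitude, dtype=float)
    ordinal = np.asarray(ordinal, dtype=float)
    tz_minutes = np.asarray(tz_minutes, dtype=float)
    t_local = np.broadcast_to(720.0, np.broadcast_shapes(lat.shape, lon.shape, ordinal.shape)).copy()
    cos_z = np.cos(np.deg2rad(zenith_deg))
    for _ in range(3):
        t = _julian_centuries(ordinal, t_local - tz_minutes)
        eqtime, decl = _equation_of_time_and_declination(t)
        noon = 720.0 - 4.0 * lon - eqtime + tz_minutes
        cos_ha = (cos_z - np.sin(lat) * np.sin(decl)) / (np.cos(lat) * np.cos(decl))
        with np.errstate(invalid="ignore"):
            ha_deg = np.rad2deg(np.arccos(np.clip(cos_ha, -1.0, 1.0)))
        ha_deg = np.where(np.abs(cos_ha) > 1.0, np.nan, ha_deg)
        t_local = noon - 4.0 * ha_deg if rising else noon + 4.0 * ha_deg
        t_local = np.where(np.isnan(t_local), 720.0, t_local) if _ != 2 else t_local
    return t_local


def _sun_minutes_vec(latitude, longitude, ordinal, tz_minutes):
    """(nautical_dawn, sunrise, sunset, nautical_dusk) in local minutes, NaN where absent."""
    dawn = _crossing_minutes(latitude, longitude, ordinal, NAUTICAL_ZENITH_DEG, True, tz_minutes)
    sunrise = _crossing_minutes(latitude, longitude, ordinal, SUNRISE_ZENITH_DEG, True, tz_minutes)
    sunset = _crossing_minutes(latitude, longitude, ordinal, SUNRISE_ZENITH_DEG, False, tz_minutes)
    dusk = _crossing_minutes(latitude, longitude, ordinal, NAUTICAL_ZENITH_DEG, False, tz_minutes)
    return dawn, sunrise, sunset, dusk


@dataclass(frozen=True)
class SunTimes:
    """Sun event instants for one site and calendar date (site-local civil time).

    Any field is ``None`` when the corresponding crossing does not occur
    (polar day or night, or sun never reaching -12 deg in high summer).
    """

    date: _date
    nautical_dawn: Optional[pd.Timestamp]
    sunrise: Optional[pd.Timestamp]
    sunset: Optional[pd.Timestamp]
    nautical_dusk: Optional[pd.Timestamp]

    @property
    def complete(self) -> bool:
        return None not in (self.nautical_dawn, self.sunrise, self.sunset, self.nautical_dusk)


def _minutes_to_timestamp(day: _date, minutes: float) -> Optional[pd.Timestamp]:
    if np.isnan(minutes):
        return None
    return pd.Timestamp(datetime(day.year, day.month, day.day)) + pd.Timedelta(minutes=float(minutes))


def sun_times(latitude: float, longitude: float, day: _date | str | pd.Timestamp) -> SunTimes:
    """Sun event times for one site/date in site-local civil time.

    Accuracy is within about a minute of almanac values for |latitude|
    well below the polar circles; the pipeline only relies on it for
    |latitude| <= 54 deg where all four events exist year-round.
    """
    day = pd.Timestamp(day).date()
    tz_min = timezone_offset_hours(longitude) * 60.0
    ordinal = float(day.toordinal())
    dawn, sunrise, sunset, dusk = _sun_minutes_vec(latitude, longitude, ordinal, tz_min)
    return SunTimes(
        date=day,
        nautical_dawn=_minutes_to_timestamp(day, float(dawn)),
        sunrise=_minutes_to_timestamp(day, float(sunrise)),
        sunset=_minutes_to_timestamp(day, float(sunset)),
        nautical_dusk=_minutes_to_timestamp(day, float(dusk)),
    )


def _require_complete(st: SunTimes) -> SunTimes:
    if not st.complete:
        raise PolarDayNightError(
            f"sun crossings incomplete on {st.date}; diel classification undefined"
        )
    return st


def classify_diel(timestamp, latitude: float, longitude: float) -> str:
    """Classify a site-local timestamp as 'day', 'twilight' or 'night'.

    Day is [sunrise, sunset); twilight is [nautical_dawn, sunrise) union
    [sunset, nautical_dusk); night is the remainder. Intervals are
    half-open on the right so the three categories tile the civil day.
    """
    ts = pd.Timestamp(timestamp)
    st = _require_complete(sun_times(latitude, longitude, ts.date()))
    if st.sunrise <= ts < st.sunset:
        return "day"
    if st.nautical_dawn <= ts < st.sunrise or st.sunset <= ts < st.nautical_dusk:
        return "twilight"
    return "night"


def _minutes_of_day(ts: pd.Timestamp) -> float:
    return ts.hour * 60.0 + ts.minute + ts.second / 60.0 + ts.microsecond / 6e7


def _day_sun_minutes(latitude, longitude, day: _date):
    tz_min = timezone_offset_hours(longitude) * 60.0
    _, sunrise, sunset, _ = _sun_minutes_vec(latitude, longitude, float(day.toordinal()), tz_min)
    if np.isnan(sunrise) or np.isnan(sunset):
        raise PolarDayNightError(f"no sunrise/sunset on {day}; anchoring undefined")
    return float(sunrise), float(sunset)


def anchor_to_sun(timestamp, latitude: float, longitude: float) -> float:
    """Map a clock time to sun-anchored circular time in [0, 2*pi).

    Double anchoring: sunrise maps to pi/2 and sunset to 3*pi/2; daytime
    is interpolated linearly between them, and night-time linearly over
    the complementary arc through 0 == 2*pi, using the adjacent day's
    sunrise/sunset so the transform is continuous across midnight.
    """
    ts = pd.Timestamp(timestamp)
    day = ts.date()
    sunrise, sunset = _day_sun_minutes(latitude, longitude, day)
    m = _minutes_of_day(ts)
    if sunrise <= m <= sunset:
        theta = np.pi / 2 + np.pi * (m - sunrise) / (sunset - sunrise)
    elif m > sunset:
        next_sunrise, _ = _day_sun_minutes(latitude, longitude, day + timedelta(days=1))
        night_len = (next_sunrise + 1440.0) - sunset
        theta = 1.5 * np.pi + np.pi * (m - sunset) / night_len
    else:  # before sunrise: night that began at the previous day's sunset
        _, prev_sunset = _day_sun_minutes(latitude, longitude, day - timedelta(days=1))
        night_len = (sunrise + 1440.0) - prev_sunset
        theta = 1.5 * np.pi + np.pi * (m + 1440.0 - prev_sunset) / night_len
    return float(np.remainder(theta, 2 * np.pi))


def sun_to_clock(theta: float, latitude: float, longitude: float, day: _date | str | pd.Timestamp) -> pd.Timestamp:
    """Invert :func:`anchor_to_sun` for a given site and anchor date.

    ``day`` names the solar day anchored at that date's sunrise: ``theta``
    in [pi/2, 3*pi/2] lands in its daytime, and any other angle in the
    night running from that date's sunset to the next sunrise (pre-dawn
    angles below pi/2 therefore fall on the next civil date). This makes
    the map a bijection from [0, 2*pi) onto one full solar day, so it
    round-trips with :func:`anchor_to_sun` to sub-second error.
    """
    theta = float(np.remainder(theta, 2 * np.pi))
    day = pd.Timestamp(day).date()
    sunrise, sunset = _day_sun_minutes(latitude, longitude, day)
    midnight = pd.Timestamp(datetime(day.year, day.month, day.day))
    if np.pi / 2 <= theta <= 1.5 * np.pi:
        m = sunrise + (theta - np.pi / 2) / np.pi * (sunset - sunrise)
    else:  # night arc from this day's sunset to the next day's sunrise
        next_sunrise, _ = _day_sun_minutes(latitude, longitude, day + timedelta(days=1))
        night_len = (next_sunrise + 1440.0) - sunset
        frac = np.remainder(theta - 1.5 * np.pi, 2 * np.pi) / np.pi
        m = sunset + frac * night_len
    return midnight + pd.Timedelta(minutes=float(m))


def annotate_frame(df: pd.DataFrame, time_col: str = "timestamp",
                   lat_col: str = "latitude", lon_col: str = "longitude") -> pd.DataFrame:
    """Vectorised diel classification + sun anchoring for an event table.

    Adds ``diel_category``, ``sun_time_rad`` and ``anchored_hour`` columns.
    Sun events are computed once per unique (latitude, longitude, date)
    triple, so large tables with shared deployments stay cheap.
    """
    if df.empty:
        out = df.copy()
        out["diel_category"] = pd.Series(dtype=str)
        out["sun_time_rad"] = pd.Series(dtype=float)
        out["anchored_hour"] = pd.Series(dtype=int)
        return out
    ts = pd.to_datetime(df[time_col])
    lat = df[lat_col].to_numpy(dtype=float)
    lon = df[lon_col].to_numpy(dtype=float)
    day_ord = np.array([t.toordinal() for t in ts.dt.date], dtype=float)
    minutes = (
        ts.dt.hour.to_numpy() * 60.0
        + ts.dt.minute.to_numpy()
        + ts.dt.second.to_numpy() / 60.0
        + ts.dt.microsecond.to_numpy() / 6e7
    )
    tz_min = np.round(lon / 15.0) * 60.0

    # unique (lat, lon, ordinal) rows; also need previous/next day sunrise/sunset
    key = np.stack([lat, lon, day_ord], axis=1)
    uniq, inv = np.unique(key, axis=0, return_inverse=True)
    ulat, ulon, uord = uniq[:, 0], uniq[:, 1], uniq[:, 2]
    utz = np.round(ulon / 15.0) * 60.0
    dawn, sunrise, sunset, dusk = _sun_minutes_vec(ulat, ulon, uord, utz)
    _, next_sr, _, _ = _sun_minutes_vec(ulat, ulon, uord + 1, utz)
    _, _, prev_ss, _ = _sun_minutes_vec(ulat, ulon, uord - 1, utz)
    if np.isnan([dawn, sunrise, sunset, dusk, next_sr, prev_ss]).any():
        raise PolarDayNightError("sun crossings incomplete for some site/date in the table")

    dawn, sunrise, sunset, dusk = dawn[inv], sunrise[inv], sunset[inv], dusk[inv]
    next_sr, prev_ss = next_sr[inv], prev_ss[inv]

    cat = np.full(len(df), "night", dtype=object)
    cat[(minutes >= sunrise) & (minutes < sunset)] = "day"
    tw = ((minutes >= dawn) & (minutes < sunrise)) | ((minutes >= sunset) & (minutes < dusk))
    cat[tw] = "twilight"

    theta = np.empty(len(df))
    is_day = (minutes >= sunrise) & (minutes <= sunset)
    evening = minutes > sunset
    morning = ~is_day & ~evening
    theta[is_day] = np.pi / 2 + np.pi * (minutes[is_day] - sunrise[is_day]) / (
        sunset[is_day] - sunrise[is_day]
    )
    theta[evening] = 1.5 * np.pi + np.pi * (minutes[evening] - sunset[evening]) / (
        next_sr[evening] + 1440.0 - sunset[evening]
    )
    theta[morning] = 1.5 * np.pi + np.pi * (minutes[morning] + 1440.0 - prev_ss[morning]) / (
        sunrise[morning] + 1440.0 - prev_ss[morning]
    )
    theta = np.remainder(theta, 2 * np.pi)

    out = df.copy()
    out["diel_category"] = cat
    out["sun_time_rad"] = theta
    out["anchored_hour"] = np.minimum(np.floor(24.0 * theta / (2 * np.pi)).astype(int), 23)
    return out
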