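"""Independent solar almanac oracle for validating dielkit.solar.

Implements the USNO 'Approximate Solar Coordinates' ephemeris (mean
longitude and anomaly linear in days from J2000, two-term equation of
centre, right-ascension-based equation of time) together with the
standard hour-angle crossing equation. This is a different derivation
from the Meeus-style polynomial ephemeris used by the package (no
quadratic/cubic secular terms, no nutation or aberration corrections),
so agreement between the two is a real cross-check, not a tautology.
Stated accuracy of the ephemeris is about 0.01 deg, i.e. well under a
minute of event-time error.

Written and frozen before the main solar module was validated; used
only by tests and the acceptance script.
"""

from __future__ import annotations

import numpy as np

_DEG = np.pi / 180.0


def _solar_position(days_j2000):
    """(equation of time [minutes], declination [rad]) from days since J2000 (UT)."""
    n = np.asarray(days_j2000, dtype=float)
    mean_long = np.remainder(280.460 + 0.9856474 * n, 360.0)
    mean_anom = np.remainder(357.528 + 0.9856003 * n, 360.0) * _DEG
    ecliptic_long = (
        mean_long + 1.915 * np.sin(mean_anom) + 0.020 * np.sin(2.0 * mean_anom)
    ) * _DEG
    obliquity = (23.439 - 0.0000004 * n) * _DEG
    decl = np.arcsin(np.sin(obliquity) * np.sin(ecliptic_long))
    ra = np.arctan2(np.cos(obliquity) * np.sin(ecliptic_long), np.cos(ecliptic_long))
    ra_deg = np.remainder(np.rad2deg(ra), 360.0)
    # equation of time: mean sun minus apparent sun, in minutes (4 min per degree)
    eqtime = 4.0 * (np.remainder(mean_long - ra_deg + 180.0, 360.0) - 180.0)
    return eqtime, decl


def _days_j2000(ordinal, minutes_utc):
    # proleptic-Gregorian ordinal of 2000-01-01 is 730120; J2000 epoch is 2000-01-01 12:00 UT
    return np.asarray(ordinal, dtype=float) - 730120.0 + np.asarray(minutes_utc, dtype=float) / 1440.0 - 0.5


def crossing_minutes_local(latitude, longitude, ordinal, zenith_deg, rising, tz_hours):
    """Local-civil minutes of a solar-zenith crossing; NaN when it does not occur.

    ``ordinal`` is the proleptic-Gregorian ordinal of the civil date
    (datetime.date.toordinal). Vectorised over broadcastable inputs;
    three fixed-point passes refine the ephemeris at the event time.
    """
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    lon = np.asarray(longitude, dtype=float)
    ordinal = np.asarray(ordinal, dtype=float)
    tz_min = np.asarray(tz_hours, dtype=float) * 60.0
    cos_z = np.cos(np.deg2rad(zenith_deg))
    shape = np.broadcast_shapes(lat.shape, lon.shape, ordinal.shape)
    minutes_local = np.broadcast_to(720.0, shape).astype(float).copy()
    sign = -1.0 if rising else 1.0
    for _ in range(3):
        eqtime, decl = _solar_position(_days_j2000(ordinal, minutes_local - tz_min))
        cos_ha = (cos_z - np.sin(lat) * np.sin(decl)) / (np.cos(lat) * np.cos(decl))
        with np.errstate(invalid="ignore"):
            ha_deg = np.rad2deg(np.arccos(np.clip(cos_ha, -1.0, 1.0)))
        ha_deg = np.where(np.abs(cos_ha) > 1.0, np.nan, ha_deg)
        est = 720.0 - 4.0 * lon - eqtime + sign * 4.0 * ha_deg + tz_min
        minutes_local = np.where(np.isnan(est), minutes_local, est)
        out = est
    return out


def sun_times_minutes(latitude, longitude, ordinal, tz_hours):
    """(nautical_dawn, sunrise, sunset, nautical_dusk) local minutes from midnight."""
    dawn = crossing_minutes_local(latitude, longitude, ordinal, 102.0, True, tz_hours)
    sunrise = crossing_minutes_local(latitude, longitude, ordinal, 90.833, True, tz_hours)
    sunset = crossing_minutes_local(latitude, longitude, ordinal, 90.833, False, tz_hours)
    dusk = crossing_minutes_local(latitude, longitude, ordinal, 102.0, False, tz_hours)
    return dawn, sunrise, sunset, dusk
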