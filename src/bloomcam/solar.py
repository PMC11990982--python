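"""Sunrise/sunset computation for filtering phenocamera archives.

Implements the standard NOAA-style sunrise equation (mean anomaly,
equation-of-center, solar transit, hour angle at the -0.833 deg horizon).
Accuracy is on the order of a minute, which is ample for window filtering
with a configurable buffer.
"""

from __future__ import annotations

import datetime as dt
import math

_J2000 = 2451545.0
_OBLIQUITY = math.radians(23.4397)
# standard altitude of the solar center at rise/set: refraction + solar radius
_ALTITUDE_DEG = -0.833

__all__ = ["PolarDayNightError", "sun_times"]


class PolarDayNightError(ValueError):
    """The sun does not rise or does not set on the requested date."""


def _julian_day(date: dt.date) -> float:
    """Julian day number at 00:00 UTC of ``date``."""
    a = (14 - date.month) // 12
    y = date.year + 4800 - a
    m = date.month + 12 * a - 3
    jdn = date.day + (153 * m + 2) // 5 + 365 * y + y // 4 - y // 100 + y // 400 - 32045
    return jdn - 0.5


def _from_julian(j: float) -> dt.datetime:
    t = (j - 2440587.5) * 86400.0
    return dt.datetime.fromtimestamp(t, tz=dt.timezone.utc)


def sun_times(
    date: dt.date, lat: float, lon: float
) -> tuple[dt.datetime, dt.datetime]:
    """Sunrise and sunset (UTC, tz-aware) for a calendar date and site.

    Parameters
    ----------
    date : datetime.date
        Calendar date (interpreted at the site; for mid-latitude sites the
        UTC/local distinction at the day boundary is absorbed by the caller).
    lat, lon : float
        Geographic coordinates in degrees; longitude positive east.

    Raises
    ------
    PolarDayNightError
        If the sun never rises or never sets on that date (polar day/night).
    """
    n = _julian_day(date) + 0.5 - _J2000 + 0.0008
    j_star = n - lon / 360.0  # mean solar noon (longitude positive east)

    m = math.radians((357.5291 + 0.98560028 * j_star) % 360.0)
    c = 1.9148 * math.sin(m) + 0.02 * math.sin(2 * m) + 0.0003 * math.sin(3 * m)
    lam = math.radians((math.degrees(m) + c + 180.0 + 102.9372) % 360.0)

    j_transit = _J2000 + j_star + 0.0053 * math.sin(m) - 0.0069 * math.sin(2 * lam)

    sin_dec = math.sin(lam) * math.sin(_OBLIQUITY)
    dec = math.asin(sin_dec)

    phi = math.radians(lat)
    cos_h = (
        math.sin(math.radians(_ALTITUDE_DEG)) - math.sin(phi) * sin_dec
    ) / (math.cos(phi) * math.cos(dec))
    if cos_h < -1.0 or cos_h > 1.0:
        raise PolarDayNightError(
            f"sun does not {'set' if cos_h < -1 else 'rise'} at lat={lat} on {date}; "
            "supply an explicit sunrise/sunset schedule"
        )
    h = math.degrees(math.acos(cos_h))
    return _from_julian(j_transit - h / 360.0), _from_julian(j_transit + h / 360.0)
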