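"""Solar position from first principles (NOAA solar-calculator equations).

Implements the low-precision solar ephemeris used by the NOAA solar
calculator spreadsheets.  Accuracy is better than 0.1 degrees of solar
elevation for years 1900-2100, comfortably within the 0.5-degree
documentation tolerance needed to classify astronomical twilight.

Angles are handled in degrees at the interface; no atmospheric refraction
correction is applied (irrelevant at the -18 degree night threshold).
"""

from __future__ import annotations

import math
from datetime import datetime, timezone

__all__ = ["julian_day", "solar_elevation", "ASTRONOMICAL_TWILIGHT_DEG"]

#: Solar elevation below which it is astronomical night.
ASTRONOMICAL_TWILIGHT_DEG = -18.0


def julian_day(when: datetime) -> float:
    """Julian day number (with fractional day) for a timezone-aware datetime."""
    if when.tzinfo is None:
        raise ValueError("timestamp must be timezone-aware")
    u = when.astimezone(timezone.utc)
    year, month = u.year, u.month
    day = (
        u.day
        + u.hour / 24.0
        + u.minute / 1440.0
        + (u.second + u.microsecond / 1e6) / 86400.0
    )
    if month <= 2:
        year -= 1
        month += 12
    a = year // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (year + 4716)) + math.floor(30.6001 * (month + 1)) + day + b - 1524.5


def _sun_declination_and_eot(t: float) -> tuple[float, float]:
    """Solar declination (deg) and equation of time (minutes) at Julian century *t*."""
    l0 = (280.46646 + t * (36000.76983 + 0.0003032 * t)) % 360.0
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    e = 0.016708634 - t * (0.000042037 + 0.0000001267 * t)
    mrad = math.radians(m)
    c = (
        math.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + math.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + math.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = math.radians(125.04 - 1934.136 * t)
    app_long = true_long - 0.00569 - 0.00478 * math.sin(omega)
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = eps0 + 0.00256 * math.cos(omega)
    eps_rad = math.radians(eps)
    decl = math.degrees(math.asin(math.sin(eps_rad) * math.sin(math.radians(app_long))))

    y = math.tan(eps_rad / 2.0) ** 2
    l0r = math.radians(l0)
    eot = 4.0 * math.degrees(
        y * math.sin(2 * l0r)
        - 2 * e * math.sin(mrad)
        + 4 * e * y * math.sin(mrad) * math.cos(2 * l0r)
        - 0.5 * y * y * math.sin(4 * l0r)
        - 1.25 * e * e * math.sin(2 * mrad)
    )
    return decl, eot


def solar_elevation(latitude: float, longitude: float, when: datetime) -> float:
    """Solar elevation angle in degrees at the given location and instant.

    Parameters
    ----------
    latitude, longitude : float
        Decimal degrees; longitude positive east.
    when : datetime
        Timezone-aware timestamp.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude out of range: {latitude}")
    if not -180.0 <= longitude <= 180.0:
        raise ValueError(f"longitude out of range: {longitude}")
    jd = julian_day(when)
    t = (jd - 2451545.0) / 36525.0
    decl, eot = _sun_declination_and_eot(t)

    u = when.astimezone(timezone.utc)
    minutes_utc = u.hour * 60.0 + u.minute + (u.second + u.microsecond / 1e6) / 60.0
    true_solar_minutes = (minutes_utc + eot + 4.0 * longitude) % 1440.0
    hour_angle = true_solar_minutes / 4.0 - 180.0
    if hour_angle < -180.0:
        hour_angle += 360.0

    lat_r = math.radians(latitude)
    decl_r = math.radians(decl)
    cos_zenith = math.sin(lat_r) * math.sin(decl_r) + math.cos(lat_r) * math.cos(decl_r) * math.cos(
        math.radians(hour_angle)
    )
    cos_zenith = min(1.0, max(-1.0, cos_zenith))
    return 90.0 - math.degrees(math.acos(cos_zenith))
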