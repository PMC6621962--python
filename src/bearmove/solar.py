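"""Sunrise/sunset from standard solar geometry (NOAA low-accuracy algorithm).

Accurate to a minute or two at mid-latitudes, which is ample for labeling
45-minute movement steps as day or night.  Polar latitudes (|lat| >= 66)
are rejected because the day/night partition is undefined there for parts
of the year.
"""

from __future__ import annotations

import datetime as dt
import math
from zoneinfo import ZoneInfo

_ZENITH = 90.833  # official sunrise/sunset zenith, degrees (refraction + solar radius)


def _solar_event_utc(date: dt.date, latitude: float, longitude: float, rising: bool) -> dt.datetime:
    """UTC time of sunrise (rising=True) or sunset on `date` at (lat, lon)."""
    n = date.timetuple().tm_yday
    lng_hour = longitude / 15.0
    t = n + ((6.0 if rising else 18.0) - lng_hour) / 24.0

    mean_anom = 0.9856 * t - 3.289
    true_lon = mean_anom + 1.916 * math.sin(math.radians(mean_anom)) \
        + 0.020 * math.sin(math.radians(2 * mean_anom)) + 282.634
    true_lon %= 360.0

    ra = math.degrees(math.atan(0.91764 * math.tan(math.radians(true_lon)))) % 360.0
    # right ascension into the same quadrant as the true longitude
    ra += (math.floor(true_lon / 90.0) - math.floor(ra / 90.0)) * 90.0
    ra /= 15.0

    sin_dec = 0.39782 * math.sin(math.radians(true_lon))
    cos_dec = math.cos(math.asin(sin_dec))

    cos_h = (math.cos(math.radians(_ZENITH)) - sin_dec * math.sin(math.radians(latitude))) / (
        cos_dec * math.cos(math.radians(latitude))
    )
    if not -1.0 <= cos_h <= 1.0:
        raise ValueError(f"sun never rises/sets at lat={latitude} on {date}")

    h = math.degrees(math.acos(cos_h))
    if rising:
        h = 360.0 - h
    h /= 15.0

    local_mean = h + ra - 0.06571 * t - 6.622
    ut = (local_mean - lng_hour) % 24.0
    base = dt.datetime(date.year, date.month, date.day, tzinfo=dt.timezone.utc)
    return base + dt.timedelta(hours=ut)


def sunrise_sunset(
    date: dt.date, latitude: float, longitude: float, tz: str | ZoneInfo = "UTC"
) -> tuple[dt.datetime, dt.datetime]:
    """Local sunrise and sunset datetimes for a calendar date.

    Raises ValueError for latitudes outside (-66, 66).
    """
    if not -66.0 < latitude < 66.0:
        raise ValueError("latitudes with polar day/night are unsupported")
    zone = ZoneInfo(tz) if isinstance(tz, str) else tz
    events = []
    for rising in (True, False):
        ev = _solar_event_utc(date, latitude, longitude, rising).astimezone(zone)
        # the UT hour can wrap past UTC midnight onto the wrong local date;
        # re-anchor to the requested date (sub-minute drift per day)
        ev += dt.timedelta(days=(date - ev.date()).days)
        events.append(ev)
    return events[0], events[1]


def is_daytime(when: dt.datetime, latitude: float, longitude: float, tz: str | ZoneInfo = "UTC") -> bool:
    """True iff `when` falls in [sunrise, sunset) local time on its local date."""
    zone = ZoneInfo(tz) if isinstance(tz, str) else tz
    local = when.astimezone(zone)
    rise, sset = sunrise_sunset(local.date(), latitude, longitude, zone)
    return rise <= local < sset
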