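"""Astronomical day length.

Wheat phenology models count light perceived well past geometric sunset:
photoperiodically effective radiation is conventionally taken to start and
end when the sun is 6 degrees below the horizon (civil twilight).  The
functions here compute that day length from latitude and day of year using
standard solar geometry: solar declination from a Fourier series in the day
angle, and the half-day hour angle at which the solar altitude crosses
``-sun_angle``.

No longitude or time-zone correction is applied; the result is the duration
of the photoperiod, not clock times of sunrise/sunset.
"""

from __future__ import annotations

import datetime as _dt

import numpy as np

__all__ = ["solar_declination", "photoperiod", "day_of_year"]


def day_of_year(date: _dt.date) -> int:
    """Day of year (1..366) of a calendar date, proleptic Gregorian."""
    return date.timetuple().tm_yday


def solar_declination(doy):
    """Solar declination in degrees for a day of year (1..366).

    Uses the Spencer Fourier expansion of the declination in the day angle
    ``g = 2*pi*(doy - 1)/365``; accurate to ~0.01 rad, ample for day-length
    work at daily resolution.
    """
    g = 2.0 * np.pi * (np.asarray(doy, dtype=float) - 1.0) / 365.0
    decl = (
        0.006918
        - 0.399912 * np.cos(g)
        + 0.070257 * np.sin(g)
        - 0.006758 * np.cos(2 * g)
        + 0.000907 * np.sin(2 * g)
        - 0.002697 * np.cos(3 * g)
        + 0.00148 * np.sin(3 * g)
    )
    return np.degrees(decl)


def photoperiod(doy, latitude: float, sun_angle: float = 6.0):
    """Day length in hours when the sun is above ``-sun_angle`` degrees.

    Parameters
    ----------
    doy : int or array-like
        Day of year, 1..366.
    latitude : float
        Site latitude in degrees north, in [-90, 90].
    sun_angle : float, default 6
        Depression angle below the horizon (degrees) at which light is
        still photoperiodically effective.  ``0`` gives the geometric
        sunrise-to-sunset day length.

    Returns
    -------
    hours : float or ndarray
        In [0, 24]; 24 under polar day, 0 under polar night.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError(f"latitude must be in [-90, 90], got {latitude}")
    lat = np.radians(latitude)
    decl = np.radians(solar_declination(doy))
    # altitude h satisfies sin(h) = sin(lat)sin(decl) + cos(lat)cos(decl)cos(H)
    # solve for hour angle H at h = -sun_angle
    cos_h = (np.sin(np.radians(-sun_angle)) - np.sin(lat) * np.sin(decl)) / (
        np.cos(lat) * np.cos(decl)
    )
    cos_h = np.clip(cos_h, -1.0, 1.0)  # polar day (-1) / polar night (+1)
    hours = 2.0 * np.degrees(np.arccos(cos_h)) / 15.0
    if np.ndim(doy) == 0:
        return float(hours)
    return hours
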