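"""Independent solar-position oracle for the test suite.

Implements the higher-accuracy solar position algorithm from Meeus,
*Astronomical Algorithms* (2nd ed., ch. 25): Keplerian elements in
Julian centuries, equation of centre, apparent longitude with nutation,
true obliquity, equatorial coordinates, and the hour angle via Greenwich
apparent sidereal time.  Accuracy is about 0.01 deg -- an order of
magnitude better than the NOAA low-accuracy formulas used by the
package, and derived along a completely different route, so it serves as
the ephemeris oracle.  Never imported by the implementation.
"""

from __future__ import annotations

import math

import pandas as pd


def _julian_day(ts: pd.Timestamp) -> float:
    y, m = ts.year, ts.month
    d = (ts.day + ts.hour / 24.0 + ts.minute / 1440.0 + ts.second / 86400.0
         + ts.microsecond / 86400.0e6)
    if m <= 2:
        y -= 1
        m += 12
    a = y // 100
    b = 2 - a + a // 4
    return math.floor(365.25 * (y + 4716)) + math.floor(30.6001 * (m + 1)) + d + b - 1524.5


def sun_elevation_meeus(time, lat_deg: float, lon_deg: float) -> float:
    """Apparent sun elevation (deg, no refraction) at a UTC instant."""
    ts = pd.Timestamp(time)
    jd = _julian_day(ts)  # UT ~ TT to well under the 0.01 deg level here
    T = (jd - 2451545.0) / 36525.0

    L0 = (280.46646 + 36000.76983 * T + 0.0003032 * T * T) % 360.0
    M = math.radians(357.52911 + 35999.05029 * T - 0.0001537 * T * T)
    C = ((1.914602 - 0.004817 * T - 0.000014 * T * T) * math.sin(M)
         + (0.019993 - 0.000101 * T) * math.sin(2 * M)
         + 0.000289 * math.sin(3 * M))
    true_lon = L0 + C
    omega = math.radians(125.04 - 1934.136 * T)
    app_lon = math.radians(true_lon - 0.00569 - 0.00478 * math.sin(omega))

    eps0 = (23.0 + 26.0 / 60 + 21.448 / 3600
            - (46.8150 * T + 0.00059 * T * T - 0.001813 * T ** 3) / 3600.0)
    eps = math.radians(eps0 + 0.00256 * math.cos(omega))

    ra = math.atan2(math.cos(eps) * math.sin(app_lon), math.cos(app_lon))
    dec = math.asin(math.sin(eps) * math.sin(app_lon))

    # Greenwich apparent sidereal time (mean sidereal + equation of equinoxes)
    gmst = (280.46061837 + 360.98564736629 * (jd - 2451545.0)
            + 0.000387933 * T * T - T ** 3 / 38710000.0) % 360.0
    dpsi = (-17.20 * math.sin(omega)) / 3600.0  # dominant nutation term
    gast = gmst + dpsi * math.cos(eps)

    H = math.radians((gast + lon_deg) % 360.0) - ra
    phi = math.radians(lat_deg)
    sin_el = (math.sin(phi) * math.sin(dec)
              + math.cos(phi) * math.cos(dec) * math.cos(H))
    return math.degrees(math.asin(max(-1.0, min(1.0, sin_el))))
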