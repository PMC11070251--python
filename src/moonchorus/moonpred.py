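"""Per-recording moonlight covariate from date, time and site location.

Night-time illumination from the moon varies over the ~29.53-day synodic
cycle by orders of magnitude, and additionally with the moon's distance
and its altitude above the local horizon.  This module computes, for any
instant and site, the lunar phase angle, illuminated disc fraction,
topocentric altitude, a waxing/waning flag, and a dimensionless
*relative ground illumination*:

    illuminated_fraction * (mean_distance / distance)^2
        * sin(altitude) * atmospheric extinction,

zeroed whenever the moon is below the horizon.  The quantity is relative
(full moon at zenith at mean distance ~ 1), not calibrated to lux:
cloud cover, canopy attenuation and twilight are out of scope, which is
acceptable for an ecological covariate entering a regression.

Positions come from standard truncated ephemeris series (Meeus-level
accuracy: ~0.3 deg in lunar longitude, ~0.2 deg in latitude), valid over
1950-2050.  Near syzygy the illuminated fraction is insensitive to
longitude error (it enters through ``cos`` at an extremum), so full and
new moon are located to well within the accuracy needed here.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import EphemerisError, JoinError
from .io import SiteConfig
from .zicount import CountRecord

__all__ = [
    "MoonIllumination",
    "EphemerisError",
    "moon_state",
    "moon_ephemeris",
    "attach_moon",
    "moon_timeseries",
]

#: mean Earth-moon distance (km), used to normalize the distance correction
MEAN_LUNAR_DISTANCE_KM = 384_400.0

#: V-band atmospheric extinction coefficient (magnitudes per airmass)
EXTINCTION_MAG_PER_AIRMASS = 0.25

#: altitude (degrees) below which ground illumination is zero; no refraction
HORIZON_CUTOFF_DEG = 0.0

_AU_KM = 149_597_870.7
_J2000 = 2_451_545.0

_DEG = np.pi / 180.0


@dataclass(frozen=True)
class MoonIllumination:
    """Lunar state relevant to ground illumination at one instant and site."""

    timestamp: pd.Timestamp
    latitude: float
    longitude: float
    phase_angle: float          # degrees, 0 = full, 180 = new
    illuminated_fraction: float  # (1 + cos(phase_angle)) / 2
    moon_altitude: float        # topocentric, degrees
    waxing: bool
    relative_ground_illumination: float


def _to_jd(timestamps) -> np.ndarray:
    """UTC timestamps -> Julian dates (float64 array)."""
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamps, dtype=object)))
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    else:
        ts = ts.tz_convert("UTC")
    unix = ts.asi8 / 1e9
    return unix / 86400.0 + 2_440_587.5


def _sin_d(x):
    return np.sin(x * _DEG)


def _cos_d(x):
    return np.cos(x * _DEG)


def moon_ephemeris(
    jd: np.ndarray, latitude: float, longitude: float
) -> dict[str, np.ndarray]:
    """Vectorized lunar state for an array of Julian dates at one site.

    Returns arrays: phase_angle (deg), illuminated_fraction, altitude
    (deg, topocentric), waxing (bool), distance_km, and
    relative_ground_illumination.
    """
    jd = np.asarray(jd, dtype=float)
    T = (jd - _J2000) / 36525.0

    # --- lunar ecliptic position, truncated series ---
    lam_m = (
        218.32
        + 481_267.8813 * T
        + 6.29 * _sin_d(134.9 + 477_198.85 * T)
        - 1.27 * _sin_d(259.2 - 413_335.38 * T)
        + 0.66 * _sin_d(235.7 + 890_534.23 * T)
        + 0.21 * _sin_d(269.9 + 954_397.70 * T)
        - 0.19 * _sin_d(357.5 + 35_999.05 * T)
        - 0.11 * _sin_d(186.6 + 966_404.05 * T)
    )
    beta_m = (
        5.13 * _sin_d(93.3 + 483_202.03 * T)
        + 0.28 * _sin_d(228.2 + 960_400.87 * T)
        - 0.28 * _sin_d(318.3 + 6_003.18 * T)
        - 0.17 * _sin_d(217.6 - 407_332.20 * T)
    )
    parallax = (
        0.9508
        + 0.0518 * _cos_d(134.9 + 477_198.85 * T)
        + 0.0095 * _cos_d(259.2 - 413_335.38 * T)
        + 0.0078 * _cos_d(235.7 + 890_534.23 * T)
        + 0.0028 * _cos_d(269.9 + 954_397.70 * T)
    )
    dist_m = 6378.14 / _sin_d(parallax)  # km

    # --- solar ecliptic longitude and distance ---
    L0 = 280.46646 + 36_000.76983 * T
    M = 357.52911 + 35_999.05029 * T
    C = (
        (1.914602 - 0.004817 * T) * _sin_d(M)
        + (0.019993 - 0.000101 * T) * _sin_d(2 * M)
        + 0.000289 * _sin_d(3 * M)
    )
    lam_s = L0 + C
    ecc = 0.016708634 - 0.000042037 * T
    nu = M + C
    dist_s = 1.000001018 * (1 - ecc**2) / (1 + ecc * _cos_d(nu)) * _AU_KM

    # --- equatorial coordinates ---
    eps = 23.4392911 - 0.0130042 * T

    def _equatorial(lam, beta):
        sl, cl = _sin_d(lam), _cos_d(lam)
        sb, cb = _sin_d(beta), _cos_d(beta)
        se, ce = _sin_d(eps), _cos_d(eps)
        ra = np.arctan2(sl * ce - np.tan(beta * _DEG) * se, cl) / _DEG
        dec = np.arcsin(sb * ce + cb * se * sl) / _DEG
        return ra, dec

    ra_m, dec_m = _equatorial(lam_m, beta_m)
    ra_s, dec_s = _equatorial(lam_s, np.zeros_like(lam_s))

    # --- phase angle and illuminated fraction ---
    cos_psi = np.clip(
        _sin_d(dec_s) * _sin_d(dec_m)
        + _cos_d(dec_s) * _cos_d(dec_m) * _cos_d(ra_s - ra_m),
        -1.0,
        1.0,
    )
    psi = np.arccos(cos_psi)  # geocentric elongation, radians
    phase = np.arctan2(dist_s * np.sin(psi), dist_m - dist_s * cos_psi) / _DEG
    frac = (1.0 + _cos_d(phase)) / 2.0
    waxing = np.mod(lam_m - lam_s, 360.0) < 180.0

    # --- topocentric altitude (parallax-corrected, no refraction) ---
    gmst = 280.460_618_37 + 360.985_647_366_29 * (jd - _J2000)
    hour_angle = gmst + longitude - ra_m
    sin_alt = _sin_d(latitude) * _sin_d(dec_m) + _cos_d(latitude) * _cos_d(
        dec_m
    ) * _cos_d(hour_angle)
    alt = np.arcsin(np.clip(sin_alt, -1.0, 1.0)) / _DEG
    alt = alt - parallax * _cos_d(alt)  # horizontal parallax lowers the moon

    # --- relative ground illumination ---
    up = alt > HORIZON_CUTOFF_DEG
    sin_alt_up = np.where(up, _sin_d(np.maximum(alt, 1e-6)), 1.0)
    airmass = 1.0 / sin_alt_up
    extinction = 10.0 ** (-0.4 * EXTINCTION_MAG_PER_AIRMASS * (airmass - 1.0))
    rgi = np.where(
        up,
        frac * (MEAN_LUNAR_DISTANCE_KM / dist_m) ** 2 * sin_alt_up * extinction,
        0.0,
    )

    return {
        "phase_angle": phase,
        "illuminated_fraction": frac,
        "altitude": alt,
        "waxing": waxing,
        "distance_km": dist_m,
        "relative_ground_illumination": rgi,
    }


def _check_range(ts: pd.Timestamp) -> None:
    if not 1950 <= ts.year <= 2050:
        raise EphemerisError(
            f"timestamp {ts} outside supported ephemeris range 1950-2050"
        )


def moon_state(timestamp, site: SiteConfig) -> MoonIllumination:
    """Lunar illumination state for one instant at one recording site."""
    ts = pd.Timestamp(timestamp)
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    _check_range(ts)
    eph = moon_ephemeris(_to_jd([ts]), site.latitude, site.longitude)
    return MoonIllumination(
        timestamp=ts,
        latitude=site.latitude,
        longitude=site.longitude,
        phase_angle=float(eph["phase_angle"][0]),
        illuminated_fraction=float(eph["illuminated_fraction"][0]),
        moon_altitude=float(eph["altitude"][0]),
        waxing=bool(eph["waxing"][0]),
        relative_ground_illumination=float(eph["relative_ground_illumination"][0]),
    )


def attach_moon(
    records: Sequence[CountRecord],
    sites: Mapping[str, SiteConfig],
    measure: str = "relative_ground_illumination",
    rescale: bool = True,
    window_duration: float = 600.0,
    passthrough: bool = True,
) -> list[CountRecord]:
    """Join the moonlight covariate onto count records.

    The covariate is evaluated at each recording window's midpoint.
    ``measure`` selects the ephemeris output used (default the relative
    ground illumination); with ``rescale`` the values are min-max scaled
    to [0, 1] across the dataset, a convenient scale for model input
    where 0 ~ darkest and 1 ~ brightest observed window.

    Records that already carry a covariate are passed through unchanged
    when ``passthrough`` is set (externally computed columns are trusted
    verbatim); a single record lacking it triggers full recomputation.
    """
    records = list(records)
    if not records:
        return []
    if passthrough and all(r.moon is not None for r in records):
        return records
    for r in records:
        if r.site_id not in sites:
            raise JoinError(f"no site configuration for site_id {r.site_id!r}")
        _check_range(pd.Timestamp(r.window_start))

    values = np.empty(len(records))
    by_site: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_site.setdefault(r.site_id, []).append(i)
    for site_id, idx in by_site.items():
        site = sites[site_id]
        mids = [
            pd.Timestamp(records[i].window_start) + pd.Timedelta(seconds=window_duration / 2)
            for i in idx
        ]
        eph = moon_ephemeris(_to_jd(mids), site.latitude, site.longitude)
        values[idx] = eph[measure]
    if rescale:
        lo, hi = values.min(), values.max()
        values = (values - lo) / (hi - lo) if hi > lo else np.zeros_like(values)
    return [replace(r, moon=float(v)) for r, v in zip(records, values)]


def moon_timeseries(
    site: SiteConfig,
    start,
    end,
    step_minutes: int = 60,
) -> pd.DataFrame:
    """Regular time series of the lunar covariate for one site."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    tz = site.tzinfo
    if start.tz is None:
        start = start.tz_localize(tz)
    if end.tz is None:
        end = end.tz_localize(tz)
    _check_range(start)
    _check_range(end)
    times = pd.date_range(start, end, freq=f"{step_minutes}min")
    eph = moon_ephemeris(_to_jd(times), site.latitude, site.longitude)
    return pd.DataFrame(
        {
            "timestamp": times,
            "phase_angle": eph["phase_angle"],
            "illuminated_fraction": eph["illuminated_fraction"],
            "moon_altitude": eph["altitude"],
            "waxing": eph["waxing"],
            "moon_illumination": eph["relative_ground_illumination"],
        }
    )
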