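"""Solar events and diel (hour-of-day) profiles of movement behaviour.

Sunrise/sunset/solar noon come from the NOAA solar position algorithm
(fractional year, equation of time, solar declination, hour angle at zenith
90.833 deg).  Hour-of-day effects on speed and on the probability of ARS are
fitted as cyclic-harmonic regressions: ordinary least squares (speed) or a
binomial-logit GLM (ARS occurrence) on {sin, cos}(2 pi k h / 24) terms.
These replace smoother-based fits: only the qualitative profile shape (peak
timing, flat vs peaked) is comparable to smooths, which is documented.

Diel hours are solar-local: UTC hour + lon / 15, since tracks span many
degrees of longitude.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import AnalysisError, ParameterError
from .ssm import StateSeries

SUNRISE_ZENITH_DEG = 90.833          # refraction + solar disc radius
DARKNESS_ELEVATION_DEG = -12.0       # nautical twilight


# ---------------------------------------------------------------------------
# Solar events (NOAA algorithm)

@dataclass
class SolarEvents:
    date: pd.Timestamp
    lon: float
    lat: float
    sunrise: pd.Timestamp | None     # UTC
    sunset: pd.Timestamp | None
    solar_noon: pd.Timestamp
    day_length_h: float
    min_elevation_deg: float         # solar elevation at solar midnight
    polar_flag: str                  # none | midnight_sun | polar_night | no_full_darkness


def _noaa_eqtime_decl(doy: int, hour: float = 12.0) -> tuple[float, float]:
    """Equation of time (minutes) and solar declination (radians)."""
    g = 2.0 * math.pi / 365.0 * (doy - 1 + (hour - 12.0) / 24.0)
    eqtime = 229.18 * (0.000075 + 0.001868 * math.cos(g) - 0.032077 * math.sin(g)
                       - 0.014615 * math.cos(2 * g) - 0.040849 * math.sin(2 * g))
    decl = (0.006918 - 0.399912 * math.cos(g) + 0.070257 * math.sin(g)
            - 0.006758 * math.cos(2 * g) + 0.000907 * math.sin(2 * g)
            - 0.002697 * math.cos(3 * g) + 0.00148 * math.sin(3 * g))
    return eqtime, decl


def solar_events(lat: float, lon: float, date) -> SolarEvents:
    """Sunrise, sunset and solar noon (UTC) for a civil date and position.

    Polar situations are reported through ``polar_flag``: ``midnight_sun``
    (sun never sets), ``polar_night`` (never rises) or ``no_full_darkness``
    (sun never drops 12 deg below the horizon -- incomplete darkness at
    night, the nautical-twilight criterion).
    """
    if not (-90.0 <= lat <= 90.0) or not (-180.0 <= lon <= 180.0):
        raise ParameterError(f"invalid coordinates lat={lat} lon={lon}")
    date = pd.Timestamp(date)
    doy = int(date.dayofyear)
    eqtime, decl = _noaa_eqtime_decl(doy)
    phi = math.radians(lat)

    noon_min = 720.0 - 4.0 * lon - eqtime
    midnight = pd.Timestamp(date.date(), tz="UTC")
    solar_noon = midnight + pd.Timedelta(minutes=noon_min)

    cos_ha = ((math.cos(math.radians(SUNRISE_ZENITH_DEG))
               - math.sin(phi) * math.sin(decl))
              / (math.cos(phi) * math.cos(decl)))
    min_elev = math.degrees(math.asin(
        max(-1.0, min(1.0, math.sin(phi) * math.sin(decl)
                      - math.cos(phi) * math.cos(decl)))))

    if cos_ha < -1.0:
        return SolarEvents(date, lon, lat, None, None, solar_noon, 24.0,
                           min_elev, "midnight_sun")
    if cos_ha > 1.0:
        return SolarEvents(date, lon, lat, None, None, solar_noon, 0.0,
                           min_elev, "polar_night")
    ha_deg = math.degrees(math.acos(cos_ha))
    sunrise = midnight + pd.Timedelta(minutes=720.0 - 4.0 * (lon + ha_deg) - eqtime)
    sunset = midnight + pd.Timedelta(minutes=720.0 - 4.0 * (lon - ha_deg) - eqtime)
    flag = "no_full_darkness" if min_elev > DARKNESS_ELEVATION_DEG else "none"
    return SolarEvents(date, lon, lat, sunrise, sunset, solar_noon,
                       8.0 * ha_deg / 60.0, min_elev, flag)


def solar_local_hours(times, lons) -> np.ndarray:
    """Solar-local hour of day: UTC hour + lon / 15, wrapped to [0, 24)."""
    idx = pd.DatetimeIndex(times)
    utc_h = idx.hour + idx.minute / 60.0 + idx.second / 3600.0
    return np.mod(utc_h.to_numpy(dtype=float) + np.asarray(lons, dtype=float) / 15.0, 24.0)


# ---------------------------------------------------------------------------
# Cyclic-harmonic profiles

@dataclass
class DielProfile:
    """A 24 h-periodic fitted profile: hourly means with pointwise SEs."""

    hour_grid: np.ndarray        # 0..23
    mean: np.ndarray
    se: np.ndarray
    coefficients: np.ndarray     # [intercept, sin1, cos1, sin2, cos2, ...]
    n_harmonics: int
    scale: str = "response"      # "response" (identity) or "probability" (logit fit)

    def predict(self, hours) -> np.ndarray:
        X = _harmonic_design(np.atleast_1d(np.asarray(hours, dtype=float)),
                             self.n_harmonics)
        eta = X @ self.coefficients
        if self.scale == "probability":
            return 1.0 / (1.0 + np.exp(-eta))
        return eta


def _harmonic_design(hours: np.ndarray, n_harmonics: int) -> np.ndarray:
    cols = [np.ones_like(hours)]
    for k in range(1, n_harmonics + 1):
        w = 2.0 * math.pi * k * hours / 24.0
        cols.append(np.sin(w))
        cols.append(np.cos(w))
    return np.column_stack(cols)


def diel_profile(hours, responses, n_harmonics: int = 2) -> DielProfile:
    """Least-squares cyclic-harmonic fit of a response on hour of day.

    With ``n_harmonics=0`` this is just the sample mean everywhere.  Raises
    on rank deficiency (e.g. all observations in a single hour).
    """
    hours = np.asarray(hours, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if np.any((hours < 0) | (hours >= 24)):
        raise ParameterError("hours must lie in [0, 24)")
    n_min = max(4 * n_harmonics, 1)
    if len(hours) < n_min:
        raise ParameterError(f"need >= {n_min} observations for {n_harmonics} harmonics")
    X = _harmonic_design(hours, n_harmonics)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AnalysisError("rank-deficient harmonic design (hours too concentrated)")
    res = sm.OLS(responses, X).fit()
    grid = np.arange(24, dtype=float)
    Xg = _harmonic_design(grid, n_harmonics)
    pred = res.get_prediction(Xg)
    return DielProfile(hour_grid=grid, mean=np.asarray(pred.predicted_mean),
                       se=np.asarray(pred.se_mean),
                       coefficients=np.asarray(res.params), n_harmonics=n_harmonics)


def hourly_ars_probability(states: StateSeries | list[StateSeries],
                           n_harmonics: int = 2) -> DielProfile:
    """Binomial-logit harmonic regression of ARS occurrence on solar hour.

    Uses classified grid states (uncertain excluded); the fitted profile is
    returned on the probability scale through the inverse logit.
    """
    series = states if isinstance(states, list) else [states]
    frames = [s.frame for s in series]
    df = pd.concat(frames, ignore_index=True)
    df = df[df["behaviour"].isin(["transiting", "ARS"])]
    if df.empty or df["behaviour"].nunique() < 2:
        raise AnalysisError("need both ARS and non-ARS states for the diel fit")
    hours = solar_local_hours(df["time"], df["lon"].to_numpy())
    y = (df["behaviour"] == "ARS").to_numpy(dtype=float)
    X = _harmonic_design(hours, n_harmonics)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise AnalysisError("rank-deficient harmonic design (hours too concentrated)")
    res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    grid = np.arange(24, dtype=float)
    Xg = _harmonic_design(grid, n_harmonics)
    pred = res.get_prediction(Xg)
    return DielProfile(hour_grid=grid,
                       mean=np.asarray(pred.predicted_mean),
                       se=np.asarray(pred.se_mean),
                       coefficients=np.asarray(res.params),
                       n_harmonics=n_harmonics, scale="probability")


# ---------------------------------------------------------------------------
# Circular homogeneity (permutation analogue of a circular ANOVA)

def _group_stat(angles: np.ndarray, sizes: np.ndarray) -> float:
    """Sum over groups of n_g * mean resultant length."""
    stat = 0.0
    start = 0
    for n in sizes:
        a = angles[start:start + n]
        start += n
        if n == 0:
            continue
        C = np.cos(a).sum()
        S = np.sin(a).sum()
        stat += math.hypot(C, S)     # n_g * Rbar_g
    return stat


def circular_homogeneity_test(angles_by_group: dict, n_perm: int = 999,
                              seed: int = 0) -> dict:
    """Permutation test for equal angular distributions across groups.

    The statistic is the size-weighted sum of per-group mean resultant
    lengths; the null distribution comes from ``n_perm`` random relabellings
    of the pooled angles.  ``p = (1 + #{perm >= obs}) / (n_perm + 1)``.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in angles_by_group.items()}
    if len(groups) < 2:
        raise ParameterError("need >= 2 groups")
    for k, v in groups.items():
        if len(v) < 5:
            raise ParameterError(f"group {k!r} has {len(v)} angles; need >= 5")
    sizes = np.array([len(v) for v in groups.values()])
    pooled = np.concatenate(list(groups.values()))
    obs = _group_stat(pooled, sizes)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if _group_stat(perm, sizes) >= obs - 1e-12:
            count += 1
    return {"statistic": obs, "p_value": (1 + count) / (n_perm + 1), "n_perm": n_perm}
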