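"""Residency, departure and ARS-area analyses derived from classified states.

Departure from the tagging area is defined as the first run of >= 48
consecutive hours in which every interval speed strictly exceeds the pooled
median ARS speed.  Residence times (with right censoring for tags that
stopped before departure) feed a Kaplan-Meier product-limit estimator and a
weighted logistic regression of daily departure probability on days since
tagging (DST).  A discrete ARS area is a maximal run of >= 3 consecutive
ARS-classified positions; its size is the minimum convex polygon (MCP) area
on a local equal-area projection.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from shapely.geometry import MultiPoint, Polygon

from .exceptions import AnalysisError, ParameterError
from .movement_metrics import EARTH_RADIUS_KM, KinematicSeries
from .ssm import StateSeries

logger = logging.getLogger("whaletrack")

DEPARTURE_WINDOW_HOURS = 48.0
MIN_ARS_RUN = 3


# ---------------------------------------------------------------------------
# Domain types

@dataclass
class ResidencyRecord:
    """One animal's residence duration in the tagging area.

    ``censored`` means the tag stopped transmitting before a departure was
    detected, so ``residence_days`` is a lower bound (equal to track length).
    """

    animal_id: str
    tagging_date: pd.Timestamp
    residence_days: float
    censored: bool
    track_days: float

    def __post_init__(self) -> None:
        if self.residence_days < 0 or self.track_days < 0:
            raise ParameterError("durations must be non-negative")
        if self.residence_days > self.track_days + 1e-9:
            raise ParameterError(
                f"{self.animal_id}: residence {self.residence_days} exceeds "
                f"track length {self.track_days}"
            )


@dataclass
class DepartureResult:
    animal_id: str
    departure_time: pd.Timestamp | None
    censored: bool


@dataclass
class KMEstimate:
    """Kaplan-Meier product-limit estimate of P(still resident at t)."""

    times: np.ndarray
    survival: np.ndarray
    median: float               # smallest t with S(t) <= 0.5 (nan if never)
    lower_quartile: float       # smallest t with S(t) <= 0.75 (25% departed)
    upper_quartile: float       # smallest t with S(t) <= 0.25 (75% departed)
    n_events: int
    n_censored: int


@dataclass
class ARSArea:
    """A discrete area-restricted-search patch within one track."""

    animal_id: str
    indices: np.ndarray         # member grid-time indices (consecutive)
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    duration_h: float
    vertices: np.ndarray        # MCP vertices, (n, 2) lon/lat degrees
    area_km2: float
    centroid: tuple[float, float]
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Departure detection

def median_ars_speed(kinematics: list[KinematicSeries]) -> float:
    """Median speed over all ARS-classified intervals pooled across animals."""
    speeds = np.concatenate(
        [k.speeds[k.behaviours == "ARS"] for k in kinematics]
    ) if kinematics else np.array([])
    if speeds.size == 0:
        raise AnalysisError(
            "no ARS-classified intervals in the pooled tracks; "
            "cannot form the departure speed threshold"
        )
    return float(np.median(speeds))


def detect_departure(kinematics: KinematicSeries, threshold: float,
                     window_h: float = DEPARTURE_WINDOW_HOURS) -> DepartureResult:
    """First run of >= ``window_h`` consecutive hours all faster than ``threshold``.

    Every interval in the run must have speed strictly greater than the
    threshold; the departure time is the start of the earliest such run.  If
    no run qualifies the record is censored at the track end.
    """
    if threshold <= 0:
        raise ParameterError(f"speed threshold must be > 0, got {threshold}")
    df = kinematics.frame
    if len(df) == 0:
        raise ParameterError("empty kinematic series")
    fast = (df["speed_kmh"] > threshold).to_numpy()
    elapsed = df["elapsed_h"].to_numpy()
    i = 0
    n = len(fast)
    while i < n:
        if not fast[i]:
            i += 1
            continue
        jj = i
        total = 0.0
        while jj < n and fast[jj]:
            total += elapsed[jj]
            jj += 1
        if total >= window_h:
            return DepartureResult(kinematics.animal_id,
                                   pd.Timestamp(df["t_start"].iloc[i]), False)
        i = jj
    return DepartureResult(kinematics.animal_id, None, True)


def residency_record(kinematics: KinematicSeries, threshold: float,
                     tagging_date: pd.Timestamp | None = None,
                     window_h: float = DEPARTURE_WINDOW_HOURS) -> ResidencyRecord:
    """Departure detection packaged as a residency record for one animal."""
    df = kinematics.frame
    start = pd.Timestamp(df["t_start"].iloc[0]) if tagging_date is None else tagging_date
    end = pd.Timestamp(df["t_end"].iloc[-1])
    track_days = (end - start).total_seconds() / 86400.0
    dep = detect_departure(kinematics, threshold, window_h)
    if dep.censored:
        res_days = track_days
    else:
        res_days = (dep.departure_time - start).total_seconds() / 86400.0
    return ResidencyRecord(kinematics.animal_id, start, res_days, dep.censored, track_days)


# ---------------------------------------------------------------------------
# Survival analysis

def _first_time_below(times: np.ndarray, surv: np.ndarray, level: float) -> float:
    idx = np.nonzero(surv <= level + 1e-12)[0]
    return float(times[idx[0]]) if idx.size else float("nan")


def kaplan_meier(records: list[ResidencyRecord]) -> KMEstimate:
    """Product-limit estimator of residence duration with right censoring.

    Ties are handled in the standard way (events before censorings at equal
    times); quartile times are the smallest t with S(t) <= 0.75 / 0.5 / 0.25.
    """
    if not records:
        raise ParameterError("need at least one residency record")
    durations = np.array([r.residence_days for r in records], dtype=float)
    events = np.array([not r.censored for r in records], dtype=bool)
    if np.any(durations < 0):
        raise ParameterError("negative residence duration")
    kmf = KaplanMeierFitter()
    kmf.fit(durations, event_observed=events)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    return KMEstimate(
        times=times,
        survival=surv,
        median=_first_time_below(times, surv, 0.5),
        lower_quartile=_first_time_below(times, surv, 0.75),
        upper_quartile=_first_time_below(times, surv, 0.25),
        n_events=int(events.sum()),
        n_censored=int((~events).sum()),
    )


def logistic_departure_curve(records: list[ResidencyRecord]) -> dict:
    """Weighted logistic regression of departure probability on DST.

    For each whole day d since tagging, the animals with working tags on day
    d form the binomial denominator and those already departed the numerator;
    the GLM (binomial, logit link, IRLS) is therefore weighted by the number
    of working tags at each DST.  Returns the slope and intercept on the
    departure scale and ``dst_at_half = -intercept/slope``, the DST at which
    the chance of having departed reaches 50%.
    """
    if not records:
        raise ParameterError("need residency records")
    max_day = int(math.ceil(max(r.track_days for r in records)))
    days, n_dep, n_pres = [], [], []
    for d in range(1, max_day + 1):
        at_risk = [r for r in records if r.track_days >= d]
        if not at_risk:
            continue
        departed = sum(1 for r in at_risk if (not r.censored) and r.residence_days < d)
        days.append(d)
        n_dep.append(departed)
        n_pres.append(len(at_risk) - departed)
    days = np.array(days, dtype=float)
    n_dep = np.array(n_dep, dtype=float)
    n_pres = np.array(n_pres, dtype=float)
    frac = n_dep / (n_dep + n_pres)
    if not np.any((frac > 0) & (frac < 1)):
        raise AnalysisError(
            "perfect separation: departure outcome is a step function of DST; "
            "the logistic slope is not identifiable"
        )
    X = sm.add_constant(days)
    model = sm.GLM(np.column_stack([n_dep, n_pres]), X,
                   family=sm.families.Binomial())
    res = model.fit()
    intercept, slope = float(res.params[0]), float(res.params[1])
    return {
        "intercept": intercept,
        "slope": slope,
        "dst_at_half": -intercept / slope,
        "n_days": len(days),
    }


# ---------------------------------------------------------------------------
# ARS areas (minimum convex polygons)

def _laea_project(lon: np.ndarray, lat: np.ndarray,
                  lon0: float, lat0: float) -> np.ndarray:
    """Lambert azimuthal equal-area projection centred at (lon0, lat0), km."""
    lam = np.radians(lon - lon0)
    phi = np.radians(lat)
    phi0 = math.radians(lat0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    kp = np.sqrt(2.0 / denom)
    x = EARTH_RADIUS_KM * kp * np.cos(phi) * np.sin(lam)
    y = EARTH_RADIUS_KM * kp * (np.cos(phi0) * np.sin(phi)
                                - np.sin(phi0) * np.cos(phi) * np.cos(lam))
    return np.column_stack([x, y])


def mcp_polygon(points) -> tuple[np.ndarray, float, bool]:
    """Convex hull of lon/lat points on a local equal-area plane.

    Returns (hull vertices in lon/lat, area in km^2, degenerate flag); a
    collinear or duplicate-ridden set gets area 0 and the flag set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise ParameterError("need >=3 (lon, lat) points for an MCP")
    lon0, lat0 = float(pts[:, 0].mean()), float(pts[:, 1].mean())
    xy = _laea_project(pts[:, 0], pts[:, 1], lon0, lat0)
    hull = MultiPoint(xy).convex_hull
    if not isinstance(hull, Polygon):
        logger.warning("degenerate MCP (collinear or <3 distinct points): area 0")
        return pts[np.unique(pts, axis=0, return_index=True)[1]], 0.0, True
    hx, hy = hull.exterior.coords.xy
    hull_xy = np.column_stack([hx, hy])[:-1]
    # map hull vertices back to the closest input points' lon/lat
    verts = []
    for p in hull_xy:
        i = int(np.argmin(np.sum((xy - p) ** 2, axis=1)))
        verts.append(pts[i])
    return np.array(verts), float(hull.area), False


def mcp_area(points) -> float:
    """MCP area in km^2 (0.0 for degenerate point sets)."""
    return mcp_polygon(points)[1]


def extract_ars_areas(states: StateSeries) -> list[ARSArea]:
    """Maximal runs of >= 3 consecutive ARS-classified states as MCP areas.

    An "uncertain" or "transiting" state breaks a run; runs shorter than 3
    are discarded.
    """
    df = states.frame
    is_ars = (df["behaviour"] == "ARS").to_numpy()
    areas: list[ARSArea] = []
    i = 0
    n = len(is_ars)
    while i < n:
        if not is_ars[i]:
            i += 1
            continue
        jj = i
        while jj < n and is_ars[jj]:
            jj += 1
        if jj - i >= MIN_ARS_RUN:
            idx = np.arange(i, jj)
            pts = df[["lon", "lat"]].iloc[i:jj].to_numpy()
            verts, area, degen = mcp_polygon(pts)
            t_first = pd.Timestamp(df["time"].iloc[i])
            t_last = pd.Timestamp(df["time"].iloc[jj - 1])
            areas.append(
                ARSArea(
                    animal_id=states.animal_id,
                    indices=idx,
                    start_time=t_first,
                    end_time=t_last,
                    duration_h=(t_last - t_first).total_seconds() / 3600.0,
                    vertices=verts,
                    area_km2=area,
                    centroid=(float(pts[:, 0].mean()), float(pts[:, 1].mean())),
                    degenerate=degen,
                )
            )
        i = jj
    return areas


# ---------------------------------------------------------------------------
# Time budgets and reporting

def behaviour_time_budget(states: StateSeries, grouping: str = "overall") -> pd.DataFrame:
    """Fraction of grid intervals spent in each behaviour class.

    Each interval inherits the class of its starting state.  ``grouping`` is
    "overall", "day" or "month" (months pool across years, as multi-year
    tracking data must).
    """
    df = states.frame
    if len(df) < 2:
        raise ParameterError("need >=2 states for a time budget")
    cls = df["behaviour"].iloc[:-1].to_numpy()
    t_start = pd.DatetimeIndex(df["time"].iloc[:-1])
    if grouping == "overall":
        keys = np.zeros(len(cls), dtype=int)
    elif grouping == "day":
        keys = t_start.normalize()
    elif grouping == "month":
        keys = t_start.month
    else:
        raise ParameterError(f"unknown grouping {grouping!r}")
    tab = pd.DataFrame({"group": keys, "behaviour": cls})
    counts = tab.groupby("group")["behaviour"].value_counts().unstack(fill_value=0)
    for label in ("transiting", "ARS", "uncertain"):
        if label not in counts.columns:
            counts[label] = 0
    totals = counts.sum(axis=1)
    out = counts[["transiting", "ARS", "uncertain"]].div(totals, axis=0)
    out["n_intervals"] = totals
    if grouping == "overall":
        out.index = ["overall"]
    return out.reset_index(names="group")


def summarize_residency(table: pd.DataFrame, exclusions: list[str] | None = None) -> dict:
    """Cohort means of residence time and ARS proportion.

    ``table`` needs columns ``animal_id``, ``residence_days`` and
    ``ars_percent``; ``exclusions`` lists animals (e.g. very short tracks)
    left out of the means.  Means are rounded to 1 decimal for reporting.
    """
    for col in ("animal_id", "residence_days", "ars_percent"):
        if col not in table.columns:
            raise ParameterError(f"summary table missing column {col!r}")
    excl = set(str(e) for e in (exclusions or []))
    kept = table[~table["animal_id"].astype(str).isin(excl)]
    if len(kept) == 0:
        raise AnalysisError("all animals excluded from the summary")
    return {
        "n": int(len(kept)),
        "mean_residence_days": round(float(kept["residence_days"].mean()), 1),
        "mean_ars_percent": round(float(kept["ars_percent"].mean()), 1),
    }
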