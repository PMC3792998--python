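"""Geodesic kinematics over classified state series.

Distances are great-circle (haversine, R = 6371 km), headings are forward
azimuths on the sphere, and turn angles are wrapped differences of successive
azimuths in (-pi, pi] (a reversal is +pi by convention).  Each grid interval
inherits the behaviour class of its starting state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .ssm import StateSeries

EARTH_RADIUS_KM = 6371.0


def great_circle_distance(p1, p2) -> float:
    """Haversine distance in km between two (lon, lat) points in degrees."""
    lon1, lat1 = float(p1[0]), float(p1[1])
    lon2, lat2 = float(p2[0]), float(p2[1])
    for lat in (lat1, lat2):
        if not -90.0 <= lat <= 90.0:
            raise ParameterError(f"latitude {lat} outside [-90, 90]")
    return float(_haversine(np.array([lon1]), np.array([lat1]),
                            np.array([lon2]), np.array([lat2]))[0])


def _haversine(lon1, lat1, lon2, lat2) -> np.ndarray:
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def _forward_azimuth(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Initial bearing (radians, clockwise from north) of the geodesic 1 -> 2."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def wrap_angle(a):
    """Wrap angle(s) to (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(a, dtype=float), 2.0 * np.pi)


@dataclass
class KinematicSeries:
    """Per-interval kinematics for one animal.

    ``frame`` columns: t_start, t_end, distance_km, elapsed_h, speed_kmh,
    heading_deg (true), behaviour (class of the starting state).
    ``turn_angles`` has one entry per interior state (length n_intervals - 1),
    NaN where a zero-length displacement leaves the angle undefined.
    """

    animal_id: str
    frame: pd.DataFrame
    turn_angles: np.ndarray

    @property
    def speeds(self) -> np.ndarray:
        return self.frame["speed_kmh"].to_numpy()

    @property
    def behaviours(self) -> np.ndarray:
        return self.frame["behaviour"].to_numpy()


def speed_series(states: StateSeries) -> KinematicSeries:
    """Interval distances, speeds and headings between consecutive states."""
    df = states.frame
    if len(df) < 2:
        raise ParameterError("need >=2 states for kinematics")
    times = df["time"].to_numpy()
    elapsed = np.diff(times).astype("timedelta64[s]").astype(float) / 3600.0
    if np.any(elapsed <= 0):
        raise ParameterError("grid times must be strictly increasing")
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    dist = _haversine(lon[:-1], lat[:-1], lon[1:], lat[1:])
    az = _forward_azimuth(lon[:-1], lat[:-1], lon[1:], lat[1:])
    frame = pd.DataFrame(
        {
            "t_start": df["time"].iloc[:-1].to_numpy(),
            "t_end": df["time"].iloc[1:].to_numpy(),
            "distance_km": dist,
            "elapsed_h": elapsed,
            "speed_kmh": dist / elapsed,
            "heading_deg": np.degrees(np.mod(az, 2 * np.pi)),
            "behaviour": df["behaviour"].iloc[:-1].to_numpy(),
        }
    )
    return KinematicSeries(animal_id=states.animal_id, frame=frame,
                           turn_angles=turn_angle_series(states))


def turn_angle_series(states: StateSeries) -> np.ndarray:
    """Signed turn angles between successive displacements, in (-pi, pi].

    A zero-length displacement makes the adjacent angles undefined: they are
    returned as NaN, never coerced to 0.
    """
    df = states.frame
    if len(df) < 3:
        raise ParameterError("need >=3 states for turn angles")
    lon = df["lon"].to_numpy()
    lat = df["lat"].to_numpy()
    dist = _haversine(lon[:-1], lat[:-1], lon[1:], lat[1:])
    az = _forward_azimuth(lon[:-1], lat[:-1], lon[1:], lat[1:])
    # azimuths are clockwise-from-north; the DCRW rotation is counterclockwise
    # positive, so a left turn (east then north) is +pi/2
    turns = wrap_angle(az[:-1] - az[1:])
    undefined = (dist[1:] == 0.0) | (dist[:-1] == 0.0)
    turns = np.where(undefined, np.nan, turns)
    return turns
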