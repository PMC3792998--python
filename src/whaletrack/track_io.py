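"""Reading and writing Argos-style track tables and the regular state-time grid.

The raw input is one CSV row per Argos uplink: animal id, UTC timestamp,
longitude, latitude and location class (one of ``3,2,1,0,A,B``).  Tracks are
irregular in time; the state-space model works on a regular grid (2 h for fin
whales, 4 h for blue whales), so each observation is located inside its grid
interval by an index ``t`` and a fractional weight ``j in [0, 1)`` such that

    time = t0 + (t + j) * dt

and the model predicts the observed position as ``(1-j)*x_t + j*x_{t+1}``.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import ParameterError, RowError, SchemaError

logger = logging.getLogger("whaletrack")

LOCATION_CLASSES = ("3", "2", "1", "0", "A", "B")
BEHAVIOUR_LABELS = ("transiting", "ARS", "uncertain")

#: default CSV column names; override via the ``schema`` argument / YAML config
DEFAULT_SCHEMA = {
    "animal_id": "id",
    "time": "date",
    "loc_class": "lc",
    "lon": "lon",
    "lat": "lat",
}


@dataclass(frozen=True)
class ArgosObservation:
    """A single Argos uplink."""

    animal_id: str
    time: pd.Timestamp          # UTC
    lon: float                  # decimal degrees WGS84, (-180, 180]
    lat: float                  # decimal degrees WGS84
    loc_class: str              # one of LOCATION_CLASSES


@dataclass
class Track:
    """One animal's time-sorted Argos observations plus metadata.

    ``data`` has columns ``time`` (UTC), ``lon``, ``lat``, ``loc_class``.
    """

    animal_id: str
    data: pd.DataFrame
    species: str = "fin"        # {"fin", "blue"}
    tag_date: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if len(self.data) < 2:
            raise ParameterError(
                f"track {self.animal_id}: need >=2 observations, got {len(self.data)}"
            )
        if not self.data["time"].is_monotonic_increasing:
            raise ParameterError(f"track {self.animal_id}: observations not time-sorted")
        lon = self.data["lon"].to_numpy()
        if np.any(np.abs(np.diff(lon)) > 180.0):
            raise ParameterError(
                f"track {self.animal_id}: longitude jump >180 deg; tracks crossing "
                "the antimeridian are not supported"
            )
        if self.tag_date is None:
            self.tag_date = self.data["time"].iloc[0].normalize()

    @property
    def observations(self) -> list[ArgosObservation]:
        return [
            ArgosObservation(self.animal_id, row.time, row.lon, row.lat, row.loc_class)
            for row in self.data.itertuples(index=False)
        ]

    @property
    def times(self) -> np.ndarray:
        return self.data["time"].to_numpy()

    @property
    def lonlat(self) -> np.ndarray:
        return self.data[["lon", "lat"]].to_numpy(dtype=float)

    @property
    def loc_classes(self) -> np.ndarray:
        return self.data["loc_class"].to_numpy()

    def duration_hours(self) -> float:
        span = self.data["time"].iloc[-1] - self.data["time"].iloc[0]
        return span.total_seconds() / 3600.0


@dataclass
class RegularGrid:
    """Regular state timeline plus the (interval, weight) map of each observation."""

    t0: pd.Timestamp
    dt_hours: float
    n_states: int
    obs_interval: np.ndarray    # int array, one entry per observation
    obs_weight: np.ndarray      # float array, j in [0, 1)

    def times(self) -> pd.DatetimeIndex:
        return self.t0 + pd.to_timedelta(np.arange(self.n_states) * self.dt_hours, unit="h")

    def reconstruct_obs_times(self) -> pd.DatetimeIndex:
        frac = self.obs_interval + self.obs_weight
        return self.t0 + pd.to_timedelta(frac * self.dt_hours, unit="h")


def _validate_rows(df: pd.DataFrame, path: str) -> None:
    # line numbers: header is line 1
    lines = df.index.to_numpy() + 2
    bad_class = ~df["loc_class"].isin(LOCATION_CLASSES)
    if bad_class.any():
        i = int(np.argmax(bad_class.to_numpy()))
        raise RowError(
            f"{path}: unknown location class {df['loc_class'].iloc[i]!r}", int(lines[i])
        )
    for col, lo, hi in (("lat", -90.0, 90.0), ("lon", -180.0, 180.0)):
        vals = df[col].to_numpy()
        bad = ~np.isfinite(vals) | (vals < lo) | (vals > hi)
        if bad.any():
            i = int(np.argmax(bad))
            raise RowError(f"{path}: {col} value {vals[i]!r} out of range", int(lines[i]))
    if df["time"].isna().any():
        i = int(np.argmax(df["time"].isna().to_numpy()))
        raise RowError(f"{path}: unparseable timestamp", int(lines[i]))


def read_argos_observations(
    path,
    schema: dict[str, str] | None = None,
    species: str = "fin",
) -> list[Track]:
    """Read an Argos-style CSV into one :class:`Track` per animal.

    Exact duplicate rows are dropped; among fixes sharing an animal and
    timestamp (e.g. different classes) the first is kept and the rest logged.
    Animals with fewer than 2 usable rows are skipped with a warning.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    raw = pd.read_csv(path, dtype=str)
    for field_name, col in colmap.items():
        if col not in raw.columns:
            raise SchemaError(
                f"{path}: required column {col!r} (field {field_name}) missing; "
                f"found {list(raw.columns)}"
            )
    df = pd.DataFrame(
        {
            "animal_id": raw[colmap["animal_id"]].astype(str),
            "time": pd.to_datetime(raw[colmap["time"]], utc=True, errors="coerce"),
            "lon": pd.to_numeric(raw[colmap["lon"]], errors="coerce"),
            "lat": pd.to_numeric(raw[colmap["lat"]], errors="coerce"),
            "loc_class": raw[colmap["loc_class"]].astype(str).str.strip(),
        }
    )
    _validate_rows(df, str(path))

    rows_in = len(df)
    df = df.drop_duplicates()
    n_exact = rows_in - len(df)
    # duplicate-time fixes (possibly different classes): keep the first
    df = df.sort_values(["animal_id", "time"], kind="mergesort")
    dup_time = df.duplicated(subset=["animal_id", "time"])
    n_dup_time = int(dup_time.sum())
    if n_dup_time:
        logger.info("dropping %d duplicate-time fixes (first kept)", n_dup_time)
    df = df[~dup_time]
    rows_kept = len(df)
    logger.info(
        "read %s: rows_in=%d rows_kept=%d rows_dropped=%d",
        path, rows_in, rows_kept, rows_in - rows_kept,
    )
    assert rows_in == rows_kept + n_exact + n_dup_time

    tracks: list[Track] = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        if len(sub) < 2:
            logger.warning("animal %s: <2 usable rows, skipped", animal_id)
            continue
        tracks.append(Track(str(animal_id), sub.reset_index(drop=True), species=species))
    return tracks


def write_argos_observations(tracks: Iterable[Track], path) -> None:
    """Write tracks back to the default CSV schema (inverse of the reader)."""
    frames = []
    for tr in tracks:
        out = pd.DataFrame(
            {
                "id": tr.animal_id,
                "date": tr.data["time"].dt.strftime("%Y-%m-%dT%H:%M:%S+00:00"),
                "lc": tr.data["loc_class"],
                "lon": tr.data["lon"].map(lambda v: format(v, ".6f")),
                "lat": tr.data["lat"].map(lambda v: format(v, ".6f")),
            }
        )
        frames.append(out)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def build_time_grid(track: Track, dt_hours: float) -> RegularGrid:
    """Construct the regular state grid covering a track.

    ``t0`` is the first observation time; ``n_states = ceil(span/dt) + 1``.
    Each observation maps to ``(t, j)`` with ``time = t0 + (t + j) * dt``.
    """
    if dt_hours <= 0:
        raise ParameterError(f"dt_hours must be > 0, got {dt_hours}")
    times = track.data["time"]
    t0 = times.iloc[0]
    span_h = (times.iloc[-1] - t0).total_seconds() / 3600.0
    n_states = int(math.ceil(span_h / dt_hours - 1e-9)) + 1
    frac = (times - t0).dt.total_seconds().to_numpy() / (3600.0 * dt_hours)
    interval = np.floor(frac + 1e-12).astype(np.int64)
    weight = frac - interval
    # observations landing exactly on a node keep j == 0
    weight[np.abs(weight) < 1e-9] = 0.0
    interval = np.minimum(interval, n_states - 1)
    return RegularGrid(t0=t0, dt_hours=float(dt_hours), n_states=n_states,
                       obs_interval=interval, obs_weight=weight)


# ---------------------------------------------------------------------------
# State-series output

STATE_COLUMNS = ["time", "lon", "lat", "lon_lo", "lon_hi", "lat_lo", "lat_hi",
                 "b_mean", "behaviour"]


def write_states(states, path, format: str = "csv") -> None:
    """Write a classified state series (or a list of them) to CSV or GeoJSON.

    One record per grid time: posterior-median position, 95% credible bounds,
    behaviour mean ``b`` and class label. GeoJSON coordinates are (lon, lat).
    """
    from .ssm import StateSeries  # local import to avoid a cycle

    if isinstance(states, StateSeries):
        states = [states]
    states = list(states)
    if not states or all(len(s.frame) == 0 for s in states):
        raise ParameterError("no states to write")
    if format == "csv":
        frames = []
        for s in states:
            out = s.frame.copy()
            out.insert(0, "animal_id", s.animal_id)
            out["time"] = out["time"].dt.strftime("%Y-%m-%dT%H:%M:%S+00:00")
            frames.append(out)
        pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.6f")
    elif format == "geojson":
        feats = []
        for s in states:
            for row in s.frame.itertuples(index=False):
                feats.append(
                    {
                        "type": "Feature",
                        "geometry": {"type": "Point",
                                     "coordinates": [round(row.lon, 6), round(row.lat, 6)]},
                        "properties": {
                            "animal_id": s.animal_id,
                            "time": row.time.isoformat(),
                            "b_mean": round(row.b_mean, 6),
                            "behaviour": row.behaviour,
                            "lon_ci": [round(row.lon_lo, 6), round(row.lon_hi, 6)],
                            "lat_ci": [round(row.lat_lo, 6), round(row.lat_hi, 6)],
                        },
                    }
                )
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)
    else:
        raise ParameterError(f"unknown format {format!r}; use 'csv' or 'geojson'")


def read_states(path) -> list:
    """Read back a CSV written by :func:`write_states`."""
    from .ssm import StateSeries

    df = pd.read_csv(path, parse_dates=["time"])
    df["time"] = pd.to_datetime(df["time"], utc=True)
    out = []
    for animal_id, sub in df.groupby("animal_id", sort=True):
        sub = sub.drop(columns=["animal_id"]).reset_index(drop=True)
        dt_h = np.median(np.diff(sub["time"].to_numpy()).astype("timedelta64[s]").astype(float)) / 3600.0
        out.append(StateSeries(animal_id=str(animal_id), dt_hours=float(dt_h), frame=sub))
    return out
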