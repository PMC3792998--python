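"""Synthetic two-regime whale tracks with Argos-like observation error.

The generator runs the DCRW process model forwards: behaviours evolve by the
two-state Markov chain, displacements by the switching first-difference
recursion, and positions by cumulative summation from the start point.
Observations are then drawn from a homogeneous Poisson process in time, each
fix receiving an Argos location class from a frequency table and independent
scaled-t noise in lon and lat with that class's parameters.

Presets echo the two telemetry regimes of the source study's Azores
deployments: ``fin_2009_2012`` (2 h grid, ~12 fixes/day, 30-day tracks,
start 38N 28W) and ``blue_2009_2011`` (4 h grid, ~7 fixes/day, 45-day
tracks).  Transiting is directed and persistent (gamma 0.9, turn angle 0);
ARS is slow with frequent reversals (gamma 0.3, turn angle pi).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .ssm import ArgosErrorModel, MovementParams, StateSeries, rotation_matrix
from .track_io import Track

logger = logging.getLogger("whaletrack")

DEFAULT_CLASS_FREQS = {"3": 0.08, "2": 0.12, "1": 0.20, "0": 0.15, "A": 0.20, "B": 0.25}


def default_movement_params() -> MovementParams:
    return MovementParams(
        theta=np.array([0.0, np.pi]),
        gamma=np.array([0.9, 0.3]),
        Sigma=np.array([[0.03 ** 2, 0.0], [0.0, 0.03 ** 2]]),
        alpha=np.array([0.95, 0.10]),
    )


@dataclass
class SimulationConfig:
    """Stated world for a synthetic population of tracks."""

    n_animals: int = 8
    duration_days: float = 30.0
    dt_hours: float = 2.0
    params: MovementParams = field(default_factory=default_movement_params)
    error_model: ArgosErrorModel | None = None
    fixes_per_day: float = 12.0
    class_freqs: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_FREQS))
    start_lonlat: tuple[float, float] = (-28.0, 38.0)
    start_date: str = "2010-04-15"
    species: str = "fin"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 1 or self.duration_days <= 0 or self.dt_hours <= 0:
            raise ParameterError("n_animals, duration_days and dt_hours must be positive")
        if self.fixes_per_day <= 0:
            raise ParameterError("fixes_per_day must be > 0")
        total = sum(self.class_freqs.values())
        if abs(total - 1.0) > 1e-6:
            raise ParameterError(f"class frequencies must sum to 1, got {total}")
        if self.seed is None:
            raise ParameterError("seed is mandatory")
        if self.error_model is None:
            self.error_model = ArgosErrorModel.default()


PRESETS = {
    "fin_2009_2012": dict(n_animals=8, duration_days=30.0, dt_hours=2.0,
                          fixes_per_day=12.0, species="fin"),
    "blue_2009_2011": dict(n_animals=3, duration_days=45.0, dt_hours=4.0,
                           fixes_per_day=7.0, species="blue"),
}


def preset_config(name: str, seed: int = 0, **overrides) -> SimulationConfig:
    if name not in PRESETS:
        raise ParameterError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    kw = dict(PRESETS[name])
    kw.update(overrides)
    return SimulationConfig(seed=seed, **kw)


@dataclass
class TrueTrack:
    """Noise-free grid-time positions and true behaviours for one animal.

    ``data`` columns: time (UTC), lon, lat, b (behaviour of the displacement
    ending at that grid time; entry 0 mirrors entry 1).
    """

    animal_id: str
    dt_hours: float
    data: pd.DataFrame


def simulate_tracks(config: SimulationConfig) -> list[TrueTrack]:
    """Generate true state series by running the DCRW model forwards."""
    p = config.params
    if np.linalg.eigvalsh(p.Sigma).min() <= 0:
        raise ParameterError("degenerate process covariance")
    chol = np.linalg.cholesky(p.Sigma)
    A = [p.gamma[0] * rotation_matrix(p.theta[0]),
         p.gamma[1] * rotation_matrix(p.theta[1])]
    # stationary probability of transiting for the initial behaviour
    pi1 = p.alpha[1] / (1.0 - p.alpha[0] + p.alpha[1])

    n_steps = int(round(config.duration_days * 24.0 / config.dt_hours))
    t0 = pd.Timestamp(config.start_date, tz="UTC")
    times = t0 + pd.to_timedelta(np.arange(n_steps + 1) * config.dt_hours, unit="h")

    root = np.random.SeedSequence(config.seed)
    out = []
    for k, ss in enumerate(root.spawn(config.n_animals)):
        rng = np.random.default_rng(ss)
        b = np.zeros(n_steps + 1, dtype=np.int8)
        b[1] = 1 if rng.uniform() < pi1 else 2
        for t in range(2, n_steps + 1):
            p_stay1 = p.alpha[0] if b[t - 1] == 1 else p.alpha[1]
            b[t] = 1 if rng.uniform() < p_stay1 else 2
        b[0] = b[1]

        d = np.zeros((n_steps + 1, 2))
        # first displacement at the stationary magnitude of its regime
        g0 = p.gamma[b[1] - 1]
        d[1] = chol @ rng.standard_normal(2) / np.sqrt(max(1.0 - g0 ** 2, 1e-6))
        noise = (chol @ rng.standard_normal((2, n_steps + 1))).T
        for t in range(2, n_steps + 1):
            d[t] = A[b[t] - 1] @ d[t - 1] + noise[t]
        x = np.empty((n_steps + 1, 2))
        x[0] = config.start_lonlat
        np.cumsum(d[1:], axis=0, out=x[1:])
        x[1:] += x[0]

        data = pd.DataFrame({"time": times, "lon": x[:, 0], "lat": x[:, 1], "b": b})
        out.append(TrueTrack(animal_id=f"sim{k + 1:02d}",
                             dt_hours=config.dt_hours, data=data))
    return out


def observe_tracks(truths: list[TrueTrack], config: SimulationConfig) -> list[Track]:
    """Argos-style observation of true tracks.

    Observation times come from a homogeneous Poisson process over the track
    span; each fix draws a location class from the frequency table and adds
    independent scaled-t noise in lon/lat with that class's (nu, tau).  The
    true path is interpolated linearly to the observation times.  Times are
    rounded to whole seconds.  Fully reproducible given the config seed.
    """
    em = config.error_model
    classes = sorted(config.class_freqs)
    freqs = np.array([config.class_freqs[c] for c in classes])
    root = np.random.SeedSequence((config.seed, 1))
    tracks = []
    for truth, ss in zip(truths, root.spawn(len(truths))):
        rng = np.random.default_rng(ss)
        span_h = (len(truth.data) - 1) * truth.dt_hours
        rate = config.fixes_per_day / 24.0
        for attempt in range(20):
            n = rng.poisson(rate * span_h)
            if n >= 2:
                break
        else:
            logger.warning("%s: Poisson draw kept returning <2 fixes", truth.animal_id)
            n = 2
        t_h = np.sort(np.round(rng.uniform(0.0, span_h, size=n) * 3600.0) / 3600.0)
        grid_h = np.arange(len(truth.data)) * truth.dt_hours
        lon = np.interp(t_h, grid_h, truth.data["lon"].to_numpy())
        lat = np.interp(t_h, grid_h, truth.data["lat"].to_numpy())
        ci = rng.choice(len(classes), size=n, p=freqs)
        nu = np.empty(n)
        tau = np.empty((n, 2))
        for i, c in enumerate(ci):
            nu[i], tau[i, 0], tau[i, 1] = em.params_for(classes[c])
        lon = lon + rng.standard_t(nu) * tau[:, 0]
        lat = lat + rng.standard_t(nu) * tau[:, 1]
        t0 = truth.data["time"].iloc[0]
        data = pd.DataFrame(
            {
                "time": t0 + pd.to_timedelta(np.round(t_h * 3600.0), unit="s"),
                "lon": lon,
                "lat": np.clip(lat, -89.9, 89.9),
                "loc_class": [classes[c] for c in ci],
            }
        )
        data = data.drop_duplicates(subset="time").reset_index(drop=True)
        tracks.append(Track(animal_id=truth.animal_id, data=data,
                            species=config.species, tag_date=t0.normalize()))
    return tracks


def decode_accuracy(truth: TrueTrack, states: StateSeries,
                    exclude_uncertain: bool = True) -> float:
    """Fraction of grid times whose classified behaviour matches the truth.

    Fitted grid times are matched to the nearest true grid time (within half
    a step); "uncertain" classifications are excluded by default.
    """
    tf = states.frame
    true_times = (pd.DatetimeIndex(truth.data["time"]).tz_convert(None)
                  .to_numpy().astype("datetime64[s]").astype(np.int64))
    fit_times = (pd.DatetimeIndex(tf["time"]).tz_convert(None)
                 .to_numpy().astype("datetime64[s]").astype(np.int64))
    pos = np.searchsorted(true_times, fit_times)
    pos = np.clip(pos, 0, len(true_times) - 1)
    prev = np.clip(pos - 1, 0, len(true_times) - 1)
    use_prev = np.abs(fit_times - true_times[prev]) <= np.abs(fit_times - true_times[pos])
    nearest = np.where(use_prev, prev, pos)
    ok_dist = np.abs(fit_times - true_times[nearest]) <= truth.dt_hours * 1800.0
    true_b = truth.data["b"].to_numpy()[nearest]
    fit_cls = tf["behaviour"].to_numpy()
    mask = ok_dist
    if exclude_uncertain:
        mask = mask & (fit_cls != "uncertain")
    if mask.sum() == 0:
        raise ParameterError("no comparable classified states")
    fit_b = np.where(fit_cls == "transiting", 1, 2)
    return float(np.mean(fit_b[mask] == true_b[mask]))
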