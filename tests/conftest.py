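import numpy as np
import pandas as pd
import pytest

import whaletrack as wt

LABEL_TO_BMEAN = {"transiting": 1.0, "ARS": 2.0, "uncertain": 1.5}


def make_states(lons, lats, behaviours=None, dt_hours=2.0,
                t0="2010-05-01T00:00:00Z", animal_id="w1", b_mean=None):
    """Hand-build a classified StateSeries for unit tests."""
    lons = np.asarray(lons, dtype=float)
    lats = np.asarray(lats, dtype=float)
    n = len(lons)
    if behaviours is None:
        behaviours = ["transiting"] * n
    if b_mean is None:
        b_mean = [LABEL_TO_BMEAN[b] for b in behaviours]
    times = pd.Timestamp(t0) + pd.to_timedelta(np.arange(n) * dt_hours, unit="h")
    frame = pd.DataFrame(
        {
            "time": times,
            "lon": lons, "lat": lats,
            "lon_lo": lons, "lon_hi": lons,
            "lat_lo": lats, "lat_hi": lats,
            "b_mean": np.asarray(b_mean, dtype=float),
            "behaviour": list(behaviours),
        }
    )
    return wt.StateSeries(animal_id=animal_id, dt_hours=dt_hours, frame=frame)


@pytest.fixture(scope="session")
def error_model():
    return wt.ArgosErrorModel.default()


@pytest.fixture(scope="session")
def azores_cohort():
    """Published per-animal residency summaries for the 2009-2012 Azores
    fin/blue whale tagging cohort: residence time in the archipelago (days)
    and percent of track time classified as area-restricted search.  The two
    fin whales tracked for only 2-3 days are flagged for exclusion from
    cohort means."""
    fin = pd.DataFrame(
        [
            ("80716", 6, 8.2), ("80713", 3, 100.0), ("80702", 13, 92.9),
            ("80707", 17, 98.4), ("80704", 6, 22.2), ("89969", 4, 50.0),
            ("80703", 2, 100.0), ("80715", 3, 39.1), ("60787", 11, 59.3),
            ("61878", 18, 13.8), ("61699", 22, 78.5), ("60784", 12, 90.2),
        ],
        columns=["animal_id", "residence_days", "ars_percent"],
    )
    blue = pd.DataFrame(
        [("80709", 60, 73.5), ("80700", 45, 82.5)],
        columns=["animal_id", "residence_days", "ars_percent"],
    )
    return {"fin": fin, "blue": blue, "short_track_ids": ["80713", "80703"]}


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated population shared by cheap tests."""
    cfg = wt.preset_config("fin_2009_2012", seed=3, n_animals=2, duration_days=8.0)
    truths = wt.simulate_tracks(cfg)
    tracks = wt.observe_tracks(truths, cfg)
    return cfg, truths, tracks


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A quick 2-chain fit of the small population (scaled-down MCMC)."""
    _, _, tracks = small_sim
    return wt.fit_hssm(
        tracks, 2.0,
        mcmc={"n_chains": 2, "n_iter": 600, "burn_in": 400, "thin": 2},
        seed=11,
    )
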