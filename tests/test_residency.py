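import numpy as np
import pandas as pd
import pytest

import whaletrack as wt
from conftest import make_states

KM_PER_DEG = 111.19492664455873  # pi/180 * 6371


def make_kinematics(speeds, dt_hours=2.0, behaviours=None, animal_id="w1",
                    t0="2010-05-01T00:00:00Z"):
    """Hand-build a KinematicSeries with prescribed interval speeds."""
    n = len(speeds)
    if behaviours is None:
        behaviours = ["transiting"] * n
    t_start = pd.Timestamp(t0) + pd.to_timedelta(np.arange(n) * dt_hours, unit="h")
    frame = pd.DataFrame(
        {
            "t_start": t_start,
            "t_end": t_start + pd.Timedelta(hours=dt_hours),
            "distance_km": np.asarray(speeds) * dt_hours,
            "elapsed_h": dt_hours,
            "speed_kmh": np.asarray(speeds, dtype=float),
            "heading_deg": 90.0,
            "behaviour": list(behaviours),
        }
    )
    return wt.KinematicSeries(animal_id=animal_id, frame=frame,
                              turn_angles=np.zeros(max(n - 1, 0)))


def hand_product_limit(durations, events):
    """Independent hand product-limit oracle (no lifelines)."""
    order = np.argsort(durations, kind="mergesort")
    durations = np.asarray(durations, dtype=float)[order]
    events = np.asarray(events, dtype=bool)[order]
    s = 1.0
    out = {}
    at_risk = len(durations)
    for t in np.unique(durations[events]):
        d = int(np.sum((durations == t) & events))
        n = int(np.sum(durations >= t))  # events precede censorings at ties
        s *= (n - d) / n
        out[float(t)] = s
    return out


class TestMedianArsSpeed:
    def test_odd_count(self):
        k = make_kinematics([1, 2, 3], behaviours=["ARS"] * 3)
        assert wt.median_ars_speed([k]) == 2.0

    def test_even_count_mean_of_middle(self):
        k = make_kinematics([1, 2, 3, 4], behaviours=["ARS"] * 4)
        assert wt.median_ars_speed([k]) == 2.5

    def test_pooling_equals_concatenation(self):
        k1 = make_kinematics([1, 5], behaviours=["ARS"] * 2)
        k2 = make_kinematics([2, 3, 9], behaviours=["ARS"] * 3, animal_id="w2")
        assert wt.median_ars_speed([k1, k2]) == np.median([1, 5, 2, 3, 9])

    def test_transiting_intervals_ignored(self):
        k = make_kinematics([1, 2, 100], behaviours=["ARS", "ARS", "transiting"])
        assert wt.median_ars_speed([k]) == 1.5

    def test_no_ars_errors(self):
        k = make_kinematics([1, 2, 3])
        with pytest.raises(wt.AnalysisError, match="ARS"):
            wt.median_ars_speed([k])


class TestDetectDeparture:
    def test_speed_equal_to_threshold_is_censored(self):
        # strict inequality: sustained speed == threshold never departs
        k = make_kinematics([2.0] * 60)
        res = wt.detect_departure(k, threshold=2.0)
        assert res.censored and res.departure_time is None

    def test_slow_then_fast_departs_at_transition(self):
        # 5 days at 1 km/h then 3 days at 6 km/h, threshold 2 km/h
        k = make_kinematics([1.0] * 60 + [6.0] * 36)
        res = wt.detect_departure(k, threshold=2.0)
        expected = pd.Timestamp("2010-05-01T00:00:00Z") + pd.Timedelta(hours=120)
        assert not res.censored
        assert res.departure_time == expected

    def test_47h_burst_does_not_depart(self):
        k = make_kinematics([1.0] * 10 + [6.0] * 23 + [1.0] * 30, dt_hours=2.0)
        res = wt.detect_departure(k, threshold=2.0)  # 23 * 2 h = 46 h < 48 h
        assert res.censored

    def test_exactly_48h_run_departs(self):
        k = make_kinematics([1.0] * 10 + [6.0] * 24 + [1.0] * 5, dt_hours=2.0)
        res = wt.detect_departure(k, threshold=2.0)
        assert not res.censored

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(21)
        speeds = rng.gamma(2.0, 2.0, 300)
        k = make_kinematics(speeds)
        prev_time = None
        for thr in (0.5, 1.0, 2.0, 4.0):
            res = wt.detect_departure(k, threshold=thr)
            if res.censored:
                continue
            if prev_time is not None:
                assert res.departure_time >= prev_time
            prev_time = res.departure_time

    def test_empty_series_rejected(self):
        with pytest.raises(wt.ParameterError):
            wt.detect_departure(make_kinematics([]), threshold=1.0)

    def test_residency_record_censoring(self):
        k = make_kinematics([1.0] * 120)  # 10 days, never fast
        rec = wt.residency_record(k, threshold=2.0)
        assert rec.censored
        assert rec.residence_days == pytest.approx(rec.track_days)


def rec(animal_id, residence, censored=False, track=None):
    return wt.ResidencyRecord(
        animal_id=animal_id,
        tagging_date=pd.Timestamp("2010-05-01", tz="UTC"),
        residence_days=float(residence),
        censored=censored,
        track_days=float(track if track is not None else residence),
    )


class TestKaplanMeier:
    def test_three_events_no_censoring(self):
        km = wt.kaplan_meier([rec("a", 1), rec("b", 2), rec("c", 3)])
        surv = dict(zip(km.times, km.survival))
        assert surv[1.0] == pytest.approx(2 / 3)
        assert surv[2.0] == pytest.approx(1 / 3)
        assert surv[3.0] == pytest.approx(0.0)
        assert km.median == 2.0

    def test_all_censored(self):
        km = wt.kaplan_meier([rec("a", 5, censored=True), rec("b", 8, censored=True)])
        assert np.all(km.survival == 1.0)
        assert np.isnan(km.median)

    def test_mixed_toy_with_censoring(self):
        # events {3,4,6,6,13,17}, censorings {11,12,18,22}
        events = [rec(f"e{i}", t) for i, t in enumerate([3, 4, 6, 6, 13, 17])]
        cens = [rec(f"c{i}", t, censored=True) for i, t in enumerate([11, 12, 18, 22])]
        km = wt.kaplan_meier(events + cens)
        surv = dict(zip(km.times, km.survival))
        assert surv[6.0] == pytest.approx(0.60)
        assert surv[13.0] == pytest.approx(0.45)
        assert km.median == 13.0
        assert km.n_events == 6 and km.n_censored == 4

    def test_matches_hand_product_limit(self):
        rng = np.random.default_rng(31)
        durations = rng.integers(1, 20, 15).astype(float)
        censored = rng.uniform(size=15) < 0.3
        records = [rec(f"w{i}", d, censored=bool(c))
                   for i, (d, c) in enumerate(zip(durations, censored))]
        km = wt.kaplan_meier(records)
        oracle = hand_product_limit(durations, ~censored)
        got = dict(zip(km.times, km.survival))
        for t, s in oracle.items():
            assert got[t] == pytest.approx(s, abs=1e-12)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(32)
        durations = rng.integers(1, 15, 12).astype(float)
        records = [rec(f"w{i}", d) for i, d in enumerate(durations)]
        km = wt.kaplan_meier(records)
        for t, s in zip(km.times, km.survival):
            assert s == pytest.approx(np.mean(durations > t), abs=1e-12)

    def test_negative_duration_rejected(self):
        with pytest.raises(wt.ParameterError):
            rec("a", -1)

    def test_quartiles_definition(self):
        km = wt.kaplan_meier([rec(f"w{i}", t) for i, t in enumerate(range(1, 9))])
        # S(t) <= 0.75 first at t=2 (S=6/8), <= 0.5 at t=4, <= 0.25 at t=6
        assert km.lower_quartile == 2.0
        assert km.median == 4.0
        assert km.upper_quartile == 6.0


class TestLogisticDeparture:
    def test_symmetric_departures_give_midpoint(self):
        # departure times mirrored around DST 10 (half-integers so the daily
        # presence fractions are exactly symmetric about (10, 0.5))
        records = [rec(f"w{i}", t, track=19)
                   for i, t in enumerate([5.5, 7.5, 9.5, 10.5, 12.5, 14.5])]
        out = wt.logistic_departure_curve(records)
        assert out["dst_at_half"] == pytest.approx(10.0, abs=1e-6)
        assert out["slope"] > 0

    def test_all_departed_day_one_is_separation(self):
        records = [rec(f"w{i}", 0.5, track=10) for i in range(4)]
        with pytest.raises(wt.AnalysisError, match="separation"):
            wt.logistic_departure_curve(records)

    def test_irls_matches_grid_search_oracle(self):
        # brute-force refinement of the binomial log-likelihood surface
        records = [rec(f"w{i}", t, track=5)
                   for i, t in enumerate([1.5, 2.5, 2.5, 3.5, 4.5])]
        out = wt.logistic_departure_curve(records)

        days = np.arange(1, 6, dtype=float)
        n_dep = np.array([sum(1 for t in [1.5, 2.5, 2.5, 3.5, 4.5] if t < d)
                          for d in days], dtype=float)
        n_tot = np.full(5, 5.0)

        def loglik(a, b):
            p = 1.0 / (1.0 + np.exp(-(a + b * days)))
            p = np.clip(p, 1e-12, 1 - 1e-12)
            return np.sum(n_dep * np.log(p) + (n_tot - n_dep) * np.log(1 - p))

        a_lo, a_hi, b_lo, b_hi = -15.0, 5.0, -1.0, 5.0
        for _ in range(12):
            aa = np.linspace(a_lo, a_hi, 41)
            bb = np.linspace(b_lo, b_hi, 41)
            ll = np.array([[loglik(a, b) for b in bb] for a in aa])
            i, j = np.unravel_index(np.argmax(ll), ll.shape)
            da, db = (a_hi - a_lo) / 40, (b_hi - b_lo) / 40
            a_lo, a_hi = aa[i] - 2 * da, aa[i] + 2 * da
            b_lo, b_hi = bb[j] - 2 * db, bb[j] + 2 * db
        a_star, b_star = (a_lo + a_hi) / 2, (b_lo + b_hi) / 2
        assert out["intercept"] == pytest.approx(a_star, abs=1e-4)
        assert out["slope"] == pytest.approx(b_star, abs=1e-4)


class TestMCP:
    def test_right_triangle_area(self):
        # 4 km x 3 km right triangle near the equator -> 6 km^2
        pts = [(0.0, 0.0), (4.0 / KM_PER_DEG, 0.0), (0.0, 3.0 / KM_PER_DEG)]
        assert wt.mcp_area(pts) == pytest.approx(6.0, rel=1e-3)

    def test_interior_point_does_not_change_hull(self):
        pts = [(0.0, 0.0), (0.1, 0.0), (0.1, 0.1), (0.0, 0.1)]
        centroid = (0.05, 0.05)
        assert wt.mcp_area(pts + [centroid]) == pytest.approx(wt.mcp_area(pts))

    def test_permutation_invariance(self):
        rng = np.random.default_rng(41)
        pts = rng.uniform(-0.2, 0.2, (12, 2)) + np.array([-28.0, 38.0])
        a1 = wt.mcp_area(pts)
        a2 = wt.mcp_area(pts[rng.permutation(12)])
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_small_equatorial_square(self):
        pts = [(0.0, 0.0), (0.1, 0.0), (0.1, 0.1), (0.0, 0.1)]
        assert wt.mcp_area(pts) == pytest.approx((KM_PER_DEG * 0.1) ** 2, rel=5e-3)

    def test_matches_shoelace_on_planar_toy(self):
        # km-scale offsets near the equator: projection is effectively planar
        rng = np.random.default_rng(42)
        xy_km = rng.uniform(0, 10, (9, 2))
        pts = xy_km / KM_PER_DEG
        from scipy.spatial import ConvexHull

        hull = ConvexHull(xy_km)
        v = xy_km[hull.vertices]
        shoelace = 0.5 * abs(
            np.sum(v[:, 0] * np.roll(v[:, 1], -1) - np.roll(v[:, 0], -1) * v[:, 1]))
        assert wt.mcp_area(pts) == pytest.approx(shoelace, rel=1e-4)

    def test_collinear_degenerate(self):
        # along a meridian the projected points stay exactly collinear
        verts, area, degen = wt.mcp_polygon([(0.0, 0.0), (0.0, 0.1), (0.0, 0.2)])
        assert area == 0.0 and degen

    def test_duplicate_points_degenerate(self):
        _, area, degen = wt.mcp_polygon([(0.0, 0.0), (0.0, 0.0), (0.1, 0.1)])
        assert area == 0.0 and degen

    def test_too_few_points_rejected(self):
        with pytest.raises(wt.ParameterError):
            wt.mcp_area([(0.0, 0.0), (1.0, 1.0)])


class TestArsAreas:
    def test_run_of_three_detected(self):
        s = make_states(np.linspace(-28, -27.6, 5), np.linspace(38, 38.4, 5),
                        ["transiting", "ARS", "ARS", "ARS", "transiting"])
        areas = wt.extract_ars_areas(s)
        assert len(areas) == 1
        assert list(areas[0].indices) == [1, 2, 3]

    def test_uncertain_breaks_runs(self):
        s = make_states(np.linspace(-28, -27.6, 5), np.linspace(38, 38.4, 5),
                        ["ARS", "ARS", "uncertain", "ARS", "ARS"])
        assert wt.extract_ars_areas(s) == []

    def test_all_ars_single_area(self):
        s = make_states(np.cumsum(np.full(10, 0.05)) - 28.0,
                        np.cumsum(np.full(10, 0.03)) + 38.0,
                        ["ARS"] * 10, dt_hours=2.0)
        areas = wt.extract_ars_areas(s)
        assert len(areas) == 1
        assert areas[0].duration_h == pytest.approx(9 * 2.0)

    def test_runs_disjoint_and_maximal(self):
        rng = np.random.default_rng(51)
        labels = rng.choice(["transiting", "ARS", "uncertain"], 60,
                            p=[0.35, 0.5, 0.15])
        s = make_states(np.cumsum(rng.normal(0.02, 0.02, 60)) - 28.0,
                        np.cumsum(rng.normal(0.01, 0.02, 60)) + 38.0,
                        list(labels))
        areas = wt.extract_ars_areas(s)
        used = set()
        for a in areas:
            assert len(a.indices) >= 3
            assert all(labels[i] == "ARS" for i in a.indices)
            lo, hi = a.indices[0] - 1, a.indices[-1] + 1
            if lo >= 0:
                assert labels[lo] != "ARS"  # maximal on the left
            if hi < 60:
                assert labels[hi] != "ARS"  # maximal on the right
            overlap = used & set(a.indices.tolist())
            assert not overlap
            used |= set(a.indices.tolist())


class TestTimeBudget:
    def test_all_ars(self):
        s = make_states(np.linspace(-28, -27, 6), np.full(6, 38.0), ["ARS"] * 6)
        out = wt.behaviour_time_budget(s)
        assert out["ARS"].iloc[0] == 1.0

    def test_alternating_half_half(self):
        labels = ["transiting", "ARS"] * 4 + ["transiting"]
        s = make_states(np.linspace(-28, -27, 9), np.full(9, 38.0), labels)
        out = wt.behaviour_time_budget(s)
        assert out["transiting"].iloc[0] == pytest.approx(0.5)
        assert out["ARS"].iloc[0] == pytest.approx(0.5)
        assert out["uncertain"].iloc[0] == 0.0

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(61)
        labels = list(rng.choice(["transiting", "ARS", "uncertain"], 50))
        s = make_states(np.linspace(-28, -26, 50), np.full(50, 38.0), labels)
        out = wt.behaviour_time_budget(s, grouping="day")
        sums = out[["transiting", "ARS", "uncertain"]].sum(axis=1)
        np.testing.assert_allclose(sums, 1.0)
        assert out["n_intervals"].sum() == 49

    def test_monthly_grouping_partitions(self):
        n = 30 * 24 // 2 * 3  # three months at 2 h
        labels = ["transiting"] * n
        s = make_states(np.linspace(-28, -20, n), np.full(n, 38.0), labels,
                        t0="2010-03-15T00:00:00Z")
        out = wt.behaviour_time_budget(s, grouping="month")
        assert out["n_intervals"].sum() == n - 1
        assert len(out) >= 3


class TestSummarize:
    def test_mean_row_reproduced(self, azores_cohort):
        out = wt.summarize_residency(azores_cohort["fin"],
                                     exclusions=azores_cohort["short_track_ids"])
        assert out == {"n": 10, "mean_residence_days": 11.2, "mean_ars_percent": 55.3}

    def test_all_excluded_errors(self, azores_cohort):
        ids = list(azores_cohort["blue"]["animal_id"])
        with pytest.raises(wt.AnalysisError):
            wt.summarize_residency(azores_cohort["blue"], exclusions=ids)
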