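"""Wind events, aggregations, lags, and the Poisson GLM, checked against
brute-force oracles and hand computations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import plumelag as pl
from plumelag.errors import DegenerateDataError, ValidationError


def wind_table(speeds, start="2017-01-01"):
    idx = pd.date_range(start, periods=len(speeds), freq="D")
    return pd.DataFrame({"date": idx, "speed": np.asarray(speeds, float), "direction": 270.0})


def brute_force_events(exceed, min_days=2):
    """All maximal runs of True of length >= min_days, by enumeration."""
    runs = []
    for start, grp in itertools.groupby(enumerate(exceed), key=lambda t: t[1]):
        grp = list(grp)
        if start and len(grp) >= min_days:
            runs.append((grp[0][0], grp[-1][0]))
    return runs


class TestWindEvents:
    def test_definition_example(self):
        events = pl.detect_wind_events(wind_table([6, 7, 3, 6, 4]), 5.5)
        assert len(events) == 1
        assert events[0].duration_days == 2
        assert events[0].start_date == pd.Timestamp("2017-01-01")
        assert events[0].peak_speed == 7.0

    def test_no_exceedance_no_events(self):
        assert pl.detect_wind_events(wind_table([5.5, 5.0, 4.0]), 5.5) == []

    def test_strict_exceedance(self):
        # equality does not count as exceeding
        assert pl.detect_wind_events(wind_table([5.5, 5.5, 5.5]), 5.5) == []

    def test_record_gap_breaks_runs(self):
        w = wind_table([6, 6], start="2017-01-01")
        w2 = wind_table([6, 6], start="2017-01-04")
        events = pl.detect_wind_events(pd.concat([w, w2], ignore_index=True), 5.5)
        assert len(events) == 2

    @given(st.integers(0, 4095))
    @settings(max_examples=80, deadline=None, derandomize=True)
    def test_matches_run_enumeration_oracle(self, bits):
        exceed = [(bits >> i) & 1 == 1 for i in range(12)]
        speeds = [7.0 if e else 3.0 for e in exceed]
        events = pl.detect_wind_events(wind_table(speeds), 5.5)
        expected = brute_force_events(exceed)
        got = [
            ((e.start_date - pd.Timestamp("2017-01-01")).days, (e.end_date - pd.Timestamp("2017-01-01")).days)
            for e in events
        ]
        assert got == expected

    def test_exceedance_nested_in_threshold(self):
        rng = np.random.default_rng(0)
        speeds = rng.uniform(0, 12, 200)
        w = wind_table(speeds)
        days_hi = {d for e in pl.detect_wind_events(w, 8.0) for d in pd.date_range(e.start_date, e.end_date)}
        days_lo = {d for e in pl.detect_wind_events(w, 4.0) for d in pd.date_range(e.start_date, e.end_date)}
        assert days_hi <= days_lo


class TestSummarizeEvents:
    def test_gaps_and_durations(self, config):
        speeds = [3.0] * 40
        speeds[0:2] = [7, 7]  # days 0-1
        speeds[9:12] = [7, 7, 7]  # days 9-11
        events = pl.detect_wind_events(wind_table(speeds, start="2016-11-01"), 5.5)
        s = pl.summarize_events(events, config)
        assert s["duration_range"] == (2, 3)
        assert s["gap_mean"] == 8.0
        assert s["per_season_counts"] == {2017: 2}

    def test_single_event_has_no_gap_stats(self, config):
        events = pl.detect_wind_events(wind_table([7, 7, 3], start="2016-11-01"), 5.5)
        s = pl.summarize_events(events, config)
        assert np.isnan(s["gap_mean"])

    def test_generator_event_rate_recovered(self, config):
        counts = []
        for seed in range(12):
            w = pl.gen_wind(pl.WindSimParams(), seed=seed)
            events = pl.detect_wind_events(w, 5.5)
            per = pl.summarize_events(events, config)["per_season_counts"]
            counts += [c for lab, c in per.items() if 2010 <= lab <= 2019]
        counts = np.asarray(counts, float)
        se = counts.std(ddof=1) / np.sqrt(len(counts))
        assert abs(counts.mean() - 18.0) <= 3 * se


class TestHaversine:
    def test_identical_points(self):
        assert pl.haversine_km((-40.0, 173.0), (-40.0, 173.0)) == 0.0

    def test_one_degree_of_latitude(self):
        assert pl.haversine_km((0, 0), (1, 0)) == pytest.approx(np.pi / 180 * 6371, abs=1e-6)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a = (rng.uniform(-80, 80), rng.uniform(-180, 180))
            b = (rng.uniform(-80, 80), rng.uniform(-180, 180))
            assert pl.haversine_km(a, b) == pytest.approx(pl.haversine_km(b, a), abs=1e-12)

    def test_invalid_latitude(self):
        with pytest.raises(ValidationError):
            pl.haversine_km((95, 0), (0, 0))


def sightings_table(rows):
    return pd.DataFrame(rows, columns=["id", "date", "lat", "lon", "count"]).assign(
        date=lambda d: pd.to_datetime(d["date"])
    )


def brute_components(s, window_days=7, radius_km=50.0):
    """Connected components by all-pairs linkage + transitive closure."""
    n = len(s)
    adj = [
        [
            abs((s["date"].iloc[i] - s["date"].iloc[j]).days) <= window_days
            and pl.haversine_km(
                (s["lat"].iloc[i], s["lon"].iloc[i]), (s["lat"].iloc[j], s["lon"].iloc[j])
            )
            <= radius_km
            for j in range(n)
        ]
        for i in range(n)
    ]
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for i in range(n):
            for j in range(n):
                if adj[i][j] and labels[j] != labels[i]:
                    lo = min(labels[i], labels[j])
                    labels[i] = labels[j] = lo
                    changed = True
    groups = {}
    for i, lab in enumerate(labels):
        groups.setdefault(lab, set()).add(s["id"].iloc[i])
    return {frozenset(g) for g in groups.values()}


class TestAggregations:
    def test_five_singletons_one_aggregation(self):
        rows = [(f"s{i}", "2017-01-10", -40.5, 173.0, 1) for i in range(5)]
        aggs = pl.detect_aggregations(sightings_table(rows))
        assert len(aggs) == 1
        assert aggs[0].total_whales == 5
        assert aggs[0].start_date == pd.Timestamp("2017-01-10")

    def test_four_whales_below_minimum(self):
        rows = [(f"s{i}", "2017-01-10", -40.5, 173.0, 1) for i in range(4)]
        assert pl.detect_aggregations(sightings_table(rows)) == []

    def test_chain_links_through_intermediate(self):
        # a-b and b-c within 50 km, a-c not: single-linkage joins all three
        rows = [
            ("a", "2017-01-10", -40.0, 172.0, 2),
            ("b", "2017-01-11", -40.0, 172.5, 2),
            ("c", "2017-01-12", -40.0, 173.0, 2),
        ]
        aggs = pl.detect_aggregations(sightings_table(rows))
        assert len(aggs) == 1 and aggs[0].total_whales == 6
        # clique mode refuses the distant pair
        aggs_clique = pl.detect_aggregations(sightings_table(rows), mode="clique")
        assert all(a.total_whales < 6 for a in aggs_clique)

    def test_matches_bruteforce_connectivity_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(40):
            n = int(rng.integers(2, 11))
            rows = [
                (
                    f"s{i}",
                    pd.Timestamp("2017-01-01") + pd.Timedelta(days=int(rng.integers(0, 20))),
                    -41.0 + rng.uniform(0, 1.2),
                    172.0 + rng.uniform(0, 1.5),
                    int(rng.integers(1, 4)),
                )
                for i in range(n)
            ]
            s = sightings_table(rows)
            expected = {
                comp
                for comp in brute_components(s)
                if sum(s.set_index("id").loc[list(comp), "count"]) >= 5
            }
            got = {frozenset(a.member_sightings) for a in pl.detect_aggregations(s)}
            assert got == expected


class TestWindyDaysPrior:
    def test_window_conventions(self):
        w = wind_table([7.0] * 40, start="2017-01-01")
        assert pl.windy_days_prior(w, "2017-02-01", 30, 5.5) == 30
        calm = wind_table([3.0] * 40, start="2017-01-01")
        assert pl.windy_days_prior(calm, "2017-02-01", 30, 5.5) == 0

    def test_boundary_days(self):
        # only day -30 windy -> included; only day 0 windy -> excluded
        speeds = [3.0] * 61
        speeds[0] = 9.0  # 2017-01-01 == date - 30
        w = wind_table(speeds, start="2017-01-01")
        assert pl.windy_days_prior(w, "2017-01-31", 30, 5.5) == 1
        speeds = [3.0] * 61
        speeds[30] = 9.0  # the aggregation start day itself
        w = wind_table(speeds, start="2017-01-01")
        assert pl.windy_days_prior(w, "2017-01-31", 30, 5.5) == 0


def make_agg(date, aid="agg000"):
    return pl.Aggregation(aid, ("x",), pd.Timestamp(date), 5, (-40.5, 173.0))


class TestComputeLags:
    def test_most_recent_previous_event(self, config):
        w = wind_table([3.0] * 60, start="2017-01-01")
        events = [
            pl.WindEvent(pd.Timestamp("2017-01-01"), pd.Timestamp("2017-01-02"), 2, 7.0, 5.5),
            pl.WindEvent(pd.Timestamp("2017-01-10"), pd.Timestamp("2017-01-11"), 2, 7.0, 5.5),
        ]
        df, summary = pl.compute_lags([make_agg("2017-01-15")], events, w, config)
        assert df["lag_days"].iloc[0] == 5
        assert summary["n_excluded"] == 0

    def test_no_prior_event_excluded_and_counted(self, config):
        w = wind_table([3.0] * 200, start="2017-01-01")
        events = [pl.WindEvent(pd.Timestamp("2017-01-01"), pd.Timestamp("2017-01-02"), 2, 7.0, 5.5)]
        df, summary = pl.compute_lags([make_agg("2017-06-01")], events, w, config)
        assert len(df) == 0 and summary["n_excluded"] == 1

    def test_summary_matches_hand_computation(self, config):
        w = wind_table([3.0] * 120, start="2017-01-01")
        events = [pl.WindEvent(pd.Timestamp("2017-01-01"), pd.Timestamp("2017-01-02"), 2, 7.0, 5.5)]
        aggs = [make_agg(pd.Timestamp("2017-01-01") + pd.Timedelta(days=d), f"agg{d}") for d in (7, 14, 21)]
        _, summary = pl.compute_lags(aggs, events, w, config)
        lags_w = np.array([7, 14, 21]) / 7.0
        assert summary["mean_lag_weeks"] == pytest.approx(2.0)
        assert summary["se_lag_weeks"] == pytest.approx(lags_w.std(ddof=1) / np.sqrt(3))

    def test_translation_invariance(self, config):
        w = wind_table([3.0] * 60, start="2017-01-01")
        events = [pl.WindEvent(pd.Timestamp("2017-01-05"), pd.Timestamp("2017-01-06"), 2, 7.0, 5.5)]
        df1, _ = pl.compute_lags([make_agg("2017-01-15")], events, w, config)
        shift = pd.Timedelta(days=500)
        w2 = w.assign(date=w["date"] + shift)
        events2 = [pl.WindEvent(events[0].start_date + shift, events[0].end_date + shift, 2, 7.0, 5.5)]
        df2, _ = pl.compute_lags([make_agg(pd.Timestamp("2017-01-15") + shift)], events2, w2, config)
        assert df1["lag_days"].iloc[0] == df2["lag_days"].iloc[0]


class TestPoissonGlm:
    def test_constant_response_saturated_mean(self):
        y = np.full(50, 7.0)
        x = np.random.default_rng(0).normal(size=50)
        fit = pl.fit_poisson_glm(y, x)
        assert fit.intercept == pytest.approx(np.log(7.0), abs=1e-4)
        assert fit.slope == pytest.approx(0.0, abs=1e-4)

    def test_parameter_recovery(self):
        ok = 0
        for seed in range(25):
            rng = np.random.default_rng(seed)
            x = rng.integers(0, 31, 200).astype(float)
            y = rng.poisson(np.exp(2.5 - 0.05 * x))
            fit = pl.fit_poisson_glm(y, x)
            ok += (
                abs(fit.intercept - 2.5) <= 3 * fit.se_intercept
                and abs(fit.slope + 0.05) <= 3 * fit.se_slope
            )
        assert ok >= 24

    def test_lr_statistic_is_deviance_difference(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 31, 100).astype(float)
        y = rng.poisson(np.exp(2.0 - 0.04 * x))
        fit = pl.fit_poisson_glm(y, x)
        assert fit.lr_chi2 == pytest.approx(fit.null_deviance - fit.deviance)
        assert fit.lr_chi2 >= 0

    @pytest.mark.parametrize("y", [[1.5, 2.0, 3.0], [-1, 0, 2]])
    def test_invalid_response_rejected(self, y):
        with pytest.raises(ValidationError):
            pl.fit_poisson_glm(y, [1.0, 2.0, 3.0])

    def test_degenerate_covariate_rejected(self):
        with pytest.raises(DegenerateDataError):
            pl.fit_poisson_glm([1, 2, 3], [1.0, 1.0, 1.0])


class TestThresholdSensitivity:
    def test_event_days_nested_and_degenerate_row(self, config):
        w = pl.gen_wind(pl.WindSimParams(n_years=6), seed=3)
        events = pl.detect_wind_events(w, 5.5)
        s, _ = pl.gen_sightings(w, events, pl.SightingSimParams(), seed=4)
        table = pl.threshold_sensitivity(w, s, config, thresholds=(3.0, 5.5, 8.0, 10.5, 50.0))
        # the exceedance day set shrinks as the threshold rises (event
        # counts themselves may merge at low thresholds)
        speeds = w["speed"].to_numpy()
        day_sets = [set(np.flatnonzero(speeds > t)) for t in (3.0, 5.5, 8.0, 10.5, 50.0)]
        for lo, hi in zip(day_sets, day_sets[1:]):
            assert hi <= lo
        counts = table["n_events"].to_numpy()
        assert (np.diff(counts[1:]) <= 0).all()  # beyond the background cap
        last = table.iloc[-1]
        assert last["n_events"] == 0 and np.isnan(last["aic"])
        assert table["best_fit"].sum() == 1

    def test_mean_lag_nondecreasing_in_threshold(self, config):
        # sparser events can only push the most-recent-event lag up, in expectation
        diffs = []
        for seed in range(5):
            w = pl.gen_wind(pl.WindSimParams(n_years=8), seed=seed)
            events = pl.detect_wind_events(w, 5.5)
            s, _ = pl.gen_sightings(w, events, pl.SightingSimParams(), seed=seed + 100)
            table = pl.threshold_sensitivity(w, s, config, thresholds=(3.0, 5.5, 8.0))
            lags = table["mean_lag_weeks"].to_numpy()
            diffs.append(np.diff(lags))
        assert np.mean(np.concatenate(diffs)) > 0
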