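import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from seagrassdbn.light import (THREE_STATE, TWO_STATE, DailyLightSeries,
                               DurationThresholds, IrradianceThresholdKNN,
                               LightThresholds, MissingDataError,
                               build_monthly_evidence, classify_day,
                               classify_days, daily_light_hours,
                               default_threshold_grid, estimate_thresholds_knn,
                               hours_in_state, monthly_evidence)
from seagrassdbn.synthetic import (SiteScenario, gen_light_series,
                                   znoltei_anchor_training_table)


def make_day(irradiances, date="2016-06-01"):
    ts = pd.date_range(date, periods=len(irradiances), freq="10min")
    return pd.DataFrame({"timestamp": ts, "irradiance": irradiances})


FLAT_THRESHOLDS = LightThresholds(ik=(100.0,) * 12, ic=(10.0,) * 12)


class TestKNN:
    def test_single_record_always_returned(self):
        table = pd.DataFrame({"species": ["s"], "temp_c": [20.0],
                              "ik": [100.0], "ic": [10.0]})
        thr = estimate_thresholds_knn([5.0] * 6 + [30.0] * 6, table, k=1)
        assert thr.ik == (100.0,) * 12 and thr.ic == (10.0,) * 12

    def test_k1_returns_nearest_training_pair_exactly(self):
        rng = np.random.default_rng(0)
        temps = np.sort(rng.uniform(5, 30, 15))
        table = pd.DataFrame({"species": "s", "temp_c": temps,
                              "ik": 100 + 10 * temps, "ic": 5 + temps})
        model = IrradianceThresholdKNN(k=1).fit(
            temps, table[["ik", "ic"]].to_numpy())
        queries = rng.uniform(5, 30, 20)
        pred = model.predict(queries)
        for q, p in zip(queries, pred):
            i = np.argmin(np.abs(temps - q))
            assert p == pytest.approx([table["ik"][i], table["ic"][i]])

    def test_tie_broken_toward_warmer_record(self):
        table = pd.DataFrame({"species": ["s", "s"], "temp_c": [10.0, 20.0],
                              "ik": [100.0, 200.0], "ic": [10.0, 20.0]})
        warm = IrradianceThresholdKNN.from_table(table, k=1, tie="warmer")
        cool = IrradianceThresholdKNN.from_table(table, k=1, tie="cooler")
        assert warm.predict([15.0])[0, 0] == 200.0
        assert cool.predict([15.0])[0, 0] == 100.0

    def test_k_larger_than_table_rejected(self):
        table = znoltei_anchor_training_table()
        with pytest.raises(ValueError, match="k="):
            estimate_thresholds_knn([15.0] * 12, table, k=5)

    def test_empty_table_rejected(self):
        empty = pd.DataFrame({"species": [], "temp_c": [], "ik": [], "ic": []})
        with pytest.raises(ValueError):
            estimate_thresholds_knn([15.0] * 12, empty)

    def test_k2_averages_neighbours(self):
        table = pd.DataFrame({"species": ["s"] * 3, "temp_c": [10.0, 12.0, 30.0],
                              "ik": [100.0, 200.0, 500.0],
                              "ic": [10.0, 20.0, 50.0]})
        thr = estimate_thresholds_knn([11.0] * 12, table, k=2)
        assert thr.ik[0] == pytest.approx(150.0)
        assert thr.ic[0] == pytest.approx(15.0)


class TestHoursInState:
    def test_all_above_gives_24h(self):
        day = make_day([200.0] * 144)
        assert hours_in_state(day, 100.0, 10.0) == pytest.approx(24.0)

    def test_all_dark_gives_zero(self):
        day = make_day([0.0] * 144)
        assert hours_in_state(day, 100.0, 10.0) == 0.0

    def test_sample_count_times_interval(self):
        irr = [200.0] * 36 + [0.0] * 108
        day = make_day(irr)
        assert hours_in_state(day, 100.0, 10.0) == pytest.approx(6.0)

    def test_empty_day_raises(self):
        with pytest.raises(MissingDataError):
            hours_in_state(make_day([]), 100.0, 10.0)


class TestClassifyDay:
    def test_two_state_above(self):
        day = make_day([200.0] * 60 + [0.0] * 84)  # 10 h above
        dur = DurationThresholds(TWO_STATE, 6.0)
        assert classify_day(day, FLAT_THRESHOLDS, dur, "Jun", 10.0) == \
            "above_saturation"

    def test_three_state_clause_order(self):
        # 5 h above I_k (< H_sat) but 9 h above I_c (>= H_comp)
        irr = [200.0] * 30 + [50.0] * 24 + [0.0] * 90
        day = make_day(irr)
        dur = DurationThresholds(THREE_STATE, 6.0, 8.5)
        assert classify_day(day, FLAT_THRESHOLDS, dur, "Jun", 10.0) == \
            "below_saturation"

    def test_three_state_below_limitation(self):
        day = make_day([0.0] * 144)
        dur = DurationThresholds(THREE_STATE, 6.0, 8.5)
        assert classify_day(day, FLAT_THRESHOLDS, dur, "Jun", 10.0) == \
            "below_limitation"

    @given(st.integers(0, 143), st.integers(0, 143), st.integers(0, 1000))
    def test_matches_per_sample_counting_oracle(self, n_hi, n_mid, seed):
        """classify_day agrees with a direct per-sample count for random
        arrangements of bright/dim/dark samples."""
        rng = np.random.default_rng(seed)
        irr = np.zeros(144)
        pos = rng.permutation(144)
        irr[pos[:n_hi]] = 150.0
        irr[pos[n_hi:min(144, n_hi + n_mid)]] = 50.0
        day = make_day(irr)
        dur = DurationThresholds(THREE_STATE, 6.0, 8.5)
        got = classify_day(day, FLAT_THRESHOLDS, dur, "Jun", 10.0)
        h_sat = (irr >= 100).sum() / 6.0
        h_comp = (irr >= 10).sum() / 6.0
        if h_sat >= 6.0:
            expect = "above_saturation"
        elif h_comp < 8.5:
            expect = "below_limitation"
        else:
            expect = "below_saturation"
        assert got == expect


class TestMonthlyEvidence:
    def classified(self, above, total, month="Jun"):
        states = (["above_saturation"] * above +
                  ["below_saturation"] * (total - above))
        frames = []
        for m in ("Jan", "Feb", "Mar", "Apr", "May", "Jun",
                  "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"):
            frames.append(pd.DataFrame({
                "date": pd.date_range("2016-01-01", periods=total),
                "month": m,
                "state": states if m == month else ["below_saturation"] * total,
            }))
        return pd.concat(frames, ignore_index=True)

    def test_all_above_gives_unit_delta(self):
        ev = monthly_evidence(self.classified(30, 30), TWO_STATE)
        assert ev.delta[5] == pytest.approx([1.0, 0.0])

    def test_fraction_of_days(self):
        ev = monthly_evidence(self.classified(12, 30), TWO_STATE)
        assert ev.delta[5, 0] == pytest.approx(0.4)

    def test_rows_on_simplex(self):
        ev = monthly_evidence(self.classified(7, 31), TWO_STATE)
        assert np.allclose(ev.delta.sum(axis=1), 1.0)
        assert (ev.delta >= 0).all()

    def test_missing_month_raises(self):
        df = self.classified(5, 10)
        with pytest.raises(MissingDataError, match="Mar"):
            monthly_evidence(df[df.month != "Mar"], TWO_STATE)


@pytest.fixture(scope="module")
def sample_series():
    scn = SiteScenario(site="S", months=25, seed=4, peak_ratio=2.0)
    return gen_light_series(scn, FLAT_THRESHOLDS)


class TestEvidencePipeline:
    def test_delta_above_nonincreasing_in_h_sat(self, sample_series):
        deltas = []
        for h in (4.0, 6.0, 8.0, 10.0):
            ev = build_monthly_evidence(sample_series, FLAT_THRESHOLDS,
                                        DurationThresholds(TWO_STATE, h))
            deltas.append(ev.delta[:, 0])
        for lo, hi in zip(deltas, deltas[1:]):
            assert np.all(hi <= lo + 1e-12)

    def test_two_three_state_consistency(self, sample_series):
        d2 = build_monthly_evidence(sample_series, FLAT_THRESHOLDS,
                                    DurationThresholds(TWO_STATE, 6.0)).delta
        d3 = build_monthly_evidence(sample_series, FLAT_THRESHOLDS,
                                    DurationThresholds(THREE_STATE, 6.0, 9.0)).delta
        assert np.allclose(d3[:, 0], d2[:, 0])
        assert np.allclose(d3[:, 1] + d3[:, 2], d2[:, 1])

    def test_gappy_days_excluded(self, sample_series):
        data = sample_series.data.iloc[::2].reset_index(drop=True)  # 20-min gaps
        thin = DailyLightSeries(site="S", data=data, interval_minutes=10.0)
        with pytest.raises(MissingDataError):
            daily_light_hours(thin, FLAT_THRESHOLDS, max_missing_frac=0.2)

    def test_classify_days_matches_per_day_calls(self, sample_series):
        dur = DurationThresholds(THREE_STATE, 6.0, 9.0)
        fast = classify_days(sample_series, FLAT_THRESHOLDS, dur)
        sample = fast.sample(10, random_state=0)
        for _, row in sample.iterrows():
            day = sample_series.data[
                pd.to_datetime(sample_series.data.timestamp).dt.normalize()
                == row["date"]]
            assert classify_day(day, FLAT_THRESHOLDS, dur, row["month"],
                                10.0) == row["state"]


def test_default_grid_mirrors_published_candidates():
    two = default_threshold_grid(TWO_STATE)
    three = default_threshold_grid(THREE_STATE)
    assert [t.h_sat for t in two] == [4, 5, 5.5, 6, 7, 7.5, 8, 8.5, 9]
    assert len(three) == 25
    assert {t.h_comp for t in three} == {8.5, 9.0, 10.0, 11.0, 12.0}
    assert len(default_threshold_grid()) == 34


def test_duration_threshold_invariants():
    with pytest.raises(ValueError):
        DurationThresholds(TWO_STATE, 0.0)
    with pytest.raises(ValueError):
        DurationThresholds(THREE_STATE, 6.0, None)
    with pytest.raises(ValueError):
        DurationThresholds("four_state", 6.0)


def test_light_thresholds_require_ik_above_ic():
    with pytest.raises(ValueError):
        LightThresholds(ik=(10.0,) * 12, ic=(10.0,) * 12)
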