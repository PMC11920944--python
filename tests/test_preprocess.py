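"""Range filtering, day/night splitting, period tiling, LAI compositing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import fluxdebt as fd
from fluxdebt import preprocess
from fluxdebt.periods import assign_periods, build_periods


class TestFilterRange:
    def test_out_of_range_values_flagged(self, flux_frame):
        out = fd.filter_range(flux_frame)
        qc = out["qc"].to_list()
        assert qc[0] == "range_removed"      # -150
        assert qc[1] == qc[2] == "ok"        # -50, 0
        assert qc[3] == "range_removed"      # 101
        assert qc[5] == "missing"
        # originals preserved
        assert out["nee"].iloc[0] == -150.0

    def test_in_range_series_unchanged(self):
        ts = pd.date_range("2018-01-01", periods=4, freq="30min")
        flux = pd.DataFrame({"timestamp": ts, "nee": [-5.0, 0.0, 3.0, 99.9],
                             "rg": 0.0, "tair": 20.0, "qc": "ok"})
        out = fd.filter_range(flux)
        assert (out["qc"] == "ok").all()

    def test_invalid_bounds_rejected(self, flux_frame):
        with pytest.raises(ValueError):
            fd.filter_range(flux_frame, lo=10.0, hi=10.0)

    def test_empty_series_rejected(self):
        with pytest.raises(ValueError):
            fd.filter_range(pd.DataFrame({"nee": []}))

    @given(st.lists(st.floats(min_value=-200, max_value=200,
                              allow_nan=False), min_size=1, max_size=40))
    def test_filtering_is_idempotent(self, values):
        ts = pd.date_range("2018-01-01", periods=len(values), freq="30min")
        flux = pd.DataFrame({"timestamp": ts, "nee": values, "rg": 0.0,
                             "tair": 20.0})
        once = fd.filter_range(flux)
        twice = fd.filter_range(once)
        pd.testing.assert_frame_equal(once, twice)


class TestSplitDaynight:
    def test_threshold_is_strict_for_day(self, flux_frame):
        day, night = fd.split_daynight(flux_frame)
        assert day.tolist()[:4] == [False, False, False, True]
        assert night.tolist()[:4] == [True, True, True, False]

    def test_masks_partition_defined_records(self, flux_frame):
        day, night = fd.split_daynight(flux_frame)
        assert not np.any(day & night)
        assert np.all(day | night)

    def test_zero_threshold_all_day(self):
        ts = pd.date_range("2018-01-01", periods=3, freq="30min")
        flux = pd.DataFrame({"timestamp": ts, "nee": 0.0,
                             "rg": [1.0, 5.0, 900.0], "tair": 20.0})
        day, _ = fd.split_daynight(flux, rg_threshold=0.0)
        assert day.all()

    def test_all_rg_missing_rejected(self):
        ts = pd.date_range("2018-01-01", periods=3, freq="30min")
        flux = pd.DataFrame({"timestamp": ts, "nee": 0.0, "rg": np.nan,
                             "tair": 20.0})
        with pytest.raises(ValueError):
            fd.split_daynight(flux)


class TestPeriodCalendar:
    def test_first_periods_of_a_year(self):
        cal = build_periods(2018)
        assert cal.iloc[0]["start"] == pd.Timestamp("2018-01-01")
        assert cal.iloc[0]["end"] == pd.Timestamp("2018-01-25")
        assert cal.iloc[1]["start"] == pd.Timestamp("2018-01-25")

    def test_final_period_absorbs_remainder(self):
        cal = build_periods(2018)
        last = cal.iloc[-1]
        assert (last["end"] - last["start"]).days == 29
        cal_leap = build_periods(2020)
        assert (cal_leap.iloc[-1]["end"] - cal_leap.iloc[-1]["start"]).days == 30

    def test_two_years_tile_without_overlap(self):
        cal = build_periods([2018, 2019])
        assert len(cal) == 30
        assert (cal["start"].iloc[1:].to_numpy()
                == cal["end"].iloc[:-1].to_numpy()).all()

    def test_tiling_conserves_record_counts(self):
        cal = build_periods(2018)
        ts = pd.date_range("2018-01-01", "2019-01-01", freq="30min",
                           inclusive="left")
        idx = assign_periods(ts, cal)
        assert (idx >= 0).all()
        counts = np.bincount(idx, minlength=len(cal))
        assert counts.sum() == 365 * 48
        assert (counts[:14] == 24 * 48).all()


class TestCompositeLai:
    def test_period_maximum_selected(self):
        cal = build_periods(2018)
        lai8 = pd.DataFrame({
            "date": pd.to_datetime(["2018-01-01", "2018-01-09", "2018-01-17"]),
            "lai": [4.1, 5.0, 4.7]})
        out = fd.composite_lai(lai8, cal)
        assert out["lai"].iloc[0] == 5.0

    def test_empty_period_left_missing(self):
        cal = build_periods(2018)
        lai8 = pd.DataFrame({"date": pd.to_datetime(["2018-01-01"]),
                             "lai": [4.0]})
        out = fd.composite_lai(lai8, cal)
        assert np.isnan(out["lai"].iloc[1])

    def test_screened_value_excluded_from_max(self):
        cal = build_periods(2018)
        dates = pd.to_datetime(["2018-01-01", "2018-01-09", "2018-01-17"])
        lai8 = pd.DataFrame({"date": dates, "lai": [4.1, np.nan, 4.7]})
        out = fd.composite_lai(lai8, cal)
        # brute-force oracle: max over in-window unscreened values
        in_win = [v for d, v in zip(dates, [4.1, np.nan, 4.7])
                  if cal.iloc[0]["start"] <= d < cal.iloc[0]["end"]
                  and np.isfinite(v)]
        assert out["lai"].iloc[0] == max(in_win) == 4.7


class TestGapfill:
    @staticmethod
    def _series(values):
        cal = build_periods(2018).iloc[:len(values)].copy()
        cal["lai"] = values
        cal["filled"] = False
        return cal

    def test_midpoint_interpolation(self):
        out = fd.gapfill_linear(self._series([4.0, np.nan, 6.0]), max_gap=1)
        assert out["lai"].to_list() == [4.0, 5.0, 6.0]
        assert out["filled"].to_list() == [False, True, False]

    def test_long_gap_untouched(self):
        vals = [4.0, np.nan, np.nan, np.nan, 6.0]
        out = fd.gapfill_linear(self._series(vals), max_gap=2)
        assert out["lai"].isna().sum() == 3

    def test_leading_gap_never_filled(self):
        out = fd.gapfill_linear(self._series([np.nan, 4.0, np.nan, 6.0]),
                                max_gap=3)
        assert np.isnan(out["lai"].iloc[0])
        assert out["lai"].iloc[2] == 5.0

    def test_filled_values_bounded_by_neighbors(self):
        vals = [2.0, np.nan, np.nan, 8.0, np.nan, 3.0]
        out = fd.gapfill_linear(self._series(vals), max_gap=2)
        filled = out.loc[out["filled"], "lai"]
        assert (filled >= 2.0).all() and (filled <= 8.0).all()

    def test_single_observation_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            out = fd.gapfill_linear(self._series([4.0, np.nan, np.nan]),
                                    max_gap=2)
        assert out["lai"].isna().sum() == 2


class TestCoverage:
    def test_full_and_half_coverage(self):
        usable = np.array([True, True, False, False])
        mask = np.array([True, True, True, True])
        assert preprocess.coverage(np.ones(4, bool), mask) == 1.0
        assert preprocess.coverage(usable, mask) == 0.5

    def test_empty_mask_is_zero(self):
        assert preprocess.coverage(np.ones(4, bool), np.zeros(4, bool)) == 0.0
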