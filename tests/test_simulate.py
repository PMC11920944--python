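"""Simulator ground truth: determinism, driver geometry, LAI laws, noise."""

import numpy as np
import pandas as pd
import pytest

import fluxdebt as fd
from fluxdebt import simulate


class TestDrivers:
    def test_deterministic_under_fixed_seed(self, clean_cfg):
        a = simulate.simulate_drivers(clean_cfg)
        b = simulate.simulate_drivers(clean_cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_midnight_radiation_is_zero(self, clean_cfg):
        d = simulate.simulate_drivers(clean_cfg)
        midnight = pd.DatetimeIndex(d["timestamp"])
        at_zero = (midnight.hour == 0) & (midnight.minute == 0)
        assert np.all(d.loc[at_zero, "rg"] == 0.0)
        assert np.all(d["rg"] >= 0.0)

    def test_annual_mean_tair_matches_configured_mean(self, clean_cfg):
        d = simulate.simulate_drivers(clean_cfg)
        assert abs(d["tair"].mean() - clean_cfg.tair_mean) < 0.1

    def test_series_length_is_whole_noleap_years(self):
        cfg = fd.SimConfig(start_date="2015-01-01", n_years=3,
                           landfall_date="2016-06-01")
        d = simulate.simulate_drivers(cfg)
        assert len(d) == 3 * 365 * 48

    def test_nonpositive_years_rejected(self):
        with pytest.raises(ValueError):
            fd.SimConfig(n_years=0, landfall_date="2015-06-01")


class TestLai:
    def test_no_disturbance_gives_constant_baseline(self):
        cfg = fd.SimConfig(n_years=2, landfall_date="2015-06-01",
                           lai_drop_frac=0.0, lai_baseline=6.0)
        lai = simulate.simulate_lai(cfg)
        assert np.allclose(lai["lai"], 6.0)

    def test_step_drop_at_landfall(self):
        # landfall on an 8-day sample date so the first post value is exact
        cfg = fd.SimConfig(start_date="2015-01-01", n_years=2,
                           landfall_date="2015-03-06", lai_baseline=6.0,
                           lai_drop_frac=0.5)
        lai = simulate.simulate_lai(cfg)
        at_landfall = lai.loc[lai["date"] == "2015-03-06", "lai"].iloc[0]
        assert at_landfall == pytest.approx(3.0)

    def test_exponential_recovery_law(self):
        cfg = fd.SimConfig(n_years=2, landfall_date="2015-03-06",
                           lai_baseline=6.0, lai_drop_frac=0.5,
                           lai_recovery_days=100.0)
        when = pd.DatetimeIndex([pd.Timestamp("2015-03-06")
                                 + pd.Timedelta(days=100)])
        val = simulate.lai_trajectory(cfg, when)[0]
        assert val == pytest.approx(6.0 - 3.0 * np.exp(-1.0), rel=1e-12)

    def test_invalid_drop_fraction_rejected(self):
        with pytest.raises(ValueError):
            fd.SimConfig(n_years=1, landfall_date="2015-06-01",
                         lai_drop_frac=1.5)


class TestTower:
    def test_deterministic_under_fixed_seed(self):
        cfg = fd.SimConfig(n_years=1, landfall_date="2015-06-01", seed=3)
        a = simulate.simulate_tower(cfg)
        b = simulate.simulate_tower(cfg)
        pd.testing.assert_frame_equal(a.flux, b.flux)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_noiseless_day_records_follow_light_curve(self, clean_sim, clean_cfg):
        flux, truth = clean_sim.flux, clean_sim.truth
        idx = simulate.assign_periods(flux["timestamp"], truth)
        day = flux["rg"].to_numpy() > clean_cfg.rg_threshold
        p = truth.iloc[idx[day][0]]
        sel = day & (idx == idx[day][0])
        expected = fd.predict_lrc(flux.loc[sel, "rg"], p["qy"], p["amax"],
                                  p["reco"])
        np.testing.assert_allclose(flux.loc[sel, "nee"], expected, rtol=1e-12)

    def test_noiseless_night_records_follow_temperature_curve(self, clean_sim):
        flux, truth = clean_sim.flux, clean_sim.truth
        idx = simulate.assign_periods(flux["timestamp"], truth)
        dark = flux["rg"].to_numpy() == 0.0
        sel = dark & (idx == 0)
        p = truth.iloc[0]
        expected = fd.predict_trc(flux.loc[sel, "tair"], p["rb"], p["e0"])
        np.testing.assert_allclose(flux.loc[sel, "nee"], expected, rtol=1e-12)

    def test_injected_noise_sd_recoverable_from_residuals(self):
        cfg = fd.SimConfig(n_years=1, landfall_date="2015-06-01",
                           noise_sd=2.0, missing_frac=0.0, seed=7)
        sim = simulate.simulate_tower(cfg)
        resid = sim.flux["nee"].to_numpy() - sim.nee_clean
        assert len(resid) >= 10_000
        assert np.std(resid) == pytest.approx(2.0, abs=0.1)

    def test_missingness_fraction_applied(self):
        cfg = fd.SimConfig(n_years=1, landfall_date="2015-06-01",
                           missing_frac=0.25, seed=9)
        sim = simulate.simulate_tower(cfg)
        frac = sim.flux["nee"].isna().mean()
        assert frac == pytest.approx(0.25, abs=1e-3)

    def test_outage_interval_blanks_block(self):
        cfg = fd.SimConfig(n_years=1, landfall_date="2015-06-01",
                           missing_frac=0.0, noise_sd=0.0,
                           outage=("2015-07-01", "2015-08-01"))
        sim = simulate.simulate_tower(cfg)
        ts = pd.DatetimeIndex(sim.flux["timestamp"])
        inside = (ts >= "2015-07-01") & (ts < "2015-08-01")
        assert sim.flux.loc[inside, "nee"].isna().all()
        assert sim.flux.loc[~inside, "nee"].notna().all()


class TestLandscape:
    def test_degenerate_mixture_is_constant(self):
        cfg = fd.LandscapeConfig(n_pixels=50, mixture_weights=(1.0, 0.0),
                                 mode_means=(3.0, 5.0), mode_sds=(0.0, 1.0))
        px = simulate.simulate_landscape(cfg)
        assert np.allclose(px["lai"], 3.0)

    def test_mixture_mean_matches_formula(self):
        cfg = fd.LandscapeConfig(n_pixels=10_000,
                                 mixture_weights=(0.5, 0.5),
                                 mode_means=(2.9, 5.5),
                                 mode_sds=(0.5, 0.5), seed=3)
        px = simulate.simulate_landscape(cfg)
        # mixture mean 4.2; mixture sd ~ sqrt(0.25 + 1.69)
        sd = np.sqrt(0.5 * 0.25 + 0.5 * 0.25 + 0.25 * (5.5 - 2.9) ** 2)
        assert abs(px["lai"].mean() - 4.2) < 3 * sd / np.sqrt(10_000)

    def test_truncation_keeps_lai_nonnegative(self):
        cfg = fd.LandscapeConfig(n_pixels=5000, mode_means=(0.3, 5.0),
                                 mode_sds=(0.5, 0.5), seed=1)
        assert (simulate.simulate_landscape(cfg)["lai"] >= 0).all()

    def test_zero_pixels_rejected(self):
        with pytest.raises(ValueError):
            fd.LandscapeConfig(n_pixels=0)

    def test_negative_mode_mean_rejected(self):
        with pytest.raises(ValueError):
            fd.LandscapeConfig(mode_means=(-1.0, 5.0))


class TestExpectedDebt:
    def test_zero_disturbance_gives_zero_debt(self, debt_cfg):
        import dataclasses
        cfg = dataclasses.replace(debt_cfg, lai_drop_frac=0.0)
        ed = simulate.expected_debt(cfg)
        assert np.allclose(ed["annual_debt"], 0.0, atol=1e-9)

    def test_reference_window_before_start_rejected(self):
        cfg = fd.SimConfig(start_date="2015-01-01", n_years=6,
                           landfall_date="2015-06-01")
        with pytest.raises(ValueError):
            simulate.expected_debt(cfg)

    def test_param_law_hits_both_site_anchors(self):
        law = fd.ParamLaw()
        tall = law(5.55)
        scrub = law(2.87)
        assert tall["amax"] == pytest.approx(-32.14)
        assert tall["reco"] == pytest.approx(7.49)
        assert scrub["amax"] == pytest.approx(-9.97, rel=1e-10)
        assert scrub["reco"] == pytest.approx(1.76, rel=1e-10)
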