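"""Forward model and sampling behaviour of the phantom-spectrum simulator."""

import math

import numpy as np
import pytest

import woundxrf as wx
from woundxrf.simulator import STUDY_C_PPM, STUDY_D_MSV, STUDY_T_MM


class TestExpectedSpectrum:
    def test_blank_expectation_independent_of_thickness(self, sim_config):
        """Device background originates upstream of the blood layer."""
        e0 = wx.expected_spectrum(sim_config, 0.0, 0.0, 33.0)
        e2 = wx.expected_spectrum(sim_config, 0.0, 2.0, 33.0)
        np.testing.assert_allclose(e0, e2)

    def test_linearity_in_dose(self, sim_config):
        e1 = wx.expected_spectrum(sim_config, 10.0, 1.0, 16.5)
        e2 = wx.expected_spectrum(sim_config, 10.0, 1.0, 33.0)
        np.testing.assert_allclose(e2, 2.0 * e1, rtol=1e-12)

    def test_half_thickness_halves_net_window_expectation(self, sim_config, windows):
        """At t = ln2/mu the Lambert law halves the attenuated net signal."""
        la = sim_config.analyte_lines[0]
        t_half = math.log(2.0) / la.mu_per_mm
        grid = sim_config.energy_grid()
        mask = windows["PbLa"].mask(grid)
        bg = sim_config.background_per_mSv(grid)[mask].sum() * 66.0
        net0 = wx.expected_spectrum(sim_config, 20.0, 0.0, 66.0)[mask].sum() - bg
        net1 = wx.expected_spectrum(sim_config, 20.0, t_half, 66.0)[mask].sum() - bg
        assert net1 == pytest.approx(net0 / 2.0, rel=1e-9)

    def test_window_integral_matches_closed_form(self, sim_config, windows):
        """Integral over the La window = I1*exp(-mu t)*d*c + B_La*d exactly."""
        tp = sim_config.true_params()
        c, t, d = 15.0, 1.5, 49.5
        grid = sim_config.energy_grid()
        integ = wx.expected_spectrum(sim_config, c, t, d)[windows["PbLa"].mask(grid)].sum()
        expected = tp["I1_La"] * math.exp(-tp["mu_La"] * t) * d * c + tp["I0"] * d
        assert integ == pytest.approx(expected, rel=1e-12)

    def test_lb_background_exceeds_la_background(self, sim_config, windows):
        """The Mo Ka Compton tail inflates the background under the Lb window."""
        assert sim_config.background_rate(windows["PbLb"]) > sim_config.background_rate(
            windows["PbLa"]
        )


class TestSimulateSpectrum:
    def test_deterministic_under_seed(self, sim_config):
        a = wx.simulate_spectrum(sim_config, 10.0, 0.5, 33.0, seed=5)
        b = wx.simulate_spectrum(sim_config, 10.0, 0.5, 33.0, seed=5)
        assert a == b

    def test_accumulation_time_from_dose(self, sim_config):
        s = wx.simulate_spectrum(sim_config, 0.0, 0.0, 16.5, seed=0)
        assert s.accumulation_time_s == pytest.approx(5.0)

    def test_monte_carlo_mean_matches_expectation(self, sim_config, windows, rng):
        """Window counts over 500 replicates: mean within 3 SE of closed form."""
        c, t, d = 10.0, 0.5, 16.5
        grid = sim_config.energy_grid()
        mask = windows["PbLa"].mask(grid)
        truth = wx.expected_spectrum(sim_config, c, t, d)[mask].sum()
        vals = [
            wx.simulate_spectrum(sim_config, c, t, d, rng).counts[mask].sum()
            for _ in range(500)
        ]
        se = np.std(vals, ddof=1) / math.sqrt(len(vals))
        assert abs(np.mean(vals) - truth) < 3.0 * se

    def test_poisson_variance_equals_mean(self, sim_config, windows, rng):
        """Blank window counts: variance within 20% of the mean (Poisson)."""
        grid = sim_config.energy_grid()
        mask = windows["PbLa"].mask(grid)
        vals = [
            wx.simulate_spectrum(sim_config, 0.0, 0.0, 16.5, rng).counts[mask].sum()
            for _ in range(500)
        ]
        assert np.var(vals, ddof=1) == pytest.approx(np.mean(vals), rel=0.20)

    def test_intensity_scales_with_accumulation_time(self, sim_config, windows, rng):
        """4x the live time (dose) -> 4x the mean window counts, within 3 SE."""
        grid = sim_config.energy_grid()
        mask = windows["PbLa"].mask(grid)
        short = np.array(
            [wx.simulate_spectrum(sim_config, 5.0, 0.0, 16.5, rng).counts[mask].sum()
             for _ in range(100)], dtype=float)
        long = np.array(
            [wx.simulate_spectrum(sim_config, 5.0, 0.0, 66.0, rng).counts[mask].sum()
             for _ in range(100)], dtype=float)
        ratio = long.mean() / short.mean()
        se = ratio * math.sqrt(
            (long.std(ddof=1) / long.mean()) ** 2 + (short.std(ddof=1) / short.mean()) ** 2
        ) / math.sqrt(100)
        assert abs(ratio - 4.0) < 3.0 * se


class TestSimulateDesign:
    def test_default_grid_is_the_full_phantom_study(self, study_design):
        assert len(study_design) == 480
        cases = {(m.c_ppm, m.t_mm, m.d_mSv) for m in study_design}
        assert len(cases) == 120
        assert cases == {
            (c, t, d) for c in STUDY_C_PPM for t in STUDY_T_MM for d in STUDY_D_MSV
        }

    def test_singleton_design(self, sim_config):
        out = wx.simulate_design(sim_config, [5.0], [0.0], [16.5], 1, seed=0)
        assert len(out) == 1
        assert (out[0].c_ppm, out[0].t_mm, out[0].d_mSv) == (5.0, 0.0, 16.5)

    def test_different_master_seeds_change_counts_not_labels(self, sim_config):
        a = wx.simulate_design(sim_config, [10.0], [0.5], [33.0], 2, seed=1)
        b = wx.simulate_design(sim_config, [10.0], [0.5], [33.0], 2, seed=2)
        assert [(m.c_ppm, m.t_mm, m.d_mSv, m.replicate) for m in a] == [
            (m.c_ppm, m.t_mm, m.d_mSv, m.replicate) for m in b
        ]
        assert any(
            not np.array_equal(x.spectrum.counts, y.spectrum.counts)
            for x, y in zip(a, b)
        )

    def test_adding_replicates_preserves_earlier_draws(self, sim_config):
        a = wx.simulate_design(sim_config, [10.0], [0.5], [33.0], 2, seed=7)
        b = wx.simulate_design(sim_config, [10.0], [0.5], [33.0], 4, seed=7)
        for x, y in zip(a, b[:2]):
            assert np.array_equal(x.spectrum.counts, y.spectrum.counts)

    def test_empty_design_rejected(self, sim_config):
        with pytest.raises(ValueError):
            wx.simulate_design(sim_config, [], [0.0], [16.5], 1)


class TestConfig:
    def test_json_round_trip(self, sim_config, tmp_path):
        path = tmp_path / "sim.json"
        sim_config.to_json(path)
        loaded = wx.SimConfig.from_json(path)
        np.testing.assert_allclose(
            wx.expected_spectrum(loaded, 10.0, 1.0, 33.0),
            wx.expected_spectrum(sim_config, 10.0, 1.0, 33.0),
        )

    def test_inverted_attenuation_ordering_rejected(self):
        w = wx.default_windows()
        lines = (
            wx.simulator.AnalyteLine("Pb La", 10.55, 0.15, 6.0, 0.20, w["PbLa"]),
            wx.simulator.AnalyteLine("Pb Lb", 12.61, 0.15, 4.0, 0.27, w["PbLb"]),
        )
        with pytest.raises(ValueError, match="attenuation"):
            wx.SimConfig(analyte_lines=lines)


class TestPhantomRecipe:
    def test_paint_series_maps_to_phantom_series(self):
        """The 0..2000 ppm paint solutions at 1:99 give the 0..20 ppm phantoms."""
        for stock, final in [(0, 0), (200, 2), (500, 5), (1000, 10), (1500, 15), (2000, 20)]:
            assert wx.phantom_concentration(stock) == pytest.approx(final)

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            wx.phantom_concentration(2000, 0.0, 99.0)
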