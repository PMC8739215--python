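"""Analysis window, extrema extraction, dominant frequency, FeatureSet."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tcnmm import (DriveSpec, ModelParameters, analysis_window,
                   compute_features, dominant_frequency, extract_extrema,
                   simulate)
from tcnmm.features import features_of_segment


@pytest.fixture(scope="module")
def sine_256():
    dt = 1.0 / 256
    t = np.arange(0, 2.0, dt)
    return np.sin(2 * np.pi * 3.0 * t), dt


class TestAnalysisWindow:
    def test_default_window_is_512_samples(self, default_run):
        seg = analysis_window(default_run, 2.0)
        assert seg.size == 512

    def test_half_second_window(self, default_run):
        assert analysis_window(default_run, 0.5).size == 128

    def test_full_duration_window(self, params):
        r = simulate(params, DriveSpec(), duration=1.0)
        assert analysis_window(r, 1.0).size == round(1.0 / r.dt)

    def test_too_long_window_raises(self, params):
        r = simulate(params, DriveSpec(), duration=1.0)
        with pytest.raises(ValueError):
            analysis_window(r, 2.0)


class TestExtrema:
    def test_sine_single_levels(self, sine_256):
        x, _ = sine_256
        maxima, minima, max_lv, min_lv = extract_extrema(x)
        assert max_lv.size == 1 and min_lv.size == 1
        assert max_lv[0] == pytest.approx(1.0, abs=1e-3)
        assert min_lv[0] == pytest.approx(-1.0, abs=1e-3)

    def test_two_amplitude_train_two_levels(self, fixture_bundle):
        x, _ = fixture_bundle["series"]["two_amplitude_spikes"]
        _, _, max_lv, _ = extract_extrema(x)
        assert max_lv.size == 2
        assert max_lv == pytest.approx([1.0, 0.6], abs=0.02)

    def test_constant_series_no_extrema(self):
        maxima, minima, max_lv, min_lv = extract_extrema(np.full(100, 0.3))
        assert maxima.size == minima.size == 0
        assert max_lv.size == min_lv.size == 0

    def test_negation_swaps_roles(self, fixture_bundle, rng):
        x = rng.standard_normal(300)
        mx, mn, _, _ = extract_extrema(x)
        mx2, mn2, _, _ = extract_extrema(-x)
        assert np.allclose(np.sort(mx), np.sort(-mn2))
        assert np.allclose(np.sort(mn), np.sort(-mx2))

    def test_short_segment_raises(self):
        with pytest.raises(ValueError):
            extract_extrema([1.0, 2.0])


class TestDominantFrequency:
    def test_pure_sine(self, sine_256):
        x, dt = sine_256
        assert dominant_frequency(x, dt) == pytest.approx(3.0, abs=0.5)

    def test_constant_is_zero(self):
        assert dominant_frequency(np.full(512, 1.3), 1 / 256) == 0.0

    def test_dominant_component_wins(self, fixture_bundle):
        x, dt = fixture_bundle["series"]["mixed_2_5hz"]
        assert dominant_frequency(x, dt) == pytest.approx(5.0, abs=0.5)

    @pytest.mark.parametrize("freq", [2.0, 3.3, 7.25, 14.5])
    def test_windowed_sine_within_one_bin(self, freq):
        dt = 0.0039
        t = np.arange(0, 2.0, dt)
        x = np.sin(2 * np.pi * freq * t)
        bin_width = 1.0 / (x.size * dt)
        assert dominant_frequency(x, dt) == pytest.approx(freq,
                                                          abs=bin_width)


class TestFeatureSet:
    def test_normal_state_has_zero_df(self, default_run):
        f = compute_features(default_run)
        assert f.DF == 0.0
        assert f.n_max_clusters == 0
        assert np.isnan(f.Pmax1) and np.isnan(f.Pmin1)

    def test_tonic_regime_df_at_least_14(self, params):
        r = simulate(params.replace(c_i1_ei=0.8), DriveSpec())
        f = compute_features(r)
        assert f.DF >= 14

    def test_swd_fixture_min_gap(self, fixture_bundle):
        x, dt = fixture_bundle["series"]["swd_like"]
        f = features_of_segment(x, dt)
        assert f.Pmin1 - f.Pmin2 == pytest.approx(0.05, abs=0.02)

    def test_ranked_ordering_and_ptp(self, fixture_bundle):
        x, dt = fixture_bundle["series"]["two_amplitude_spikes"]
        f = features_of_segment(x, dt)
        assert f.Pmax1 >= f.Pmax2
        assert f.Pmin1 >= f.Pmin2
        assert f.ptp == pytest.approx(np.ptp(x))

    @given(st.floats(0.05, 50.0))
    @settings(deadline=None, max_examples=30)
    def test_scaling_equivariance(self, k):
        dt = 1 / 256
        t = np.arange(0, 2.0, dt)
        x = 0.4 * np.sin(2 * np.pi * 3 * t) + 0.1 * np.sin(2 * np.pi * 6 * t)
        f1 = features_of_segment(x, dt)
        f2 = features_of_segment(k * x, dt)
        # sub-bin peak interpolation adds float noise far below bin width
        assert f2.DF == pytest.approx(f1.DF, abs=1e-3)
        assert f2.ptp == pytest.approx(k * f1.ptp, rel=1e-9)
        assert f2.Pmax1 == pytest.approx(k * f1.Pmax1, rel=1e-9)
        assert f2.Pmin2 == pytest.approx(k * f1.Pmin2, rel=1e-9)

    def test_row_round_trip(self, fixture_bundle):
        f = fixture_bundle["feature_sets"]["clonic"]
        row = f.to_row()
        assert set(row) == {"DF", "Pmax1", "Pmax2", "Pmin1", "Pmin2",
                            "ptp", "n_max_clusters", "mean"}
        from tcnmm import FeatureSet
        assert FeatureSet.from_row(row) == f
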