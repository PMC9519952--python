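"""Fluorescence-lifetime analysis: centroid estimator, maps, ROI stats."""

import numpy as np
import pytest

from tissueqc import flim, synthetic as syn
from tissueqc.flim import (
    DecayWaveform,
    EmptyRoiError,
    LifetimeMap,
    LowSignalError,
    average_lifetime,
    build_lifetime_map,
    roi_statistics,
    subtract_background,
)

DT = 80e-12


class TestSubtractBackground:
    def test_constant_waveform_becomes_zero(self):
        w = DecayWaveform(np.full(16, 10.0), DT)
        out = subtract_background(w, (0, 16))
        assert np.allclose(out.samples, 0.0)

    def test_arithmetic_example(self):
        w = DecayWaveform([12, 11, 110, 60, 35], DT)
        out = subtract_background(w, (0, 2))  # mean 11.5
        assert np.allclose(out.samples, [0.5, -0.5, 98.5, 48.5, 23.5])

    @pytest.mark.parametrize("window", [(0, 0), (5, 3), (-1, 2), (0, 99)])
    def test_bad_pre_window_raises(self, window):
        w = DecayWaveform(np.arange(10.0), DT)
        with pytest.raises(ValueError):
            subtract_background(w, window)


class TestAverageLifetime:
    def test_mono_exponential_centroid_equals_tau(self):
        # 100 ns window = 20 tau: centroid of an exponential equals tau
        t = np.arange(1250) * DT
        w = DecayWaveform(np.exp(-t / 5e-9), DT)
        assert average_lifetime(w) == pytest.approx(5.0, rel=0.01)

    def test_two_component_closed_form(self):
        # centroid of a1*exp(-t/tau1)+a2*exp(-t/tau2) is
        # (a1 tau1^2 + a2 tau2^2)/(a1 tau1 + a2 tau2)
        t = np.arange(3000) * DT
        w = DecayWaveform(3 * np.exp(-t / 2e-9) + np.exp(-t / 8e-9), DT)
        expected = (3 * 2**2 + 1 * 8**2) / (3 * 2 + 1 * 8)
        assert average_lifetime(w) == pytest.approx(expected, rel=0.01)

    def test_all_zero_waveform_is_low_signal(self):
        with pytest.raises(LowSignalError):
            average_lifetime(DecayWaveform(np.zeros(100), DT))

    @pytest.mark.parametrize("scale", [1e-3, 1.0, 7.3, 1e4])
    def test_invariant_under_positive_scaling(self, scale):
        t = np.arange(1250) * DT
        base = 3 * np.exp(-t / 4e-9) + np.exp(-t / 1e-9)
        ref = average_lifetime(DecayWaveform(base, DT))
        assert average_lifetime(DecayWaveform(scale * base, DT)) == pytest.approx(ref, rel=1e-9)

    def test_threshold_onset_policy(self):
        t = np.arange(1250) * DT
        w = DecayWaveform(np.exp(-t / 5e-9), DT)
        lt = average_lifetime(w, onset_policy="threshold", threshold_frac=0.99)
        assert lt == pytest.approx(5.0, rel=0.02)

    def test_unknown_policy_raises(self):
        w = DecayWaveform(np.ones(10), DT)
        with pytest.raises(ValueError):
            average_lifetime(w, onset_policy="bogus")


class TestDeconvolveIrf:
    def test_recovers_centroid_under_wide_irf(self):
        # 1.5 ns FWHM IRF visibly shifts the raw centroid; RL deconvolution
        # restores it
        dt_ns = 0.08
        t = np.arange(1250) * dt_ns
        sigma = 1.5 / 2.355
        kern = np.exp(-0.5 * ((np.arange(-80, 81) * dt_ns) / sigma) ** 2)
        kern /= kern.sum()
        ideal = np.zeros_like(t)
        ideal[50:] = np.exp(-(t[50:] - t[50]) / 3.0)
        conv = np.convolve(ideal, kern)[80 : 80 + t.size]
        w = DecayWaveform(conv * 1000, 80e-12)
        dec = flim.deconvolve_irf(w, kern, iterations=200)
        assert average_lifetime(dec) == pytest.approx(3.0, abs=0.1)


class TestBuildLifetimeMap:
    def _uniform_scan(self, tau_ns=3.0, shape=(4, 4), nt=1250):
        t = np.arange(nt) * DT
        decay = 100.0 * np.exp(-t / (tau_ns * 1e-9))
        return np.broadcast_to(decay, shape + (nt,)).copy()

    def test_uniform_grid_gives_uniform_map(self):
        m = build_lifetime_map(self._uniform_scan())
        assert m.valid_mask.all()
        assert np.allclose(m.grid, 3.0, rtol=0.01)

    def test_zero_signal_pixel_marked_missing(self):
        scan = self._uniform_scan()
        scan[2, 1, :] = 0.0
        m = build_lifetime_map(scan)
        assert np.isnan(m.grid[2, 1])
        assert np.isnan(m.grid).sum() == 1

    def test_ragged_grid_rejected(self):
        with pytest.raises(ValueError):
            build_lifetime_map(np.zeros((4, 5)))

    def test_two_region_phantom_recovers_both_lifetimes(self):
        nt = 1250
        t = np.arange(nt) * DT
        scan = np.empty((4, 8, nt))
        scan[:, :4, :] = 100 * np.exp(-t / 3e-9)
        scan[:, 4:, :] = 100 * np.exp(-t / 6e-9)
        m = build_lifetime_map(scan)
        assert m.grid[:, :4].mean() == pytest.approx(3.0, rel=0.02)
        assert m.grid[:, 4:].mean() == pytest.approx(6.0, rel=0.02)

    def test_intensity_plane_matches_total_counts(self):
        scan = self._uniform_scan()
        m = build_lifetime_map(scan)
        assert np.allclose(m.intensity, scan.sum(axis=-1))


class TestRoiStatistics:
    def _map(self, grid):
        g = np.asarray(grid, dtype=float)
        return LifetimeMap(grid=g, intensity=np.ones_like(g))

    def test_uniform_map_sd_zero(self):
        m = self._map(np.full((9, 9), 3.0))
        st = roi_statistics(m, (4, 4), 3)
        assert st.mean_lt == 3.0
        assert st.sd_lt == 0.0

    def test_two_value_population_sd(self):
        # {2,4} split evenly: mean 3, population sd 1
        g = np.full((2, 10), 2.0)
        g[1, :] = 4.0
        st = roi_statistics(self._map(g), (0.5, 4.5), 50)
        assert st.mean_lt == pytest.approx(3.0)
        assert st.sd_lt == pytest.approx(1.0)

    def test_roi_outside_sample_raises(self):
        g = np.full((8, 8), np.nan)
        g[:2, :2] = 3.0
        m = LifetimeMap(grid=g, intensity=np.ones_like(g))
        with pytest.raises(EmptyRoiError):
            roi_statistics(m, (6, 6), 1.2)

    def test_auto_roi_lies_inside_valid_region(self):
        spec = syn.FlimPhantomSpec(shape=(16, 16), noise="none", background_margin=3)
        scan, _ = syn.gen_flim_phantom(spec)
        m = build_lifetime_map(scan, pre_window=(0, 25))
        (cy, cx), r = flim.auto_roi(m)
        st = roi_statistics(m, (cy, cx), r)
        assert st.n_pixels >= 1
        assert st.sd_lt == pytest.approx(0.0, abs=1e-9)


def test_uniform_phantom_roundtrip_sd_is_exactly_zero():
    """Identical decays must map to identical lifetimes: sd == 0 exactly."""
    spec = syn.FlimPhantomSpec(shape=(8, 8), noise="none")
    scan, _ = syn.gen_flim_phantom(spec)
    m = build_lifetime_map(scan, pre_window=(0, 25))
    st = roi_statistics(m, (3.5, 3.5), 3)
    assert st.sd_lt == 0.0
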