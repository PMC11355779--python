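"""Phasor transform, ROI selection, modal lifetime and FRET efficiency."""

import numpy as np
import pytest

from clcphasor import (
    FlimSimParams,
    FlimStack,
    PhasorPoint,
    analyze_fret_experiment,
    fret_efficiency,
    lifetime_from_phasor,
    modal_phasor,
    phasor_histogram,
    phasor_transform,
    select_roi,
    simulate_fret_pair,
    single_exp_phasor,
)
from clcphasor.flim_phasor import PhasorMap, calibrate_phasor

from conftest import noiseless_stack


def make_stack(counts, laser_freq=80.0):
    counts = np.asarray(counts)
    bw = (1000.0 / laser_freq) / counts.shape[-1]
    return FlimStack(counts=counts, laser_freq=laser_freq, bin_width=bw)


class TestPhasorTransform:
    def test_delta_decay_maps_to_unit_g(self):
        """All photons in the first bin: the zero-lifetime limit (G,S)=(1,0)
        up to the half-bin phase offset of the bin center."""
        counts = np.zeros((1, 1, 256), dtype=int)
        counts[0, 0, 0] = 1000
        pm = phasor_transform(make_stack(counts))
        # bin center sits half a bin after t=0, a phase of pi/256
        assert pm.g[0, 0] == pytest.approx(np.cos(np.pi / 256), abs=1e-12)
        assert pm.s[0, 0] == pytest.approx(np.sin(np.pi / 256), abs=1e-12)

    def test_uniform_decay_maps_to_origin(self):
        """A flat histogram has no first-harmonic content: (G,S)=(0,0)."""
        counts = np.full((2, 2, 128), 50, dtype=int)
        pm = phasor_transform(make_stack(counts))
        assert np.allclose(pm.g, 0.0, atol=1e-12)
        assert np.allclose(pm.s, 0.0, atol=1e-12)

    def test_expected_histogram_matches_closed_form(self):
        """The noiseless 2.5 ns decay lands on the analytic single-exponential
        phasor (0.3877, 0.4872) within the bin-discretization tolerance."""
        stack = noiseless_stack(FlimSimParams(width=1, height=1))
        pm = phasor_transform(stack)
        assert pm.g[0, 0] == pytest.approx(0.3877, abs=0.002)
        assert pm.s[0, 0] == pytest.approx(0.4872, abs=0.002)

    def test_zero_pixels_flagged_invalid(self):
        counts = np.zeros((2, 1, 64), dtype=int)
        counts[0, 0, 3] = 10
        pm = phasor_transform(make_stack(counts))
        assert pm.valid[0, 0] and not pm.valid[1, 0]
        assert np.isnan(pm.g[1, 0])

    def test_all_zero_stack_rejected(self):
        with pytest.raises(ValueError, match="no photons"):
            phasor_transform(make_stack(np.zeros((2, 2, 64), dtype=int)))

    def test_matches_bruteforce_trig_sum(self):
        """Vectorized transform equals an independent per-pixel loop."""
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 50, size=(4, 3, 64))
        stack = make_stack(counts)
        pm = phasor_transform(stack)
        period = 1000.0 / 80.0
        t = (np.arange(64) + 0.5) * (period / 64)
        for i in range(4):
            for j in range(3):
                c = counts[i, j].astype(float)
                tot = c.sum()
                g = sum(ck * np.cos(2 * np.pi * tk / period)
                        for ck, tk in zip(c, t)) / tot
                s = sum(ck * np.sin(2 * np.pi * tk / period)
                        for ck, tk in zip(c, t)) / tot
                assert pm.g[i, j] == pytest.approx(g, rel=1e-12)
                assert pm.s[i, j] == pytest.approx(s, rel=1e-12)


class TestSingleExpPhasor:
    def test_zero_lifetime(self):
        p = single_exp_phasor(0.0, 80.0)
        assert (p.g, p.s) == (1.0, 0.0)

    def test_semicircle_apex_at_unit_omega_tau(self):
        """tau = 1/omega = 1.9894 ns at 80 MHz sits at the apex (0.5, 0.5)."""
        p = single_exp_phasor(1.9894367886486917, 80.0)
        assert p.g == pytest.approx(0.5, abs=1e-12)
        assert p.s == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("tau", [0.1, 1.0, 2.5, 10.0])
    def test_roundtrip_identity(self, tau):
        p = single_exp_phasor(tau, 80.0)
        assert lifetime_from_phasor(p, 80.0) == pytest.approx(tau, rel=1e-12)

    @pytest.mark.parametrize("tau", np.geomspace(0.05, 50, 12).tolist())
    def test_on_universal_semicircle(self, tau):
        p = single_exp_phasor(tau, 80.0)
        assert p.g ** 2 + p.s ** 2 == pytest.approx(p.g, abs=1e-12)

    def test_negative_tau_rejected(self):
        with pytest.raises(ValueError):
            single_exp_phasor(-1.0, 80.0)


class TestLifetimeFromPhasor:
    def test_apex_lifetime(self):
        tau = lifetime_from_phasor(PhasorPoint(0.5, 0.5), 80.0)
        assert tau == pytest.approx(1.9894, abs=1e-4)

    def test_closed_form_inversion(self):
        tau = lifetime_from_phasor(PhasorPoint(0.3877266367, 0.4872316614),
                                   80.0)
        assert tau == pytest.approx(2.500, abs=1e-3)

    def test_zero_lifetime_point(self):
        assert lifetime_from_phasor(PhasorPoint(1.0, 0.0), 80.0) == 0.0

    def test_nonpositive_g_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            lifetime_from_phasor(PhasorPoint(0.0, 0.3), 80.0)


class TestCalibration:
    def test_reference_lands_on_its_theoretical_point(self):
        ref_true = single_exp_phasor(2.5, 80.0)
        # instrument rotates by 0.2 rad and demodulates by 0.9
        rot = 0.9 * np.exp(0.2j)
        z = complex(ref_true.g, ref_true.s) * rot
        measured = PhasorPoint(z.real, z.imag)
        cal = calibrate_phasor(measured, measured, 2.5, 80.0)
        assert cal.g == pytest.approx(ref_true.g, abs=1e-12)
        assert cal.s == pytest.approx(ref_true.s, abs=1e-12)


class TestSelectRoi:
    def test_full_band_selects_all_nonzero(self):
        img = np.array([[0, 1, 2], [3, 0, 4]], dtype=float)
        roi = select_roi(img, 0.0, 1.0)
        assert roi.n_pixels == 4
        assert not roi.mask[0, 0] and not roi.mask[1, 1]

    def test_three_plateaus_middle_band(self):
        """Quantile band [0.34, 0.66] of a 3-plateau image keeps exactly the
        middle plateau."""
        img = np.concatenate([np.full(1000, 1.0), np.full(1000, 2.0),
                              np.full(1000, 3.0)]).reshape(3, 1000)
        roi = select_roi(img, 0.34, 0.66)
        assert roi.n_pixels == 1000
        assert np.all(img[roi.mask] == 2.0)

    def test_all_zero_image_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            select_roi(np.zeros((4, 4)))

    def test_provenance_recorded(self):
        roi = select_roi(np.arange(1, 101, dtype=float).reshape(10, 10),
                         0.3, 0.8)
        assert roi.provenance["low_quantile"] == 0.3
        assert roi.provenance["intensity_low"] <= roi.provenance["intensity_high"]


class TestPhasorHistogram:
    def _map(self, g, s):
        g = np.atleast_2d(g)
        s = np.atleast_2d(s)
        return PhasorMap(g=g, s=s, valid=np.isfinite(g), laser_freq=80.0)

    def test_single_pixel_single_bin(self):
        plot = phasor_histogram(self._map([[0.4]], [[0.45]]), n_bins=200)
        assert plot.histogram.sum() == 1
        assert plot.n_pixels == 1

    def test_identical_phasors_one_bin(self):
        g = np.full((100, 100), 0.4)
        s = np.full((100, 100), 0.45)
        plot = phasor_histogram(self._map(g, s), n_bins=200)
        assert (plot.histogram > 0).sum() == 1
        assert plot.histogram.max() == 10_000

    def test_gaussian_cloud_marginal_means(self):
        rng = np.random.default_rng(12)
        g = rng.normal(0.4, 0.02, (200, 200))
        s = rng.normal(0.45, 0.02, (200, 200))
        plot = phasor_histogram(self._map(g, s), n_bins=200)
        gm = (plot.histogram.sum(axis=1) @ plot.g_centers) / plot.histogram.sum()
        sm = (plot.histogram.sum(axis=0) @ plot.s_centers) / plot.histogram.sum()
        assert gm == pytest.approx(0.4, abs=0.005)
        assert sm == pytest.approx(0.45, abs=0.005)

    def test_total_equals_valid_roi_pixels(self, small_flim_params):
        from clcphasor import simulate_flim_stack
        stack, _ = simulate_flim_stack(small_flim_params)
        pm = phasor_transform(stack)
        roi = select_roi(stack.intensity(), 0.3, 0.8)
        plot = phasor_histogram(pm, roi)
        assert plot.histogram.sum() == (roi.mask & pm.valid).sum()


class TestModalPhasor:
    def _plot_from_points(self, g, s, n_bins=200):
        pm = PhasorMap(g=np.asarray(g), s=np.asarray(s),
                       valid=np.isfinite(np.asarray(g)), laser_freq=80.0)
        return phasor_histogram(pm, n_bins=n_bins)

    def test_single_bin_returns_its_center(self):
        plot = self._plot_from_points([[0.4]], [[0.45]])
        mode = modal_phasor(plot)
        gi = np.searchsorted(plot.g_edges, 0.4) - 1
        si = np.searchsorted(plot.s_edges, 0.45) - 1
        assert mode.g == pytest.approx(plot.g_centers[gi], abs=0.01)
        assert mode.s == pytest.approx(plot.s_centers[si], abs=0.01)

    def test_gaussian_cloud_mode_near_center(self):
        rng = np.random.default_rng(3)
        n = 100_000
        g = rng.normal(0.4, 0.02, (1, n))
        s = rng.normal(0.45, 0.02, (1, n))
        mode = modal_phasor(self._plot_from_points(g, s))
        assert mode.g == pytest.approx(0.4, abs=0.003)
        assert mode.s == pytest.approx(0.45, abs=0.003)

    def test_boundary_truncated_cloud(self):
        """A cloud clipped at the semicircle boundary still localizes its
        center to ~0.01."""
        rng = np.random.default_rng(4)
        n = 100_000
        g = rng.normal(0.5, 0.015, n)
        s = rng.normal(0.5, 0.015, n)
        inside = g ** 2 + s ** 2 <= g  # keep only points inside
        mode = modal_phasor(self._plot_from_points(g[None, inside],
                                                   s[None, inside]))
        assert mode.g == pytest.approx(0.5, abs=0.01)
        assert mode.s == pytest.approx(0.5, abs=0.01)

    def test_empty_plot_rejected(self):
        plot = self._plot_from_points([[0.4]], [[0.45]])
        plot.histogram[:] = 0
        with pytest.raises(ValueError, match="empty"):
            modal_phasor(plot)


class TestFretEfficiency:
    def test_unquenched_is_zero(self):
        assert fret_efficiency(2.5, 2.5).efficiency == 0.0

    def test_published_quench_level(self):
        """tau_DA = 2.025 ns against tau_D = 2.5 ns gives E = 0.19."""
        assert fret_efficiency(2.5, 2.025).efficiency == pytest.approx(0.19)

    def test_half_life_quenching(self):
        assert fret_efficiency(2.5, 1.25).efficiency == pytest.approx(0.5)

    def test_negative_efficiency_reported_not_clipped(self):
        assert fret_efficiency(2.5, 2.6).efficiency < 0

    def test_nonpositive_donor_rejected(self):
        with pytest.raises(ValueError):
            fret_efficiency(0.0, 1.0)


class TestAnalyzeFretExperiment:
    def _stacks(self, efficiency, n_cells=3, seed0=50, **kw):
        donors, pairs = [], []
        for i in range(n_cells):
            params = FlimSimParams(width=48, height=48,
                                   seed=seed0 + 2 * i, **kw)
            d, p = simulate_fret_pair(params, efficiency=efficiency)
            donors.append(d)
            pairs.append(p)
        return donors, pairs

    def test_zero_efficiency_recovers_zero(self):
        donors, pairs = self._stacks(0.0)
        res = analyze_fret_experiment(donors, pairs)
        assert res.mean_efficiency == pytest.approx(0.0, abs=0.01)

    def test_published_efficiency_recovered(self):
        donors, pairs = self._stacks(0.19)
        res = analyze_fret_experiment(donors, pairs)
        assert res.mean_efficiency == pytest.approx(0.19, abs=0.02)
        assert len(res.table) == 3
        assert (res.table["efficiency"] ==
                1 - res.table["tau_da_ns"] / res.table["tau_donor_ns"]).all()

    def test_missing_donor_reference_rejected(self):
        _, pairs = self._stacks(0.1, n_cells=1)
        with pytest.raises(ValueError, match="donor-only"):
            analyze_fret_experiment([], pairs)

    def test_per_cell_donor_matching_option(self):
        donors, pairs = self._stacks(0.19, n_cells=2)
        res = analyze_fret_experiment(donors, pairs, pool_donor=False)
        assert res.mean_efficiency == pytest.approx(0.19, abs=0.02)


class TestInvariants:
    def test_linearity_of_mixture_phasor(self):
        """Phasor of a summed histogram is the intensity-weighted mean of
        the component phasors (transform linearity, exact)."""
        p1 = FlimSimParams(width=1, height=1, lifetimes=(1.0,),
                           photons_per_pixel=1e4)
        p2 = FlimSimParams(width=1, height=1, lifetimes=(4.0,),
                           photons_per_pixel=1e4)
        s1, s2 = noiseless_stack(p1), noiseless_stack(p2)
        c1 = s1.counts.astype(float)
        c2 = 3.0 * s2.counts.astype(float)  # unequal intensities
        mix = FlimStack(counts=(c1 + c2).astype(np.int64),
                        laser_freq=80.0, bin_width=s1.bin_width)
        pm1 = phasor_transform(s1)
        pm2 = phasor_transform(s2)
        pmx = phasor_transform(mix)
        w1 = c1.sum() / (c1.sum() + c2.sum())
        g_expect = w1 * pm1.g[0, 0] + (1 - w1) * pm2.g[0, 0]
        s_expect = w1 * pm1.s[0, 0] + (1 - w1) * pm2.s[0, 0]
        assert pmx.g[0, 0] == pytest.approx(g_expect, abs=1e-6)
        assert pmx.s[0, 0] == pytest.approx(s_expect, abs=1e-6)

    @pytest.mark.parametrize("tau", [0.3, 1.0, 2.5, 8.0])
    def test_expected_decay_phasor_on_semicircle(self, tau):
        """Ideal single-exponential expected decays satisfy the semicircle
        identity |G^2+S^2-G| < 2/n_bins."""
        params = FlimSimParams(width=1, height=1, lifetimes=(tau,))
        pm = phasor_transform(noiseless_stack(params))
        g, s = pm.g[0, 0], pm.s[0, 0]
        assert abs(g ** 2 + s ** 2 - g) < 2.0 / params.n_bins

    def test_efficiency_monotone_in_quenching(self):
        """Recovered E increases strictly with the simulated quenching for a
        fixed photon budget (noiseless expected histograms)."""
        levels = np.linspace(0.0, 0.45, 10)
        recovered = []
        donor = noiseless_stack(FlimSimParams(width=1, height=1))
        pm_d = phasor_transform(donor)
        tau_d = lifetime_from_phasor((pm_d.g[0, 0], pm_d.s[0, 0]), 80.0)
        for e in levels:
            tau_da_true = 2.5 * (1 - e)
            pair = noiseless_stack(FlimSimParams(
                width=1, height=1, lifetimes=(tau_da_true,)))
            pm = phasor_transform(pair)
            tau_da = lifetime_from_phasor((pm.g[0, 0], pm.s[0, 0]), 80.0)
            recovered.append(1 - tau_da / tau_d)
        assert np.all(np.diff(recovered) > 0)
        assert np.allclose(recovered, levels, atol=0.01)
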