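"""Tests for IRF-reconvolution fitting and the free/bound decomposition."""

import numpy as np
import pytest

import nadhtrf as nt
from nadhtrf.datatypes import FitSpec


def _noise_free_hist(params, settings, irf, budget=1e6):
    scaled = nt.scale_to_budget(params, settings, budget)
    curve = nt.convolve_irf(nt.multiexp_curve(scaled, settings), irf)
    return nt.DecayHistogram(counts=curve, settings=settings)


class TestReconvolve:
    def test_delta_kernel_is_identity(self, settings):
        vals = np.zeros(settings.n_bins)
        vals[0] = 1.0
        delta = nt.IRFKernel(center=0.0, fwhm=settings.bin_width, values=vals)
        curve = nt.multiexp_curve(nt.FREE_NADH_25C, settings)
        out = nt.reconvolve(curve, delta)
        assert np.allclose(out, curve, rtol=1e-12)

    def test_counts_conserved(self, settings, irf200):
        curve = nt.multiexp_curve(nt.FREE_NADH_25C, settings)
        out = nt.reconvolve(curve, irf200)
        assert out.sum() == pytest.approx(curve.sum(), rel=1e-9)

    def test_axis_mismatch_rejected(self, settings, irf200):
        with pytest.raises(ValueError, match="mismatch"):
            nt.reconvolve(np.ones(10), irf200)

    def test_matches_brute_force_circular_convolution(self):
        """FFT convolution vs direct O(n^2) circular sum on a small axis."""
        s = nt.AcquisitionSettings(n_bins=256, bin_width=6.1035, rep_period=256 * 6.1035)
        irf = nt.gaussian_irf(s, center=200.0, fwhm=50.0)
        curve = nt.multiexp_curve(
            nt.MultiExpParams(lifetimes=(266.0,), fractions=(1.0,)), s
        )
        n = s.n_bins
        brute = np.array(
            [sum(curve[(i - j) % n] * irf.values[j] for j in range(n)) for i in range(n)]
        )
        assert np.allclose(nt.reconvolve(curve, irf), brute, rtol=1e-10, atol=1e-12)

    def test_peak_shifts_past_irf_center(self, settings):
        irf = nt.gaussian_irf(settings, center=1000.0, fwhm=200.0)
        curve = nt.multiexp_curve(
            nt.MultiExpParams(lifetimes=(266.0,), fractions=(1.0,)), settings
        )
        out = nt.reconvolve(curve, irf)
        assert settings.time_axis[np.argmax(out)] > 1000.0

    def test_commutes_with_amplitude_scaling(self, settings, irf200):
        curve = nt.multiexp_curve(nt.FREE_NADH_25C, settings)
        assert np.allclose(
            nt.reconvolve(3.5 * curve, irf200), 3.5 * nt.reconvolve(curve, irf200)
        )


class TestMeanLifetime:
    def test_equal_lifetimes_collapse(self):
        p = nt.MultiExpParams(lifetimes=(500.0, 500.0001), fractions=(0.3, 0.7))
        assert nt.mean_lifetime(p) == pytest.approx(500.0, abs=1e-3)

    def test_free_nadh_formula_value(self):
        # direct evaluation of sum(a tau^2)/sum(a tau) for (266, 781, 0.793)
        assert nt.mean_lifetime(nt.FREE_NADH_25C) == pytest.approx(489.45, abs=0.01)

    def test_single_component_identity(self):
        p = nt.MultiExpParams(lifetimes=(321.0,), fractions=(1.0,))
        assert nt.mean_lifetime(p) == 321.0

    def test_brackets_component_lifetimes(self):
        for a1 in (0.1, 0.5, 0.9):
            p = nt.MultiExpParams(lifetimes=(266.0, 781.0), fractions=(a1, 1 - a1))
            assert 266.0 <= nt.mean_lifetime(p) <= 781.0


class TestTotalSignalAndSubtraction:
    def test_total_signal_sum(self, settings):
        counts = np.zeros(settings.n_bins)
        counts[:3] = [1, 2, 3]
        h = nt.DecayHistogram(counts=counts, settings=settings)
        assert nt.total_signal(h) == 6

    def test_subtract_scaled_control(self, settings):
        sample = nt.DecayHistogram(counts=np.full(settings.n_bins, 10.0), settings=settings)
        control = nt.DecayHistogram(counts=np.full(settings.n_bins, 5.0), settings=settings)
        out = nt.subtract_control(sample, control, scale=1.0)
        assert np.all(out.counts == 5.0)
        # negative bins are retained, not clipped
        out2 = nt.subtract_control(control, sample, scale=1.0)
        assert np.all(out2.counts == -5.0)

    def test_background_subtraction_preserves_lifetime(self, settings, irf200):
        """Simulate decay + scatter background; subtracting the control keeps
        the fitted lifetime within 1% of the scatter-free fit."""
        rng_seed = 77
        scaled = nt.scale_to_budget(nt.FREE_NADH_25C, settings, 1e6)
        clean = nt.convolve_irf(nt.multiexp_curve(scaled, settings), irf200)
        scatter = np.full(settings.n_bins, 40.0)
        h_clean = nt.sample_histogram(clean, rng_seed, settings)
        h_contam = nt.sample_histogram(clean + scatter, rng_seed, settings)
        h_control = nt.sample_histogram(scatter, rng_seed + 1, settings)
        corrected = nt.subtract_control(h_contam, h_control)
        fit_clean = nt.fit_decay(h_clean, irf200)
        fit_corr = nt.fit_decay(corrected, irf200)
        tm_clean = nt.mean_lifetime(fit_clean.params)
        tm_corr = nt.mean_lifetime(fit_corr.params)
        assert abs(tm_corr - tm_clean) / tm_clean < 0.01


class TestFitDecay:
    @pytest.mark.parametrize(
        "params,fwhm",
        [
            (nt.FREE_NADH_25C, 200.0),
            (nt.FREE_NADH_37C, 200.0),
            (nt.BOUND_NADH, 35.0),
        ],
    )
    def test_noise_free_recovery(self, settings, params, fwhm):
        irf = nt.gaussian_irf(settings, center=1000.0, fwhm=fwhm)
        hist = _noise_free_hist(params, settings, irf)
        res = nt.fit_decay(hist, irf)
        for est, true in zip(res.params.lifetimes, params.lifetimes):
            assert abs(est - true) / true < 1e-4
        for est, true in zip(res.params.fractions, params.fractions):
            assert abs(est - true) / true < 1e-4
        assert abs(res.t0) < 1.0

    def test_lifetimes_ordered_fractions_normalized(self, settings, irf200):
        h = nt.simulate_decay(nt.FREE_NADH_25C, settings, irf200, 3)
        res = nt.fit_decay(h, irf200)
        taus = res.params.lifetimes
        assert all(b > a for a, b in zip(taus, taus[1:]))
        assert sum(res.params.fractions) == pytest.approx(1.0, abs=1e-9)

    def test_single_exponential_with_two_component_model(self, settings, irf200):
        true_tau = 500.0
        p = nt.MultiExpParams(lifetimes=(true_tau,), fractions=(1.0,))
        hist = _noise_free_hist(p, settings, irf200)
        res = nt.fit_decay(hist, irf200, FitSpec(n_components=2))
        t1, t2 = res.params.lifetimes
        tm = nt.mean_lifetime(res.params)
        assert t1 <= true_tau * 1.001 and t2 >= true_tau * 0.999
        assert abs(tm - true_tau) / true_tau < 0.01

    def test_fixed_t0_policy(self, settings, irf200):
        hist = _noise_free_hist(nt.FREE_NADH_25C, settings, irf200)
        res = nt.fit_decay(hist, irf200, FitSpec(t0_policy=0.0))
        assert res.t0 == 0.0
        assert abs(res.params.lifetimes[0] - 266.0) / 266.0 < 1e-4

    def test_all_zero_window_rejected(self, settings, irf200):
        h = nt.DecayHistogram(counts=np.zeros(settings.n_bins), settings=settings)
        with pytest.raises(ValueError, match="zero"):
            nt.fit_decay(h, irf200)

    def test_stochastic_recovery_brief(self, settings, irf200):
        """A couple of 1e6-photon replicates land within the replicate spread."""
        for seed in (11, 12):
            h = nt.simulate_decay(nt.FREE_NADH_25C, settings, irf200, seed)
            res = nt.fit_decay(h, irf200)
            assert abs(res.params.lifetimes[0] - 266.0) < 25.0
            assert abs(res.params.lifetimes[1] - 781.0) < 16.0
            assert abs(res.params.fractions[0] - 0.793) < 0.023
            assert res.chi2_reduced < 1.5


class TestFitBoundFraction:
    def test_noise_free_half_mixture(self, settings, irf35):
        mix = nt.mix_free_bound(nt.FREE_NADH_37C, nt.BOUND_NADH, 0.5)
        hist = _noise_free_hist(mix, settings, irf35)
        f, I0, res = nt.fit_bound_fraction(hist, irf35, nt.FREE_NADH_37C, nt.BOUND_NADH)
        assert f == pytest.approx(0.5, abs=1e-4)

    def test_pure_free_gives_near_zero_fraction(self, settings, irf35):
        h = nt.simulate_decay(nt.FREE_NADH_37C, settings, irf35, 42)
        f, _, _ = nt.fit_bound_fraction(h, irf35, nt.FREE_NADH_37C, nt.BOUND_NADH)
        assert f <= 0.02

    def test_fraction_bounded_even_for_pure_bound(self, settings, irf35):
        h = nt.simulate_decay(nt.BOUND_NADH, settings, irf35, 43)
        f, _, _ = nt.fit_bound_fraction(h, irf35, nt.FREE_NADH_37C, nt.BOUND_NADH)
        assert 0.98 <= f <= 1.0

    def test_identical_shapes_warn(self, settings, irf35):
        h = nt.simulate_decay(nt.FREE_NADH_37C, settings, irf35, 44)
        with pytest.warns(UserWarning, match="ill-conditioned"):
            nt.fit_bound_fraction(h, irf35, nt.FREE_NADH_37C, nt.FREE_NADH_37C)

    def test_titration_tracks_binding_model(self, settings, irf35):
        """Fitted fractions rise monotonically with [LDH] and track the Kd model."""
        nadh, kd = 12.5, 1.5
        ratios = [0.0, 0.25, 0.5, 1.0, 2.0, 4.0]
        conds = [
            nt.BindingCondition(nadh_total=nadh, ldh_total=r * nadh, kd=kd, sites_per_protein=1)
            for r in ratios
        ]
        model = nt.TitrationModel(free_shape=nt.FREE_NADH_37C, bound_shape=nt.BOUND_NADH)
        recs = nt.simulate_condition_series(model, conds, settings, irf35, seed=7)
        fs = [
            nt.fit_bound_fraction(rec.histograms["magic"], irf35, nt.FREE_NADH_37C, nt.BOUND_NADH)[0]
            for rec in recs
        ]
        assert all(b >= a - 1e-6 for a, b in zip(fs, fs[1:]))
        for rec, f in zip(recs, fs):
            assert abs(f - rec.truth["f_int"]) < 0.02
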