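"""Unit and property tests for the synthetic TCSPC generator."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

import nadhtrf as nt
from nadhtrf.simulate import polarized_components, wrapped_exponential


class TestGaussianIRF:
    def test_unit_sum_and_nonnegative(self, settings, irf200):
        assert irf200.values.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(irf200.values >= 0)

    def test_symmetric_about_center(self, settings):
        center = float(settings.time_axis[200])  # exactly on a bin center
        irf = nt.gaussian_irf(settings, center=center, fwhm=200.0)
        peak = int(np.argmax(irf.values))
        assert peak == 200
        # symmetry: weights equidistant from the peak match
        for k in (1, 5, 20):
            assert irf.values[peak - k] == pytest.approx(irf.values[peak + k], rel=1e-9)

    def test_narrower_irf_has_larger_peak_weight(self, settings, irf200, irf35):
        assert irf35.values.max() > irf200.values.max()

    def test_degenerate_fwhm_rejected(self, settings):
        with pytest.raises(ValueError, match="degenerate"):
            nt.gaussian_irf(settings, center=1000.0, fwhm=settings.bin_width / 100)


class TestMultiExpCurve:
    def test_wrap_multiplier_matches_scalar_arithmetic(self, settings):
        # tau=2503 ps, T=25000 ps -> 1/(1 - e^(-9.988)) ~ 1.0000460
        tau = 2503.0
        expected_mult = 1.0 / (1.0 - math.exp(-settings.rep_period / tau))
        t = settings.time_axis
        ratio = wrapped_exponential(tau, settings) / np.exp(-t / tau)
        assert np.allclose(ratio, expected_mult, rtol=1e-12)
        assert expected_mult == pytest.approx(1.0000460, abs=5e-7)

    def test_single_exponential_limit(self, settings):
        params = nt.MultiExpParams(lifetimes=(500.0,), fractions=(1.0,))
        curve = nt.multiexp_curve(params, settings)
        t = settings.time_axis
        ref = np.exp(-t / 500.0)
        ratio = curve / ref
        assert np.allclose(ratio, ratio[0], rtol=1e-12)

    def test_amplitude_linearity(self, settings):
        p1 = nt.MultiExpParams(lifetimes=(266.0, 781.0), fractions=(0.793, 0.207), amplitude=1.0)
        p2 = nt.MultiExpParams(lifetimes=(266.0, 781.0), fractions=(0.793, 0.207), amplitude=2.0)
        assert np.allclose(nt.multiexp_curve(p2, settings), 2 * nt.multiexp_curve(p1, settings))

    @pytest.mark.parametrize("tau", [150.0, 500.0, 2503.0, 5000.0])
    def test_wrap_equals_brute_force_period_sum(self, settings, tau):
        """Closed-form wrap factor vs explicit summation of 50 shifted periods."""
        t = settings.time_axis
        brute = np.zeros_like(t)
        for k in range(50):
            brute += np.exp(-(t + k * settings.rep_period) / tau)
        closed = wrapped_exponential(tau, settings)
        assert np.allclose(closed, brute, rtol=1e-10)

    def test_huge_lifetime_warns(self, settings):
        with pytest.warns(UserWarning, match="wrap"):
            wrapped_exponential(11 * settings.rep_period, settings)

    def test_scale_to_budget_sets_total_counts(self, settings):
        scaled = nt.scale_to_budget(nt.FREE_NADH_25C, settings, 1e6)
        curve = nt.multiexp_curve(scaled, settings)
        assert curve.sum() == pytest.approx(1e6, rel=1e-12)


class TestExpectedPolarized:
    def test_isotropic_limit_channels_proportional(self, settings, irf200):
        aniso = nt.AnisotropyParams(r0=0.0, theta=1000.0, g_factor=1.0)
        scaled = nt.scale_to_budget(nt.FREE_NADH_25C, settings, 3e6)
        par, perp, magic = nt.expected_polarized(scaled, aniso, settings, irf200)
        assert np.allclose(par, perp, rtol=1e-12)
        assert np.allclose(par, magic, rtol=1e-12)

    def test_initial_parallel_perpendicular_ratio(self):
        # r0=0.4 at t=0 (no wrap, pre-IRF): (1+0.8)/(1-0.4) = 3.0
        s = nt.AcquisitionSettings(n_bins=16, bin_width=0.01, rep_period=1e6, photon_budget=1.0)
        params = nt.MultiExpParams(lifetimes=(500.0,), fractions=(1.0,))
        aniso = nt.AnisotropyParams(r0=0.4, theta=1e5)
        S, X = polarized_components(params, aniso, s)
        ratio = (S[0] + 2 * 0.4 * X[0]) / (S[0] - 0.4 * X[0])
        assert ratio == pytest.approx(3.0, abs=1e-5)

    def test_channel_conservation_identity(self, settings, irf35):
        """G=1: parallel + 2*perpendicular = 3*magic per bin on expected curves."""
        scaled = nt.scale_to_budget(nt.BOUND_NADH, settings, 3e6)
        par, perp, magic = nt.expected_polarized(
            scaled, nt.BOUND_ANISOTROPY, settings, irf35
        )
        resid = par + 2 * perp - 3 * magic
        assert np.max(np.abs(resid)) <= 1e-9 * np.max(magic)

    def test_g_factor_attenuates_recorded_perpendicular(self, settings, irf35):
        scaled = nt.scale_to_budget(nt.BOUND_NADH, settings, 3e6)
        a1 = nt.AnisotropyParams(r0=0.35, theta=15900.0, g_factor=1.0)
        a2 = nt.AnisotropyParams(r0=0.35, theta=15900.0, g_factor=1.25)
        _, perp1, _ = nt.expected_polarized(scaled, a1, settings, irf35)
        _, perp2, _ = nt.expected_polarized(scaled, a2, settings, irf35)
        assert np.allclose(perp2, perp1 / 1.25, rtol=1e-12)


class TestSampleHistogram:
    def test_zero_expectation_gives_zero_counts(self, settings):
        hist = nt.sample_histogram(np.zeros(settings.n_bins), 1, settings)
        assert np.all(hist.counts == 0)

    def test_seed_determinism(self, settings):
        expected = np.full(settings.n_bins, 5.0)
        h1 = nt.sample_histogram(expected, 123, settings)
        h2 = nt.sample_histogram(expected, 123, settings)
        assert np.array_equal(h1.counts, h2.counts)

    def test_poisson_mean_of_seeded_draws(self):
        s = nt.AcquisitionSettings(n_bins=2, bin_width=1.0, rep_period=25000.0)
        draws = [
            nt.sample_histogram(np.array([100.0, 0.0]), seed, s).counts[0]
            for seed in range(1000)
        ]
        # 3 sigma / sqrt(1000) band around the expectation of 100
        assert np.mean(draws) == pytest.approx(100.0, abs=1.0)

    def test_negative_expectation_names_bin(self, settings):
        bad = np.zeros(settings.n_bins)
        bad[7] = -1.0
        with pytest.raises(ValueError, match="bin 7"):
            nt.sample_histogram(bad, 1, settings)

    def test_total_counts_near_budget(self, settings, irf200):
        budget = 1e6
        for seed in (1, 2, 3):
            h = nt.simulate_decay(nt.FREE_NADH_25C, settings, irf200, seed, photon_budget=budget)
            assert abs(h.counts.sum() - budget) <= 4 * math.sqrt(budget)


class TestBoundFractions:
    def test_stoichiometric_limit(self):
        # Kd -> 0: everything binds up to the limiting reagent
        cond = nt.BindingCondition(nadh_total=10.0, ldh_total=4.0, kd=1e-9, sites_per_protein=1)
        f_conc, _ = nt.bound_fractions(cond)
        assert f_conc == pytest.approx(0.4, abs=1e-6)

    def test_symmetric_point_quadratic_oracle(self):
        # S = N = Kd -> f_conc = (3 - sqrt(5))/2
        cond = nt.BindingCondition(nadh_total=1.0, ldh_total=1.0, kd=1.0, sites_per_protein=1)
        f_conc, _ = nt.bound_fractions(cond)
        assert f_conc == pytest.approx((3 - math.sqrt(5)) / 2, abs=1e-12)

    def test_unit_brightness_identity(self):
        cond = nt.BindingCondition(
            nadh_total=5.0, ldh_total=2.0, kd=1.0, sites_per_protein=1, brightness_ratio=1.0
        )
        f_conc, f_int = nt.bound_fractions(cond)
        assert f_int == pytest.approx(f_conc, abs=1e-12)

    def test_zero_nadh_rejected(self):
        cond = nt.BindingCondition(nadh_total=0.0, ldh_total=1.0, kd=1.0)
        with pytest.raises(ValueError, match="undefined"):
            nt.bound_fractions(cond)

    @hsettings(derandomize=True, max_examples=100)
    @given(
        ldh=st.floats(0.0, 100.0),
        delta=st.floats(0.01, 50.0),
        kd=st.floats(0.01, 50.0),
        dk=st.floats(0.01, 50.0),
    )
    def test_monotone_in_ldh_and_kd(self, ldh, delta, kd, dk):
        """Bound fraction grows with protein and shrinks with Kd."""
        base = nt.BindingCondition(nadh_total=10.0, ldh_total=ldh, kd=kd, sites_per_protein=2)
        more_ldh = nt.BindingCondition(nadh_total=10.0, ldh_total=ldh + delta, kd=kd, sites_per_protein=2)
        weaker = nt.BindingCondition(nadh_total=10.0, ldh_total=ldh, kd=kd + dk, sites_per_protein=2)
        f0 = nt.bound_fractions(base)[0]
        assert nt.bound_fractions(more_ldh)[0] >= f0 - 1e-12
        assert nt.bound_fractions(weaker)[0] <= f0 + 1e-12


class TestMixFreeBound:
    def test_boundaries_return_pure_shapes(self):
        free, bound = nt.FREE_NADH_37C, nt.BOUND_NADH
        assert nt.mix_free_bound(free, bound, 0.0).lifetimes == free.lifetimes
        assert nt.mix_free_bound(free, bound, 1.0).lifetimes == bound.lifetimes

    def test_intensity_fraction_is_recovered(self):
        free, bound = nt.FREE_NADH_37C, nt.BOUND_NADH
        mix = nt.mix_free_bound(free, bound, 0.3)
        bound_set = set(bound.lifetimes)
        contrib = {
            tau: a * tau for tau, a in zip(mix.lifetimes, mix.fractions)
        }
        total = sum(contrib.values())
        from_bound = sum(v for tau, v in contrib.items() if tau in bound_set)
        assert from_bound / total == pytest.approx(0.3, abs=1e-12)


class TestConditionSeries:
    def test_zero_slopes_reproduce_reference(self, settings, irf200):
        env = nt.EnvironmentModel(
            reference_params=nt.FREE_NADH_25C,
            taum_slope=0.0,
            intensity_slope=0.0,
            anisotropy_slope=0.0,
        )
        [rec] = nt.simulate_condition_series(env, [25.0], settings, irf200, seed=5)
        assert tuple(rec.truth["lifetimes"]) == nt.FREE_NADH_25C.lifetimes
        assert rec.truth["photon_budget"] == settings.photon_budget

    def test_taum_slope_ground_truth(self, settings, irf200):
        """-8 ps/degC: ground-truth tau_m drops by 80 ps per 10 degC step."""
        env = nt.EnvironmentModel(reference_params=nt.FREE_NADH_25C, taum_slope=-8.0)
        recs = nt.simulate_condition_series(env, [25.0, 35.0, 45.0], settings, irf200, seed=5)
        tms = [r.truth["tau_m"] for r in recs]
        assert tms[0] - tms[1] == pytest.approx(80.0, abs=1e-9)
        assert tms[1] - tms[2] == pytest.approx(80.0, abs=1e-9)

    def test_titration_ratio_zero_is_pure_free(self, settings, irf35):
        model = nt.TitrationModel(free_shape=nt.FREE_NADH_37C, bound_shape=nt.BOUND_NADH)
        cond = nt.BindingCondition(nadh_total=12.5, ldh_total=0.0, kd=1.5, sites_per_protein=1)
        [rec] = nt.simulate_condition_series(model, [cond], settings, irf35, seed=5)
        assert tuple(rec.truth["lifetimes"]) == nt.FREE_NADH_37C.lifetimes
        assert rec.truth["f_int"] == 0.0

    def test_out_of_range_temperature_warns(self, settings, irf200):
        env = nt.EnvironmentModel(reference_params=nt.FREE_NADH_25C)
        with pytest.warns(UserWarning, match="outside"):
            nt.simulate_condition_series(env, [50.0], settings, irf200, seed=5)

    def test_series_is_seed_deterministic(self, settings, irf200):
        env = nt.EnvironmentModel(reference_params=nt.FREE_NADH_25C)
        a = nt.simulate_condition_series(env, [25.0, 37.0], settings, irf200, seed=9)
        b = nt.simulate_condition_series(env, [25.0, 37.0], settings, irf200, seed=9)
        for ra, rb in zip(a, b):
            for ch in ra.histograms:
                assert np.array_equal(ra.histograms[ch].counts, rb.histograms[ch].counts)
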