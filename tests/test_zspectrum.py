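"""Signal chain: normalization, WASSR B0 estimation/correction, two-pool
background fit, and the AREX residual metric."""

import warnings

import numpy as np
import pytest

import rnoecest as rc
from rnoecest.errors import (ExtrapolationWarning, InvalidInputError,
                             UnreliableFitError)


class TestNormalize:
    def test_self_normalization(self):
        z = rc.normalize(np.full(5, 0.7), 0.7, np.arange(5.0))
        np.testing.assert_array_equal(z.signal, 1.0)

    def test_arithmetic(self):
        z = rc.normalize([0.3, 0.6], 0.6, [1.0, 2.0])
        np.testing.assert_allclose(z.signal, [0.5, 1.0])

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            rc.normalize([0.5], 0.0, [0.0])

    def test_simulator_round_trip(self, six_pools, invivo_grid):
        truth = rc.simulate_zspectrum(six_pools, invivo_grid, 0.0, 0)
        s0 = 1234.0
        raw = truth.signal * s0
        z = rc.normalize(raw, s0, invivo_grid)
        np.testing.assert_allclose(z.signal, truth.signal, atol=1e-12)


class TestWassr:
    def test_symmetric_dip_centered_at_zero(self):
        z = rc.simulate_zspectrum((rc.PoolSpec(0.0, 0.8, 0.5, "water"),),
                                  rc.WASSR_OFFSETS_PPM, 0.0, 0)
        assert rc.fit_wassr(z) == pytest.approx(0.0, abs=1e-6)

    def test_subgrid_center_recovery(self):
        z = rc.simulate_zspectrum((rc.PoolSpec(0.23, 0.8, 0.5, "water"),),
                                  rc.WASSR_OFFSETS_PPM, 0.0, 0)
        assert rc.fit_wassr(z) == pytest.approx(0.23, abs=1e-3)

    def test_monte_carlo_bias_small(self):
        estimates = []
        for seed in range(500):
            z = rc.simulate_zspectrum((rc.PoolSpec(0.23, 0.8, 0.5, "water"),),
                                      rc.WASSR_OFFSETS_PPM, 0.005, seed)
            estimates.append(rc.fit_wassr(z))
        assert abs(np.mean(estimates) - 0.23) < 0.005

    def test_edge_minimum_rejected(self):
        z = rc.simulate_zspectrum((rc.PoolSpec(1.4, 0.8, 0.5, "water"),),
                                  rc.WASSR_OFFSETS_PPM, 0.0, 0)
        with pytest.raises(UnreliableFitError):
            rc.fit_wassr(z)


class TestB0Correction:
    def test_zero_shift_is_identity(self, six_pools, invivo_grid):
        z = rc.simulate_zspectrum(six_pools, invivo_grid, 0.0, 0)
        out = rc.apply_b0_correction(z, 0.0)
        np.testing.assert_array_equal(out.signal, z.signal)
        assert out.b0_shift == 0.0

    def test_correction_restores_displaced_spectrum(self, six_pools, invivo_grid):
        displaced_pools = tuple(
            rc.PoolSpec(p.center + 0.2, p.amplitude, p.fwhm, p.label)
            for p in six_pools)
        measured = rc.simulate_zspectrum(displaced_pools, invivo_grid, 0.0, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            corrected = rc.apply_b0_correction(measured, 0.2)
        truth = rc.simulate_zspectrum(six_pools, invivo_grid, 0.0, 0)
        interior = np.abs(invivo_grid) <= 3.5
        np.testing.assert_allclose(corrected.signal[interior],
                                   truth.signal[interior], atol=1e-3)
        assert corrected.b0_shift == pytest.approx(0.2)

    def test_shift_then_unshift_bounded_by_interpolation_error(
            self, six_pools, invivo_grid):
        z = rc.simulate_zspectrum(six_pools, invivo_grid, 0.0, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            once = rc.apply_b0_correction(z, 0.3)
            back = rc.apply_b0_correction(once, -0.3)
        interior = np.abs(invivo_grid) <= 3.5
        # single-interpolation error on this grid
        displaced = tuple(rc.PoolSpec(p.center - 0.3, p.amplitude, p.fwhm, p.label)
                          for p in six_pools)
        truth_shift = rc.simulate_zspectrum(displaced, invivo_grid, 0.0, 0)
        single_err = np.max(np.abs(once.signal[interior]
                                   - truth_shift.signal[interior]))
        round_err = np.max(np.abs(back.signal[interior] - z.signal[interior]))
        assert round_err < 2 * single_err + 1e-12

    def test_large_shift_flagged(self, six_pools, invivo_grid):
        z = rc.simulate_zspectrum(six_pools, invivo_grid, 0.0, 0)
        with pytest.warns(ExtrapolationWarning):
            rc.apply_b0_correction(z, 1.4)


class TestTwoPoolFit:
    def test_water_mt_recovery(self, water_mt_pools, invivo_grid):
        z = rc.simulate_zspectrum(water_mt_pools, invivo_grid, 0.0, 0)
        fit = rc.fit_two_pool(z)
        assert fit.water_amp == pytest.approx(0.80, rel=1e-4)
        assert fit.water_fwhm == pytest.approx(1.4, rel=1e-4)
        assert fit.mt_amp == pytest.approx(0.08, rel=1e-4)
        assert fit.mt_fwhm == pytest.approx(25.0, rel=1e-4)
        assert fit.mt_center == pytest.approx(-2.0, abs=1e-3)
        np.testing.assert_allclose(fit.fitted_curve, z.signal, atol=1e-6)

    def test_background_envelope_over_cest_bands(self, six_pools, invivo_grid):
        z = rc.simulate_zspectrum(six_pools, invivo_grid, 0.0, 0)
        fit = rc.fit_two_pool(z)
        bands = ((invivo_grid >= 1.0) & (invivo_grid <= 4.5)) | \
                ((invivo_grid >= -4.5) & (invivo_grid <= -1.0))
        above = fit.fitted_curve[bands] >= z.signal[bands] - 1e-9
        assert above.mean() >= 0.95

    def test_absent_mt_pool_recovered_as_zero(self, invivo_grid):
        z = rc.simulate_zspectrum((rc.PoolSpec(0.0, 0.8, 1.4, "water"),),
                                  invivo_grid, 0.0, 0)
        fit = rc.fit_two_pool(z)
        assert fit.mt_amp < 0.01

    def test_mt_width_exceeds_water_width(self, six_pools, invivo_grid):
        z = rc.simulate_zspectrum(six_pools, invivo_grid, 0.0, 0)
        fit = rc.fit_two_pool(z)
        assert fit.mt_fwhm > fit.water_fwhm

    def test_grid_without_tails_rejected(self):
        offsets = np.linspace(-4, 4, 81)
        z = rc.ZSpectrum(offsets=offsets, signal=np.ones(81))
        with pytest.raises(InvalidInputError):
            rc.fit_two_pool(z)


class TestArexResid:
    def _fit(self, s_fit, f_m):
        return rc.TwoPoolFit(water_amp=0.0, water_fwhm=1.0, water_center=0.0,
                             mt_amp=f_m, mt_fwhm=10.0, mt_center=0.0,
                             fitted_curve=np.asarray(s_fit, float),
                             fit_mask=None)

    def test_null_case_is_exact_zero(self):
        z = rc.ZSpectrum(offsets=np.array([-3.5]), signal=np.array([0.8]))
        ax = rc.arex_resid(z, self._fit([0.8], 0.1), 2.0)
        assert ax.arex[0] == 0.0

    def test_simple_arithmetic(self):
        z = rc.ZSpectrum(offsets=np.array([-3.5]), signal=np.array([0.5]))
        ax = rc.arex_resid(z, self._fit([1.0], 0.0), 1.0)
        assert ax.arex[0] == pytest.approx(100.0, abs=1e-12)

    def test_hand_evaluated_case(self):
        z = rc.ZSpectrum(offsets=np.array([-3.5]), signal=np.array([0.4]))
        ax = rc.arex_resid(z, self._fit([0.5], 0.25), 2.0)
        assert ax.arex[0] == pytest.approx(20.0, abs=1e-12)

    def test_zero_signal_flagged_nan(self):
        z = rc.ZSpectrum(offsets=np.array([-3.5, -1.6]),
                         signal=np.array([0.0, 0.5]))
        ax = rc.arex_resid(z, self._fit([0.5, 0.6], 0.0), 1.0)
        assert np.isnan(ax.arex[0]) and ax.invalid_mask[0]
        assert np.isfinite(ax.arex[1])

    def test_sign_convention_dips_give_positive_arex(
            self, six_pools, invivo_grid):
        z = rc.simulate_zspectrum(six_pools, invivo_grid, 0.0, 0)
        fit = rc.fit_two_pool(z)
        ax = rc.arex_resid(z, fit, 1.8)
        below = z.signal < fit.fitted_curve
        assert np.all(ax.arex[below] > 0)

    def test_intensity_scale_invariance(self, six_pools, invivo_grid):
        truth = rc.simulate_zspectrum(six_pools, invivo_grid, 0.0, 0)
        results = []
        for c in (1.0, 77.7):
            z = rc.normalize(truth.signal * c, c, invivo_grid)
            fit = rc.fit_two_pool(z)
            results.append(rc.arex_resid(z, fit, 1.8).arex)
        # invariance up to least-squares solver tolerance
        np.testing.assert_allclose(results[0], results[1], atol=1e-5)

    def test_peak_location_recovered_end_to_end(self, invivo_grid):
        pools = (rc.PoolSpec(0.0, 0.8, 1.4, "water"),
                 rc.PoolSpec(-2.0, 0.08, 25.0, "mt"),
                 rc.PoolSpec(-3.5, 0.05, 1.2, "rnoe35"))
        z = rc.simulate_zspectrum(pools, invivo_grid, 0.0, 0)
        fit = rc.fit_two_pool(z)
        ax = rc.arex_resid(z, fit, 1.8)
        window = (invivo_grid >= -5) & (invivo_grid <= -2)
        peak = invivo_grid[window][np.argmax(ax.arex[window])]
        assert abs(peak - (-3.5)) <= 0.1 + 1e-9


class TestCsvRoundTrip:
    def test_zspectrum_csv(self, six_pools, invivo_grid, tmp_path):
        z = rc.simulate_zspectrum(six_pools, invivo_grid, 0.0, 0)
        path = tmp_path / "z.csv"
        z.to_csv(path)
        back = rc.ZSpectrum.from_csv(path)
        np.testing.assert_allclose(back.signal, z.signal, atol=1e-12)
        np.testing.assert_allclose(back.offsets, z.offsets, atol=1e-12)
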