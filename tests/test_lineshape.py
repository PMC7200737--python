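"""Line-shape synthesis, processing and fitting on small grids."""

import math

import numpy as np
import pytest

from gpcrdyn import (DecaySeries, FidGrid, GridSpec, ProcessingScheme,
                     Resonance2D, estimate_noise_rms, fit_decay,
                     fit_eta_from_ratio, fit_peaks, monte_carlo_errors,
                     process_spectrum, synthesize_fid)
from gpcrdyn.simulate import gen_relaxation_series

SMALL = GridSpec(n1=48, n2=256, dwell1=0.5e-3, dwell2=0.1642e-3)
NOAPOD = ProcessingScheme(apodization="none")


class TestSynthesize:
    def test_t0_sample_equals_amplitude(self):
        pk = Resonance2D(2.5, 100.0, -200.0, 50.0, 30.0)
        fid = synthesize_fid([pk], SMALL)
        assert fid.data[0, 0] == pytest.approx(2.5)

    def test_no_peaks_no_noise_is_zero(self):
        fid = synthesize_fid([], SMALL)
        assert np.all(fid.data == 0)

    def test_noise_rms_definition(self):
        fid = synthesize_fid([], SMALL, noise_rms=3.0, rng=0)
        assert np.sqrt(np.mean(np.abs(fid.data) ** 2)) == \
            pytest.approx(3.0, rel=0.05)

    def test_magnitude_spectrum_area_matches_lorentzian_amplitude(self):
        # the integral of a 1D complex Lorentzian over frequency equals the
        # t=0 amplitude; in 2D the spectrum integral equals A (closed form)
        pk = Resonance2D(1.0, 200.0, -400.0, 80.0, 60.0)
        fid = synthesize_fid([pk], SMALL)
        spec = process_spectrum(fid, NOAPOD)
        df1 = spec.axis1_hz[1] - spec.axis1_hz[0]
        df2 = spec.axis2_hz[1] - spec.axis2_hz[0]
        # FFT sum identity: sum(spectrum) * df / sw = fid[0,0] contribution
        integral = spec.data.sum() * df1 * df2 * SMALL.dwell1 * SMALL.dwell2
        assert integral.real == pytest.approx(1.0, rel=1e-6)


class TestProcessing:
    def test_one_time_zero_fill_doubles_axes(self):
        fid = synthesize_fid([], SMALL)
        spec = process_spectrum(fid, ProcessingScheme(zero_fill=1))
        assert spec.data.shape == (2 * SMALL.n1, 2 * SMALL.n2)

    def test_pure_sinusoid_peaks_at_its_frequency(self):
        pk = Resonance2D(1.0, 250.0, -500.0, 0.0, 0.0)
        spec = process_spectrum(synthesize_fid([pk], SMALL), NOAPOD)
        i1, i2 = np.unravel_index(np.argmax(np.abs(spec.data)),
                                  spec.data.shape)
        assert spec.axis1_hz[i1] == pytest.approx(250.0, abs=25.0)
        assert spec.axis2_hz[i2] == pytest.approx(-500.0, abs=30.0)

    def test_lorentzian_linewidth_matches_r2_over_pi(self):
        # long acquisition so truncation is negligible; the absorptive
        # (real) lineshape has FWHM = R2/pi, the magnitude one sqrt(3)x that
        grid = GridSpec(n1=4, n2=4096, dwell1=1e-3, dwell2=0.2e-3)
        r2 = 40.0
        pk = Resonance2D(1.0, 0.0, 100.0, 0.0, r2)
        spec = process_spectrum(synthesize_fid([pk], grid), NOAPOD)
        i1 = np.argmax(np.abs(spec.data).max(axis=1))
        for row, expect in ((spec.data[i1].real, r2 / math.pi),
                            (np.abs(spec.data[i1]),
                             math.sqrt(3.0) * r2 / math.pi)):
            half = row.max() / 2.0
            above = spec.axis2_hz[row >= half]
            fwhm = above.max() - above.min()
            assert fwhm == pytest.approx(expect, rel=0.15)

    def test_ppm_axes_follow_carriers(self):
        spec = process_spectrum(synthesize_fid([], SMALL), NOAPOD)
        assert np.allclose(spec.axis1_ppm * SMALL.carrier1, spec.axis1_hz)


class TestNoiseEstimate:
    def test_all_zero_region(self):
        spec = process_spectrum(synthesize_fid([], SMALL), NOAPOD)
        assert estimate_noise_rms(spec, (slice(0, 10), slice(0, 10))) == 0.0

    def test_unit_gaussian_region(self):
        rng = np.random.default_rng(1)
        spec = process_spectrum(synthesize_fid([], SMALL), NOAPOD)
        spec.data = rng.normal(size=spec.data.shape) + 0j
        rms = estimate_noise_rms(spec, (slice(None), slice(None)))
        assert rms == pytest.approx(1.0, rel=0.02)

    def test_peak_overlap_warns(self):
        spec = process_spectrum(synthesize_fid([], SMALL), NOAPOD)
        spec.data = np.full(spec.data.shape, 5.0, dtype=complex)
        spec.data += np.random.default_rng(2).normal(size=spec.data.shape)
        with pytest.warns(UserWarning, match="overlap"):
            estimate_noise_rms(spec, (slice(0, 20), slice(0, 20)))


class TestFitPeaks:
    def test_noise_free_recovery_is_exact(self):
        true = Resonance2D(1.3, 150.0, -300.0, 60.0, 35.0)
        fid = synthesize_fid([true], SMALL)
        fit = fit_peaks(fid, [Resonance2D(1.0, 130.0, -280.0, 45.0, 30.0)])
        assert fit.converged and not fit.at_bounds
        got = fit.peaks[0]
        assert got.amplitude == pytest.approx(1.3, abs=1e-6)
        assert got.freq1 == pytest.approx(150.0, abs=1e-4)
        assert got.r2_1 == pytest.approx(60.0, abs=1e-4)
        assert got.r2_2 == pytest.approx(35.0, abs=1e-4)

    @pytest.mark.parametrize("apod", ["cos2", "none"])
    def test_unbiased_for_any_window(self, apod):
        # model and data share processing, so apodization cannot bias
        scheme = ProcessingScheme(apodization=apod)
        true = Resonance2D(1.0, 100.0, 200.0, 80.0, 40.0)
        fid = synthesize_fid([true], SMALL)
        fit = fit_peaks(fid, [Resonance2D(0.7, 90.0, 210.0, 60.0, 30.0)],
                        scheme)
        assert fit.peaks[0].r2_1 == pytest.approx(80.0, abs=1e-3)

    def test_peak_outside_spectral_width_rejected(self):
        fid = synthesize_fid([], SMALL)
        bad = Resonance2D(1.0, 2.0 / SMALL.dwell1, 0.0, 10.0, 10.0)
        with pytest.raises(ValueError, match="spectral width"):
            fit_peaks(fid, [bad])

    def test_two_overlapping_peaks_jointly_resolved(self):
        peaks = [Resonance2D(1.0, 100.0, -300.0, 60.0, 30.0),
                 Resonance2D(0.25, 160.0, -280.0, 60.0, 30.0)]
        fid = synthesize_fid(peaks, SMALL)
        init = [Resonance2D(0.8, 95.0, -305.0, 50.0, 25.0),
                Resonance2D(0.3, 165.0, -275.0, 50.0, 25.0)]
        fit = fit_peaks(fid, init)
        amps = sorted((p.amplitude for p in fit.peaks), reverse=True)
        assert amps[0] == pytest.approx(1.0, abs=1e-4)
        assert amps[1] == pytest.approx(0.25, abs=1e-4)


class TestMonteCarlo:
    def test_zero_noise_gives_zero_sds(self):
        true = Resonance2D(1.0, 100.0, -300.0, 50.0, 30.0)
        fid = synthesize_fid([true], SMALL)
        fit = fit_peaks(fid, [true])
        fit = monte_carlo_errors(fit, SMALL, noise_rms=0.0, n=5, seed=0)
        assert fit.mc_sd[0]["r2_1"] == pytest.approx(0.0, abs=1e-6)

    def test_sds_scale_linearly_with_noise(self):
        true = Resonance2D(1.0, 100.0, -300.0, 50.0, 30.0)
        fid = synthesize_fid([true], SMALL)
        fit = fit_peaks(fid, [true])
        lo = monte_carlo_errors(fit, SMALL, noise_rms=0.005, n=10, seed=3)
        hi = monte_carlo_errors(fit, SMALL, noise_rms=0.010, n=10, seed=3)
        ratio = hi.mc_sd[0]["r2_1"] / lo.mc_sd[0]["r2_1"]
        assert ratio == pytest.approx(2.0, rel=0.25)

    def test_requires_converged_fit(self):
        from gpcrdyn.lineshape import PeakFitResult
        bad = PeakFitResult(peaks=[], residual_norm=1.0, converged=False,
                            at_bounds=False)
        with pytest.raises(ValueError, match="converged"):
            monte_carlo_errors(bad, SMALL, noise_rms=0.1)

    def test_seeded_reproducibility(self):
        true = Resonance2D(1.0, 100.0, -300.0, 50.0, 30.0)
        fid = synthesize_fid([true], SMALL)
        fit = fit_peaks(fid, [true])
        a = monte_carlo_errors(fit, SMALL, noise_rms=0.01, n=6, seed=11)
        b = monte_carlo_errors(fit, SMALL, noise_rms=0.01, n=6, seed=11)
        assert a.mc_sd[0] == b.mc_sd[0]


class TestDecayFit:
    def test_two_point_closed_form_on_measured_delays(self):
        # R1 delay grid 20 / 2004 ms with amplitude ratio 0.51
        series = DecaySeries(delays=[0.020, 2.004], amplitudes=[1.00, 0.51])
        rate, _ = fit_decay(series)
        assert rate == pytest.approx(0.339, abs=5e-4)

    def test_equal_amplitudes_give_zero_rate(self):
        rate, _ = fit_decay(DecaySeries(delays=[0.0, 1.0],
                                        amplitudes=[0.8, 0.8]))
        assert rate == 0.0

    def test_three_point_recovery_with_noise(self):
        series = gen_relaxation_series(60.0, (0.002, 0.006, 0.012),
                                       noise_frac=0.05, seed=8)
        rate, sd = fit_decay(series, n_mc=200, seed=9)
        assert rate == pytest.approx(60.0, abs=3.0 * sd)

    def test_nonpositive_amplitude_rejected(self):
        with pytest.raises(ValueError):
            fit_decay(DecaySeries(delays=[0.0, 1.0], amplitudes=[1.0, -0.1]))

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            DecaySeries(delays=[0.1], amplitudes=[1.0])


class TestEtaRatio:
    def test_zero_ratio_gives_zero_eta(self):
        assert fit_eta_from_ratio(0.0, 0.012) == 0.0

    def test_closed_form_at_measurement_delay(self):
        assert fit_eta_from_ratio(0.3, 0.012) == pytest.approx(25.8, abs=0.05)

    def test_round_trip_through_tanh_forward_model(self):
        eta, delay = 33.4, 0.012
        assert fit_eta_from_ratio(math.tanh(eta * delay), delay) == \
            pytest.approx(eta, rel=1e-12)

    def test_ratio_bounds_enforced(self):
        with pytest.raises(ValueError):
            fit_eta_from_ratio(1.0, 0.012)
        with pytest.raises(ValueError):
            fit_eta_from_ratio(0.3, 0.0)
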