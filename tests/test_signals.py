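"""Desensitization kinetics, thresholds, spectra and FRET correction."""

import numpy as np
import pytest

from thermogate import signals, synth
from thermogate.signals import (
    CurrentTrace,
    EmissionSpectrum,
    FretTimeCourse,
    activation_threshold,
    correct_fret_ratio,
    dh_degree,
    fit_monoexp,
    fit_skew_gauss,
    read_trace,
    spectral_ratio,
    write_trace,
)


def decay_trace(offset=0.1, amplitude=1.0, tau=5.0, duration=60.0, dt=0.1,
                noise=0.0, seed=None, temp=45.0):
    t = np.arange(0.0, duration, dt)
    y = offset + amplitude * np.exp(-t / tau)
    if noise:
        y = y + noise * amplitude * np.random.default_rng(seed) \
            .standard_normal(len(t))
    return CurrentTrace(t, y, np.full_like(t, temp))


class TestFitMonoexp:
    def test_noiseless_exact_recovery(self):
        fit = fit_monoexp(decay_trace(offset=0.1, amplitude=1.0, tau=5.0))
        assert fit.success
        assert fit.tau == pytest.approx(5.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(1.0, abs=1e-6)
        assert fit.offset == pytest.approx(0.1, abs=1e-6)

    def test_constant_trace_flags_failure(self):
        t = np.arange(0, 10, 0.1)
        fit = fit_monoexp(CurrentTrace(t, np.full_like(t, 3.0),
                                       np.full_like(t, 45.0)))
        assert not fit.success and fit.tau is None

    def test_noisy_recovery_median_error(self):
        """5% peak-amplitude noise, 10 Hz, 60 s: median relative τ error
        across seeded traces stays below 5%."""
        errs = []
        for seed in range(100):
            fit = fit_monoexp(decay_trace(tau=17.3, noise=0.05, seed=seed))
            assert fit.success
            errs.append(abs(fit.tau / 17.3 - 1.0))
        assert np.median(errs) < 0.05

    def test_scale_and_shift_equivariance(self):
        base = decay_trace(offset=0.2, amplitude=2.0, tau=7.0)
        f0 = fit_monoexp(base)
        scaled = CurrentTrace(base.time, 3.5 * base.current,
                              base.temperature)
        fs = fit_monoexp(scaled)
        assert fs.tau == pytest.approx(f0.tau, rel=1e-9)
        assert fs.amplitude == pytest.approx(3.5 * f0.amplitude, rel=1e-9)
        shifted = CurrentTrace(base.time + 100.0, base.current,
                               base.temperature)
        ft = fit_monoexp(shifted)
        assert ft.tau == pytest.approx(f0.tau, rel=1e-9)

    def test_rising_signal_recovered(self):
        t = np.arange(0, 60, 0.1)
        y = 1.0 - 0.8 * np.exp(-t / 12.0)
        fit = fit_monoexp(CurrentTrace(t, y, np.full_like(t, 45.0)))
        assert fit.success and fit.tau == pytest.approx(12.0, abs=1e-6)
        assert fit.amplitude == pytest.approx(-0.8, abs=1e-6)


class TestDhDegree:
    def test_printed_wildtype_style_decay(self):
        """A current decaying from 10 to 0.07 (relative units) has lost
        99.3% of its peak."""
        res = dh_degree(decay_trace(offset=0.07, amplitude=9.93, tau=4.0,
                                    duration=80.0))
        assert res.degree_percent == pytest.approx(99.3, abs=0.05)

    def test_constant_current_zero_degree(self):
        t = np.arange(0, 30, 0.1)
        res = dh_degree(CurrentTrace(t, np.full_like(t, 5.0),
                                     np.full_like(t, 45.0)))
        assert res.degree_percent == 0.0

    def test_complement_identity(self):
        res = dh_degree(decay_trace(offset=0.5, amplitude=1.0, tau=6.0))
        assert res.degree_percent + res.id_over_imax_percent == 100.0
        assert 0.0 <= res.degree_percent <= 100.0

    def test_temperature_excursion_errors(self):
        t = np.arange(0, 30, 0.1)
        temp = np.full_like(t, 45.0)
        temp[200:] = 47.5
        with pytest.raises(ValueError, match="not constant"):
            dh_degree(CurrentTrace(t, np.exp(-t / 5), temp),
                      constant_T_window=(0.0, 30.0))

    def test_window_autodetection_skips_ramp(self):
        """On a ramp-then-hold trace the constant-T window is the hold."""
        tr = synth.synth_current_trace(plateau_fraction=0.5, seed=0,
                                       hold_duration=120.0)
        res = dh_degree(tr)
        t_ramp = tr.spec.params["t_ramp"]
        assert res.window[0] >= t_ramp - 1.5  # ±1 °C admits the ramp tail

    def test_generator_plateau_encodes_degree(self):
        """Plateau fraction 0.573 of peak → degree 42.7% (leak-subtracted
        constant-temperature trace)."""
        tr = synth.synth_current_trace(
            start_T=45.0, hold_T=45.0, leak_25=0.0,
            plateau_fraction=synth.plateau_for_degree(42.7),
            tau_desensitization=40.0, noise_sd=0.0, seed=1)
        res = dh_degree(tr)
        assert res.degree_percent == pytest.approx(42.7, abs=0.5)


class TestActivationThreshold:
    def test_noiseless_breakpoint_exact(self):
        tr = synth.synth_current_trace(threshold_T=40.0, plateau_fraction=1.0,
                                       tau_activation=0.0, noise_sd=0.0,
                                       seed=0, hold_duration=5.0)
        res = activation_threshold(tr, smooth_time=0.0)
        assert res.found
        assert res.threshold_C == pytest.approx(40.0, abs=0.2)

    def test_pure_arrhenius_leak_no_threshold(self):
        t = np.arange(0.0, 23.0, 0.1)
        T = 25.0 + t
        x = 1.0 / (T + 273.15)
        current = 10.0 ** (3.0 - 800.0 * (x - x[0]))  # one Arrhenius line
        res = activation_threshold(CurrentTrace(t, current, T),
                                   smooth_time=0.0)
        assert not res.found and res.threshold_C is None

    def test_scaling_invariance(self):
        tr = synth.synth_current_trace(threshold_T=38.0, plateau_fraction=1.0,
                                       noise_sd=0.02, seed=4,
                                       hold_duration=5.0)
        r1 = activation_threshold(tr)
        r2 = activation_threshold(CurrentTrace(tr.time, 7.0 * tr.current,
                                               tr.temperature))
        assert r2.threshold_C == pytest.approx(r1.threshold_C, abs=1e-9)

    def test_short_ramp_errors(self):
        t = np.arange(0, 5, 0.1)
        T = 30.0 + t  # spans 5 °C only
        with pytest.raises(ValueError, match="15"):
            activation_threshold(CurrentTrace(t, np.ones_like(t), T))

    def test_noisy_recovery_within_one_degree(self):
        ths = []
        for seed in range(50):
            tr = synth.synth_current_trace(threshold_T=35.0,
                                           plateau_fraction=1.0,
                                           noise_sd=0.03, seed=seed,
                                           hold_duration=10.0)
            res = activation_threshold(tr)
            assert res.found
            ths.append(res.threshold_C)
        assert abs(np.mean(ths) - 35.0) < 1.0


class TestSkewGauss:
    def test_symmetric_peak_location(self):
        sp = synth.synth_spectrum(peaks=((1.0, 488.0, 20.0, 0.0),))
        fit = fit_skew_gauss(sp).fit
        assert fit.success
        assert fit.lambda_max == pytest.approx(488.0, abs=0.1)

    def test_blue_shift_recovery(self):
        """An 11 nm generator shift of a skewed peak is recovered within
        0.3 nm from noisy spectra."""
        shifts = []
        for seed in range(10):
            a = fit_skew_gauss(synth.synth_spectrum(
                peaks=((1.0, 492.0, 25.0, 3.0),), noise_sd=0.02,
                seed=seed)).fit.lambda_max
            b = fit_skew_gauss(synth.synth_spectrum(
                peaks=((1.0, 481.0, 25.0, 3.0),), noise_sd=0.02,
                seed=seed + 1000)).fit.lambda_max
            shifts.append(b - a)
        assert np.mean(shifts) == pytest.approx(-11.0, abs=0.3)

    def test_baseline_invariance(self):
        base = synth.synth_spectrum(peaks=((1.0, 490.0, 22.0, 2.0),))
        lifted = EmissionSpectrum(base.wavelength, base.intensity + 0.35)
        a = fit_skew_gauss(base).fit.lambda_max
        b = fit_skew_gauss(lifted).fit.lambda_max
        assert b == pytest.approx(a, abs=0.1)

    def test_too_few_points_errors(self):
        wl = np.linspace(450, 520, 10)
        with pytest.raises(ValueError):
            fit_skew_gauss(EmissionSpectrum(wl, np.exp(-(wl - 488) ** 2)))


class TestSpectralRatio:
    def test_flat_equal_bands_unity(self):
        wl = np.arange(400.0, 601.0)
        sp = EmissionSpectrum(wl, np.ones_like(wl))
        assert spectral_ratio(sp, (420, 460), (500, 540)) \
            == pytest.approx(1.0)

    def test_acceptor_linearity(self):
        sp = synth.synth_spectrum(
            peaks=((1.0, 470.0, 15.0, 0.0), (0.6, 530.0, 15.0, 0.0)))
        doubled = EmissionSpectrum(
            sp.wavelength,
            np.where(sp.wavelength > 505, 2 * sp.intensity, sp.intensity))
        r1 = spectral_ratio(sp, (450, 490), (510, 550))
        r2 = spectral_ratio(doubled, (450, 490), (510, 550))
        assert r2 == pytest.approx(2 * r1, rel=1e-9)

    def test_generator_ratio_series_recovered(self):
        """Acceptor/donor ratios of two-peak spectra track the generated
        amplitude ratio within 2%."""
        got, truth = [], []
        for k, acc in enumerate((0.4, 0.8, 1.2)):
            sp = synth.synth_spectrum(
                peaks=((1.0, 470.0, 12.0, 0.0), (acc, 530.0, 12.0, 0.0)),
                noise_sd=0.005, seed=k)
            got.append(spectral_ratio(sp, (440, 500), (505, 565)))
            truth.append(acc)
        got = np.array(got) / got[0]
        truth = np.array(truth) / truth[0]
        np.testing.assert_allclose(got, truth, rtol=0.02)

    def test_band_validation(self):
        wl = np.arange(400.0, 601.0)
        sp = EmissionSpectrum(wl, np.ones_like(wl))
        with pytest.raises(ValueError, match="overlap"):
            spectral_ratio(sp, (420, 480), (460, 520))
        with pytest.raises(ValueError, match="non-positive"):
            spectral_ratio(sp, (420, 460), (500, 540), background=2.0)


class TestFretCorrection:
    def test_identity_control(self):
        raw, _ = synth.synth_fret_timecourse(noise_sd=0.0, seed=0)
        flatT = np.linspace(20.0, 50.0, 31)
        control = FretTimeCourse(np.arange(31.0), np.ones(31), flatT)
        out = correct_fret_ratio(raw, control)
        np.testing.assert_allclose(out.corrected, raw.ratio)

    def test_exact_inversion_of_control(self):
        raw, control = synth.synth_fret_timecourse(noise_sd=0.0, seed=1)
        out = correct_fret_ratio(raw, control)
        np.testing.assert_allclose(out.corrected,
                                   raw.spec.params["truth"], atol=1e-9)

    def test_extrapolation_errors(self):
        raw, control = synth.synth_fret_timecourse(noise_sd=0.0, seed=2)
        narrow = FretTimeCourse(control.time, control.ratio,
                                control.temperature)
        narrow.temperature = np.clip(control.temperature, 30.0, 40.0)
        with pytest.raises(ValueError, match="control range"):
            correct_fret_ratio(raw, narrow)

    def test_corrected_tau_recovery(self):
        """Noisy raw/control pairs: τ fitted to the corrected ratio is
        within 10% of the generator truth (median over 50 seeds)."""
        taus = []
        for seed in range(50):
            raw, control = synth.synth_fret_timecourse(
                tau=14.9, noise_sd=0.05, seed=seed)
            out = correct_fret_ratio(raw, control)
            t_ramp = raw.spec.params["t_ramp"]
            fit = fit_monoexp(out.as_trace(), window=(t_ramp, raw.time[-1]))
            if fit.success:
                taus.append(fit.tau)
        assert len(taus) >= 45
        assert abs(np.median(taus) / 14.9 - 1.0) < 0.10

    def test_current_and_fret_share_kinetics(self):
        """Generated with one time constant, the current fit and the
        corrected-ratio fit agree within their simulation scatter."""
        tau = 14.0
        cur, fret = [], []
        for seed in range(25):
            tr = synth.synth_current_trace(
                start_T=45.0, hold_T=45.0, leak_25=0.0,
                tau_desensitization=tau, plateau_fraction=0.1,
                noise_sd=0.03, seed=seed, hold_duration=60.0)
            f1 = fit_monoexp(tr)
            raw, control = synth.synth_fret_timecourse(
                tau=tau, noise_sd=0.03, seed=seed + 500)
            out = correct_fret_ratio(raw, control)
            f2 = fit_monoexp(out.as_trace(),
                             window=(raw.spec.params["t_ramp"],
                                     raw.time[-1]))
            if f1.success and f2.success:
                cur.append(f1.tau)
                fret.append(f2.tau)
        m1, m2 = np.mean(cur), np.mean(fret)
        s = np.sqrt(np.var(cur) / len(cur) + np.var(fret) / len(fret))
        assert abs(m1 - m2) < max(3 * s, 0.05 * tau)


class TestTraceIO:
    def test_round_trip(self, tmp_path):
        tr = synth.synth_current_trace(noise_sd=0.01, seed=5,
                                       hold_duration=5.0)
        p = tmp_path / "trace.tsv"
        write_trace(tr, p)
        back = read_trace(p)
        np.testing.assert_allclose(back.current, tr.current)
        np.testing.assert_allclose(back.temperature, tr.temperature)
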