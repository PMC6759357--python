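"""Synthetic cochlea: rectifier identities, filter response, noise floor."""

import dataclasses

import numpy as np
import pytest

from zwuisdp import (
    SimConfig,
    ZwuisStimulus,
    apply_first_order_lpf,
    apply_nonlinearity,
    coherent_dft,
    simulate_recording,
)
from zwuisdp.design import sound_pressure_pa

from conftest import quadratic_dp_oracle

FS = 10000.0


def _tone(freq, amp=1.0, phase_cycles=0.0, duration=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amp * np.cos(2 * np.pi * (freq * t + phase_cycles))


class TestNonlinearity:
    def test_quadratic_single_tone_dc_and_second_harmonic(self):
        u = _tone(100.0, amp=0.5)
        cfg = SimConfig(c1=0.0, c2=1.0, polarity=+1, noise_density_pm_per_rthz=0)
        v = apply_nonlinearity(u, cfg)
        comps = coherent_dft(v, [0.0, 100.0, 200.0], FS)
        assert abs(comps[0]) == pytest.approx(0.5**2 / 2, rel=1e-12)  # DC
        assert abs(comps[1]) < 1e-12  # no fundamental without c1
        assert abs(comps[2]) == pytest.approx(0.5**2 / 2, rel=1e-12)

    def test_quadratic_two_tone_difference_product(self):
        u = _tone(300.0, 0.3) + _tone(700.0, 0.2)
        cfg = SimConfig(c1=0.0, c2=1.0, polarity=+1)
        v = apply_nonlinearity(u, cfg)
        comps = coherent_dft(v, [400.0, 1000.0], FS)
        assert np.allclose(np.abs(comps), 0.3 * 0.2, rtol=1e-12)

    def test_half_wave_fourier_series(self):
        # half-wave rectified cosine: a/pi + a/2 cos + 2a/(3 pi) cos 2th
        a = 0.8
        u = _tone(100.0, a)
        cfg = SimConfig(nonlinearity_kind="half_wave", c1=1.0, polarity=+1)
        v = apply_nonlinearity(u, cfg)
        comps = coherent_dft(v, [0.0, 100.0, 200.0], FS)
        assert abs(comps[0]) == pytest.approx(a / np.pi, rel=1e-3)
        assert abs(comps[1]) == pytest.approx(a / 2, rel=1e-3)
        assert abs(comps[2]) == pytest.approx(2 * a / (3 * np.pi), rel=1e-3)

    def test_boltzmann_small_signal_slope(self):
        cfg = SimConfig(nonlinearity_kind="boltzmann", c1=2.0, polarity=+1)
        eps = 1e-6
        v = apply_nonlinearity(np.array([-eps, 0.0, eps]), cfg)
        slope = (v[2] - v[0]) / (2 * eps)
        assert slope == pytest.approx(2.0, rel=1e-4)
        assert v[1] == pytest.approx(0.0, abs=1e-12)

    def test_unknown_kind_rejected(self):
        cfg = SimConfig()
        object.__setattr__(cfg, "nonlinearity_kind", "cubic")
        with pytest.raises(ValueError, match="unknown nonlinearity"):
            apply_nonlinearity(np.zeros(4), cfg)

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            apply_nonlinearity(np.array([1.0, np.nan]), SimConfig())


class TestFirstOrderLPF:
    def test_gain_and_phase_at_corner(self):
        fc = 500.0
        y = apply_first_order_lpf(_tone(500.0), fc, FS)
        c = coherent_dft(y, 500.0, FS)[0]
        assert 20 * np.log10(abs(c)) == pytest.approx(-3.0103, abs=1e-3)
        assert np.angle(c) / (2 * np.pi) == pytest.approx(-0.125, abs=1e-6)

    def test_17_db_attenuation_2p8_octaves_above_corner(self):
        f = 1741.0  # bin-aligned probe 2.8 octaves above the corner
        fc = f / 2**2.8
        y = apply_first_order_lpf(_tone(f), fc, FS)
        att = -20 * np.log10(abs(coherent_dft(y, f, FS)[0]))
        assert att == pytest.approx(17.0, abs=0.1)

    def test_dc_limit(self):
        fc = 100.0
        y = apply_first_order_lpf(_tone(1.0), fc, FS)
        c = coherent_dft(y, 1.0, FS)[0]
        assert 20 * np.log10(abs(c)) == pytest.approx(0.0, abs=0.001)
        assert abs(np.angle(c)) < 0.011

    def test_invalid_corner_rejected(self):
        with pytest.raises(ValueError):
            apply_first_order_lpf(np.zeros(8), -1.0, FS)
        with pytest.raises(ValueError):
            apply_first_order_lpf(np.zeros(8), FS, FS)


class TestSimulatorAgainstSymbolicOracle:
    @pytest.mark.parametrize("polarity", [+1, -1])
    def test_quadratic_dp_spectrum_matches_trig_expansion(self, polarity):
        """Simulated DP amplitudes equal the closed-form product-to-sum
        expansion on a 4-component complex to 1e-6 relative error."""
        mult = [11, 17, 24, 31]
        base = 10.0
        amps = [0.21, 0.13, 0.08, 0.17]
        phases = [0.12, 0.77, 0.31, 0.55]
        levels = [20 * np.log10(a / (np.sqrt(2) * 20e-6)) for a in amps]
        stim = ZwuisStimulus(base, mult, levels, phases, 1.2, 44100.0)
        cfg = SimConfig(
            c1=0.4, c2=1.7, polarity=polarity,
            corner_frequency_hz=None, motile_gain=1.0, linear_path_gain=0.0,
            noise_density_pm_per_rthz=0.0, sample_rate_hz=44100.0, duration_s=1.2,
        )
        res = simulate_recording(stim, cfg)
        oracle = quadratic_dp_oracle(mult, amps, phases, 0.4, 1.7, polarity)
        freqs = np.array([n * base for n in oracle if n > 0])
        meas = coherent_dft(res.record_nm, freqs, 44100.0)
        for f, c in zip(freqs, meas):
            want = oracle[int(round(f / base))]
            assert abs(c - want) <= 1e-6 * abs(want)

    def test_bilinear_amplitude_scaling(self, desk_stimulus, noiseless_config):
        """Doubling one parent raises its mixed DP2s by 6.02 dB and its
        second harmonic by 12.04 dB."""
        from zwuisdp import measure_dp2

        cfg = dataclasses.replace(noiseless_config, linear_path_gain=0.0)
        t0 = measure_dp2(simulate_recording(desk_stimulus, cfg).record_nm,
                         desk_stimulus, n_segments=12)
        levels = np.array(desk_stimulus.levels_db_spl)
        levels[3] += 20 * np.log10(2)
        t1 = measure_dp2(
            simulate_recording(desk_stimulus.replace_levels(levels), cfg).record_nm,
            desk_stimulus, n_segments=12)
        delta = t1["magnitude_db"] - t0["magnitude_db"]
        k, m = t0["parent_k"], t0["parent_m"]
        touches = (k == 3).astype(int) + (m == 3).astype(int)
        assert np.allclose(delta[touches == 0], 0.0, atol=1e-6)
        assert np.allclose(delta[touches == 1], 6.0206, atol=1e-3)
        assert np.allclose(delta[touches == 2], 12.0412, atol=1e-3)

    def test_envelope_following_component(self, two_tone_stimulus):
        """Negative rectification + 2-kHz low-pass tracks the inverted
        squared stimulus envelope."""
        from scipy.signal import hilbert

        cfg = SimConfig(
            c1=0.0, c2=50.0, polarity=-1, corner_frequency_hz=2000.0,
            motile_gain=1.0, linear_path_gain=0.0,
            noise_density_pm_per_rthz=0.0, duration_s=1.2,
        )
        res = simulate_recording(two_tone_stimulus, cfg)
        p = sound_pressure_pa(two_tone_stimulus)
        env2 = np.abs(hilbert(p)) ** 2
        lo = apply_first_order_lpf(res.record_nm, 2000.0, cfg.sample_rate_hz)
        ref = -apply_first_order_lpf(
            apply_first_order_lpf(env2, 2000.0, cfg.sample_rate_hz),
            2000.0, cfg.sample_rate_hz,
        )
        r = np.corrcoef(lo - lo.mean(), ref - ref.mean())[0, 1]
        assert r > 0.99

    def test_linear_cochlea_produces_no_significant_dp2s(self, desk_stimulus):
        from zwuisdp import measure_dp2

        cfg = SimConfig(c2=0.0, duration_s=1.2, seed=11)
        table = measure_dp2(
            simulate_recording(desk_stimulus, cfg).record_nm, desk_stimulus
        )
        assert table["significant"].mean() < 0.05

    def test_noise_floor_density(self, desk_stimulus):
        """Stimulus off: measured spectral density matches the configured
        pm/rtHz within 10% when averaged over ~1000 bins."""
        cfg = SimConfig(duration_s=1.2, seed=5, sample_rate_hz=111600.0)
        silent = desk_stimulus.replace_levels([-400.0] * desk_stimulus.n_components)
        rec = simulate_recording(silent, cfg).record_nm
        T = cfg.duration_s
        freqs = np.arange(100, 1100) / T
        amps = np.abs(coherent_dft(rec, freqs, cfg.sample_rate_hz))
        density_pm = np.sqrt(np.mean(amps**2) / 2 * T) * 1e3
        assert density_pm == pytest.approx(30.0, rel=0.10)

    def test_ledger_records_effective_input(self, desk_stimulus, noiseless_config):
        from zwuisdp import InputShaping

        cfg = dataclasses.replace(
            noiseless_config,
            input_shaping=InputShaping(kind="tilt", tilt_db_per_octave=-3.0,
                                       ref_hz=4000.0),
        )
        res = simulate_recording(desk_stimulus, cfg)
        want = np.asarray(desk_stimulus.levels_db_spl) - 3.0 * np.log2(
            desk_stimulus.component_frequencies_hz / 4000.0
        )
        assert np.allclose(res.ledger["effective_levels_db"], want, atol=1e-9)
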