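"""Bilinear input retrieval, phase retrieval, and stimulus equalization."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from zwuisdp import (
    InputShaping,
    SimConfig,
    correct_combinatorial,
    equalization_step,
    fit_bilinear_levels,
    fit_primary_phases,
    measure_dp2,
    run_equalization_loop,
    simulate_recording,
    wrap_cycles,
)

NOISELESS = dict(noise_density_pm_per_rthz=0.0, duration_s=1.2)


def _table(stimulus, cfg):
    rec = simulate_recording(stimulus, cfg).record_nm
    return correct_combinatorial(measure_dp2(rec, stimulus))


class TestLevelRetrieval:
    def test_flat_input_recovered_flat(self, desk_stimulus):
        # exactly representable model (no filter): flat to numerical tolerance
        cfg = SimConfig(corner_frequency_hz=None, **NOISELESS)
        eff = fit_bilinear_levels(
            _table(desk_stimulus, cfg), desk_stimulus.n_components, anchor_db=60.0
        )
        assert eff.range_db < 1e-6
        assert np.mean(eff.levels_db) == pytest.approx(60.0, abs=1e-9)
        # realistic motile filter: residual spline mismatch stays below 0.1 dB
        eff2 = fit_bilinear_levels(
            _table(desk_stimulus, SimConfig(**NOISELESS)),
            desk_stimulus.n_components, anchor_db=60.0,
        )
        assert eff2.range_db < 0.1

    @pytest.mark.parametrize("mode", ["octave", "parametric"])
    def test_tilted_input_recovered(self, desk_stimulus, mode):
        """A -3 dB/octave shaped input is retrieved within 0.1 dB RMS up to
        the anchor constant (noiseless)."""
        shaping = InputShaping(kind="tilt", tilt_db_per_octave=-3.0, ref_hz=4000.0)
        fc = 50000.0 if mode == "octave" else 2500.0
        cfg = SimConfig(input_shaping=shaping, corner_frequency_hz=fc, **NOISELESS)
        res = simulate_recording(desk_stimulus, cfg)
        truth = np.asarray(res.ledger["effective_levels_db"])
        eff = fit_bilinear_levels(
            _table(desk_stimulus, cfg),
            desk_stimulus.n_components,
            anchor_db=float(truth.mean()),
            mode=mode,
        )
        err = eff.levels_db - truth
        assert np.sqrt(np.mean(err**2)) < 0.1

    def test_ten_db_primary_span_gives_twenty_db_dp2_span(self, desk_stimulus):
        levels = np.linspace(55.0, 65.0, desk_stimulus.n_components)
        stim = desk_stimulus.replace_levels(levels)
        cfg = SimConfig(corner_frequency_hz=None, linear_path_gain=0.0, **NOISELESS)
        t = _table(stim, cfg)
        dp2_span = t["magnitude_db_corrected"].max() - t["magnitude_db_corrected"].min()
        assert dp2_span == pytest.approx(20.0, abs=0.05)
        eff = fit_bilinear_levels(t, stim.n_components, anchor_db=60.0)
        assert eff.range_db == pytest.approx(10.0, abs=0.05)

    def test_gauge_invariance_of_anchor(self, desk_stimulus):
        """Shifting the anchor shifts all levels by the same constant and
        leaves the fit residual unchanged."""
        cfg = SimConfig(
            input_shaping=InputShaping(kind="tilt", tilt_db_per_octave=-2.0,
                                       ref_hz=4000.0),
            **NOISELESS,
        )
        t = _table(desk_stimulus, cfg)
        e0 = fit_bilinear_levels(t, desk_stimulus.n_components, anchor_db=60.0)
        e1 = fit_bilinear_levels(t, desk_stimulus.n_components, anchor_db=66.0)
        assert np.allclose(e1.levels_db - e0.levels_db, 6.0, atol=1e-9)
        assert e1.residual_rms_db == pytest.approx(e0.residual_rms_db, abs=1e-9)

    def test_all_insignificant_fails(self, desk_stimulus):
        cfg = SimConfig(c2=0.0, duration_s=1.2, seed=2)
        t = _table(desk_stimulus, cfg)
        t = t[~t["significant"].astype(bool) | t["significant"]]  # keep as is
        t["significant"] = False
        with pytest.raises(ValueError, match="no significant"):
            fit_bilinear_levels(t, desk_stimulus.n_components, anchor_db=60.0)

    def test_recorded_motion_is_not_a_proxy_for_ohc_input(self, desk_stimulus):
        """When the direct vibration path is shaped differently from the
        bundle input, the linear component of recorded motion and the
        retrieved effective input disagree — the retrieval is required."""
        from zwuisdp import coherent_dft

        shaping = InputShaping(kind="tilt", tilt_db_per_octave=-4.0, ref_hz=4000.0)
        cfg = SimConfig(
            input_shaping=shaping,
            linear_path_shaping=InputShaping(kind="flat"),
            **NOISELESS,
        )
        res = simulate_recording(desk_stimulus, cfg)
        truth = np.asarray(res.ledger["effective_levels_db"])
        eff = fit_bilinear_levels(
            _table(desk_stimulus, cfg),
            desk_stimulus.n_components,
            anchor_db=float(truth.mean()),
        )
        motion = 20 * np.log10(
            np.abs(
                coherent_dft(
                    res.record_nm,
                    desk_stimulus.component_frequencies_hz,
                    cfg.sample_rate_hz,
                )
            )
        )
        shape_err = lambda a, b: np.sqrt(np.mean((a - a.mean() - b + b.mean()) ** 2))
        assert shape_err(eff.levels_db, truth) < 0.3
        assert shape_err(motion, truth) > 1.0


class TestPhaseRetrieval:
    def test_noiseless_phase_recovery_to_gauge(self, desk_stimulus):
        cfg = SimConfig(corner_frequency_hz=None, linear_path_gain=0.0, **NOISELESS)
        t = _table(desk_stimulus, cfg)
        truth = np.asarray(desk_stimulus.phases_cycles)
        ph, offs, rho, rms = fit_primary_phases(
            t, polarity=-1, anchor_index=0, anchor_phase_cycles=float(truth[0]),
            n_primaries=desk_stimulus.n_components,
        )
        err = wrap_cycles(ph - truth)
        assert np.max(np.abs(err)) < 1e-3
        assert rms < 1e-3

    def test_polarity_flip_moves_band_offsets_not_phases(self, desk_stimulus):
        cfg = SimConfig(corner_frequency_hz=None, linear_path_gain=0.0, **NOISELESS)
        t = _table(desk_stimulus, cfg)
        truth = np.asarray(desk_stimulus.phases_cycles)
        kw = dict(anchor_index=0, anchor_phase_cycles=float(truth[0]),
                  n_primaries=desk_stimulus.n_components)
        ph_neg, off_neg, rho_neg, _ = fit_primary_phases(t, polarity=-1, **kw)
        ph_pos, off_pos, rho_pos, _ = fit_primary_phases(t, polarity=+1, **kw)
        assert np.allclose(wrap_cycles(ph_neg - ph_pos), 0.0, atol=1e-6)
        # the constant 0.5-cycle flip lands in the offset terms, not the phases
        assert abs(abs(wrap_cycles(rho_pos - rho_neg)) - 0.5) < 1e-3
        assert np.allclose(
            [wrap_cycles(off_pos[b] - off_neg[b]) for b in off_pos], 0.0, atol=1e-3
        )

    def test_underdetermined_phases_rejected(self):
        df = pd.DataFrame(
            {
                "parent_k": [1],
                "parent_m": [0],
                "sign": ["+"],
                "frequency_hz": [500.0],
                "phase_cycles": [0.3],
                "significant": [True],
                "sigma_db": [0.1],
            }
        )
        with pytest.raises(ValueError, match="underdetermined"):
            fit_primary_phases(df, n_primaries=2)


class TestEqualization:
    def test_flat_input_is_fixed_point(self, desk_stimulus):
        cfg = SimConfig(corner_frequency_hz=None, **NOISELESS)
        eff = fit_bilinear_levels(
            _table(desk_stimulus, cfg), desk_stimulus.n_components, anchor_db=60.0
        )
        new = equalization_step(desk_stimulus, eff)
        assert np.allclose(new.levels_db_spl, desk_stimulus.levels_db_spl, atol=1e-6)

    def test_one_noiseless_step_flattens_static_tilt(self, desk_stimulus):
        shaping = InputShaping(kind="tilt", tilt_db_per_octave=-6.0, ref_hz=4000.0)
        cfg = SimConfig(input_shaping=shaping, **NOISELESS)
        t = _table(desk_stimulus, cfg)
        eff = fit_bilinear_levels(t, desk_stimulus.n_components, anchor_db=60.0)
        stim1 = equalization_step(desk_stimulus, eff)
        assert np.mean(stim1.levels_db_spl) == pytest.approx(60.0, abs=1e-9)
        eff1 = fit_bilinear_levels(
            _table(stim1, cfg), desk_stimulus.n_components, anchor_db=60.0
        )
        assert eff1.range_db < 0.2

    def test_mean_level_conserved_and_bad_mu_rejected(self, desk_stimulus):
        cfg = SimConfig(**NOISELESS)
        eff = fit_bilinear_levels(
            _table(desk_stimulus, cfg), desk_stimulus.n_components, anchor_db=60.0
        )
        with pytest.raises(ValueError):
            equalization_step(desk_stimulus, eff, mu=1.5)

    def _loop(self, stimulus, cfg, **kw):
        def source(stim, it):
            c = dataclasses.replace(cfg, seed=cfg.seed + it)
            return simulate_recording(stim, c).record_nm

        def analyzer(rec, stim):
            return correct_combinatorial(measure_dp2(rec, stim))

        return run_equalization_loop(stimulus, source, analyzer, **kw)

    def test_noiseless_loop_monotone_until_tolerance(self, desk_stimulus):
        shaping = InputShaping(kind="tilt", tilt_db_per_octave=-6.0, ref_hz=4000.0)
        cfg = SimConfig(input_shaping=shaping, **NOISELESS)
        traj = self._loop(desk_stimulus, cfg, max_iter=4, tol_db=0.5)
        ranges = [t["effective_input"].range_db for t in traj]
        assert all(b < a for a, b in zip(ranges, ranges[1:]))
        assert traj[-1]["max_abs_deviation_db"] < 0.5
        assert len(traj) <= 5

    def test_max_iter_zero_returns_initial_state(self, desk_stimulus):
        cfg = SimConfig(**NOISELESS)
        traj = self._loop(desk_stimulus, cfg, max_iter=0)
        assert len(traj) == 1 and traj[0]["iteration"] == 0

    def test_noisy_loop_reduces_dp2_scatter(self, desk_stimulus):
        """Four adjustment iterations shrink the within-band DP2 scatter
        relative to the unequalized first presentation."""
        shaping = InputShaping(kind="tilt", tilt_db_per_octave=-4.0, ref_hz=4000.0)
        cfg = SimConfig(input_shaping=shaping, duration_s=12.0, seed=9)
        traj = self._loop(desk_stimulus, cfg, max_iter=4, tol_db=0.3)
        assert traj[-1]["dp2_scatter_db"] < traj[0]["dp2_scatter_db"]
        assert (
            traj[-1]["effective_input"].range_db < traj[0]["effective_input"].range_db
        )
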