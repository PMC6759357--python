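"""Synthetic OHC-region vibration records.

The measurement model mirrors the motile pathway the analysis assumes: the
acoustic zwuis stimulus, shaped by a per-frequency input transfer (standing
in for middle-ear and intracochlear propagation), deflects the hair bundles;
a memoryless rectifying nonlinearity generates distortion; the motile
response passes a first-order low-pass filter before appearing as
displacement.  A linear (non-rectified) vibration path and a flat
displacement noise floor are summed on top.  Every ground-truth parameter is
kept in a ledger so downstream stages can be tested as parameter-recovery
problems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .design import ZwuisStimulus, sound_pressure_pa, DB_SPL_1PA

__all__ = [
    "InputShaping",
    "SimConfig",
    "SimResult",
    "apply_nonlinearity",
    "apply_first_order_lpf",
    "simulate_recording",
]


@dataclass
class InputShaping:
    """Per-frequency complex gain applied to the stimulus.

    ``kind`` is one of ``"flat"``, ``"tilt"`` (constant dB/octave slope
    re ``ref_hz``), or ``"table"`` (interpolated gain_db/phase_cycles
    samples).  Models non-flatness of middle-ear transfer and propagation.
    """

    kind: str = "flat"
    tilt_db_per_octave: float = 0.0
    ref_hz: float = 1000.0
    table_freq_hz: list[float] = field(default_factory=list)
    table_gain_db: list[float] = field(default_factory=list)
    table_phase_cycles: list[float] = field(default_factory=list)

    def gain(self, frequencies_hz) -> np.ndarray:
        f = np.atleast_1d(np.asarray(frequencies_hz, dtype=float))
        if self.kind == "flat":
            return np.ones(f.shape, dtype=complex)
        if self.kind == "tilt":
            gdb = self.tilt_db_per_octave * np.log2(f / self.ref_hz)
            return 10.0 ** (gdb / 20.0) + 0j
        if self.kind == "table":
            gdb = np.interp(f, self.table_freq_hz, self.table_gain_db)
            if self.table_phase_cycles:
                ph = np.interp(f, self.table_freq_hz, self.table_phase_cycles)
            else:
                ph = np.zeros_like(f)
            return 10.0 ** (gdb / 20.0) * np.exp(2j * np.pi * ph)
        raise ValueError(f"unknown input shaping kind {self.kind!r}")


@dataclass
class SimConfig:
    """Ground-truth parameters of the synthetic cochlea.

    Units: stimulus pressure in Pa (levels in dB SPL re 20 uPa), displacement
    in nm, positive displacement away from the probe.  The default rectifier
    is quadratic-plus-linear with negative polarity, in line with the
    negative-going rectification seen in vivo; half-wave and Boltzmann
    variants probe robustness of the conclusions to rectifier shape.
    """

    input_shaping: InputShaping = field(default_factory=InputShaping)
    nonlinearity_kind: str = "quadratic"
    polarity: int = -1
    c1: float = 1.0  # linear gain through the nonlinearity (dimensionless)
    c2: float = 50.0  # quadratic coefficient, 1/Pa
    boltzmann_slope: float = 0.02  # Pa
    boltzmann_x0: float = 0.0  # operating point, Pa
    corner_frequency_hz: float | None = 2500.0
    motile_gain: float = 20.0  # nm per nonlinearity-output unit
    linear_path_gain: float = 50.0  # nm/Pa, direct (non-motile) path
    linear_path_shaping: InputShaping | None = None  # defaults to input shaping
    noise_density_pm_per_rthz: float = 30.0
    sample_rate_hz: float = 111600.0
    duration_s: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.polarity not in (+1, -1):
            raise ValueError("polarity must be +1 or -1")
        if self.corner_frequency_hz is not None and self.corner_frequency_hz <= 0:
            raise ValueError("corner frequency must be positive")
        if self.noise_density_pm_per_rthz < 0:
            raise ValueError("noise density must be non-negative")


def apply_nonlinearity(u, config: SimConfig) -> np.ndarray:
    """Memoryless, sample-wise rectifying transfer.

    quadratic: ``v = c1 u + polarity c2 u^2``; half_wave:
    ``v = c1 polarity max(polarity u, 0)``; boltzmann: two-state saturating
    curve through the operating point, scaled to unit small-signal slope
    times ``c1`` and signed by ``polarity``.
    """
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("non-finite samples")
    kind = config.nonlinearity_kind
    pol = config.polarity
    if kind == "quadratic":
        return config.c1 * u + pol * config.c2 * u * u
    if kind == "half_wave":
        return config.c1 * pol * np.maximum(pol * u, 0.0)
    if kind == "boltzmann":
        s = config.boltzmann_slope
        x0 = config.boltzmann_x0
        b = 1.0 / (1.0 + np.exp(-(pol * u - x0) / s))
        b0 = 1.0 / (1.0 + math.exp(x0 / s))
        # normalize to unit slope at the operating point
        slope0 = b0 * (1.0 - b0) / s
        return config.c1 * pol * (b - b0) / slope0
    raise ValueError(f"unknown nonlinearity kind {kind!r}")


def first_order_lpf_response(frequencies_hz, fc_hz: float) -> np.ndarray:
    """Frequency response ``H(f) = 1 / (1 + i f / fc)`` of the motile filter."""
    f = np.asarray(frequencies_hz, dtype=float)
    return 1.0 / (1.0 + 1j * f / fc_hz)


def apply_first_order_lpf(v, fc_hz: float, sample_rate_hz: float) -> np.ndarray:
    """Exact frequency-domain first-order low-pass on a coherent record.

    Each DFT bin is multiplied by ``H(f) = 1/(1 + i f/fc)``: magnitude
    ``-10 log10(1 + (f/fc)^2)`` dB, phase ``-atan(f/fc)/(2 pi)`` cycles.
    """
    if fc_hz is None or fc_hz <= 0:
        raise ValueError("corner frequency must be positive")
    if fc_hz >= sample_rate_hz / 2:
        raise ValueError("corner frequency must lie below Nyquist")
    v = np.asarray(v, dtype=float)
    spec = np.fft.rfft(v)
    f = np.fft.rfftfreq(v.size, d=1.0 / sample_rate_hz)
    return np.fft.irfft(spec * first_order_lpf_response(f, fc_hz), n=v.size)


@dataclass
class SimResult:
    record_nm: np.ndarray
    time_s: np.ndarray
    ledger: dict


def simulate_recording(stimulus: ZwuisStimulus, config: SimConfig) -> SimResult:
    """Compose the full measurement model and record the ground truth.

    ``record = g_lin * u_lin(t) + motile_gain * LPF(NL(u(t))) + noise`` with
    ``u`` the shaped stimulus pressure.  The ledger stores the effective
    per-component input levels/phases at the bundle (what the bilinear
    retrieval should recover), the filter corner, polarity, and all gains.
    """
    cfg = config
    n = int(round(cfg.duration_s * stimulus.sample_rate_hz))
    if abs(cfg.sample_rate_hz - stimulus.sample_rate_hz) > 1e-9:
        raise ValueError("stimulus and simulation sample rates differ")
    if abs(cfg.duration_s * stimulus.base_frequency_hz
           - round(cfg.duration_s * stimulus.base_frequency_hz)) > 1e-9:
        raise ValueError("duration not coherent with the stimulus base frequency")

    if abs(cfg.duration_s - stimulus.duration_s) > 1e-12:
        stimulus = ZwuisStimulus(
            stimulus.base_frequency_hz,
            list(stimulus.multipliers),
            list(stimulus.levels_db_spl),
            list(stimulus.phases_cycles),
            cfg.duration_s,
            stimulus.sample_rate_hz,
        )
    freqs = stimulus.component_frequencies_hz
    shaped = _shaped_stimulus(stimulus, cfg.input_shaping)
    u = sound_pressure_pa(shaped)
    if cfg.linear_path_shaping is None:
        u_lin = u
    else:
        u_lin = sound_pressure_pa(_shaped_stimulus(stimulus, cfg.linear_path_shaping))

    v = apply_nonlinearity(u, cfg)
    if cfg.corner_frequency_hz is not None:
        v = apply_first_order_lpf(v, cfg.corner_frequency_hz, cfg.sample_rate_hz)
    record = cfg.linear_path_gain * u_lin + cfg.motile_gain * v

    if cfg.noise_density_pm_per_rthz > 0:
        rng = np.random.default_rng(cfg.seed)
        sigma_nm = (cfg.noise_density_pm_per_rthz * 1e-3) * math.sqrt(
            cfg.sample_rate_hz / 2.0
        )
        record = record + rng.normal(0.0, sigma_nm, size=n)

    g = cfg.input_shaping.gain(freqs)
    ledger = {
        "effective_levels_db": (
            np.asarray(stimulus.levels_db_spl, dtype=float)
            + 20.0 * np.log10(np.abs(g))
        ).tolist(),
        "effective_phases_cycles": (
            np.mod(np.asarray(stimulus.phases_cycles, dtype=float)
                   + np.angle(g) / (2 * np.pi), 1.0)
        ).tolist(),
        "corner_frequency_hz": cfg.corner_frequency_hz,
        "polarity": cfg.polarity,
        "nonlinearity_kind": cfg.nonlinearity_kind,
        "c1": cfg.c1,
        "c2": cfg.c2,
        "motile_gain": cfg.motile_gain,
        "linear_path_gain": cfg.linear_path_gain,
        "noise_density_pm_per_rthz": cfg.noise_density_pm_per_rthz,
        "seed": cfg.seed,
    }
    t = np.arange(n) / cfg.sample_rate_hz
    return SimResult(record_nm=record, time_s=t, ledger=ledger)


def _shaped_stimulus(stimulus: ZwuisStimulus, shaping: InputShaping) -> ZwuisStimulus:
    g = shaping.gain(stimulus.component_frequencies_hz)
    levels = np.asarray(stimulus.levels_db_spl, dtype=float) + 20 * np.log10(np.abs(g))
    phases = np.mod(
        np.asarray(stimulus.phases_cycles, dtype=float) + np.angle(g) / (2 * np.pi),
        1.0,
    )
    return ZwuisStimulus(
        stimulus.base_frequency_hz,
        list(stimulus.multipliers),
        [float(x) for x in levels],
        [float(x) for x in phases],
        stimulus.duration_s,
        stimulus.sample_rate_hz,
    )
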