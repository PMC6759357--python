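"""Coherent Fourier analysis with Rayleigh phase-stability testing.

Records are analyzed only at stimulus-locked frequencies, i.e. integer
multiples of the reciprocal record duration, so component estimates are
leakage-free.  Statistical significance of a component is assessed by the
Rayleigh test on its phase across coherent sub-segments of the record: a
deterministic, stimulus-locked component keeps the same phase in every
segment (vector strength R near 1), while a noise bin has uniform phases.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ComponentSpectrum",
    "coherent_dft",
    "segment_phasors",
    "rayleigh_test",
    "rayleigh_p",
    "analyze_spectrum",
]


def _bins(frequencies, n_samples: int, sample_rate_hz: float) -> np.ndarray:
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    duration = n_samples / sample_rate_hz
    k = f * duration
    k_round = np.round(k)
    if np.any(np.abs(k - k_round) > 1e-6):
        bad = f[np.abs(k - k_round) > 1e-6]
        raise ValueError(
            f"non-bin-aligned frequencies (leakage would contaminate DP "
            f"estimates): {bad[:5]}"
        )
    if np.any(k_round < 0) or np.any(k_round > n_samples // 2):
        raise ValueError("frequency outside [0, Nyquist]")
    return k_round.astype(int)


def coherent_dft(record, frequencies, sample_rate_hz: float) -> np.ndarray:
    """Complex cosine-convention amplitudes at bin-aligned frequencies.

    Returns ``A * exp(i * 2 pi * phase)`` per frequency such that the
    component is ``A cos(2 pi f t + 2 pi phase)``.  Exact (to rounding) on
    noiseless coherent sinusoids.
    """
    x = np.asarray(record, dtype=float)
    k = _bins(frequencies, x.size, sample_rate_hz)
    spec = np.fft.rfft(x)
    amps = spec[k] * (2.0 / x.size)
    amps[k == 0] /= 2.0
    return amps


def segment_phasors(
    record, frequencies, sample_rate_hz: float, n_segments: int
) -> np.ndarray:
    """Per-segment complex amplitudes, shape ``(n_segments, n_frequencies)``.

    Each segment must itself be coherent for every requested frequency.
    """
    x = np.asarray(record, dtype=float)
    if n_segments < 1 or x.size % n_segments:
        raise ValueError("record length not divisible into segments")
    seg_len = x.size // n_segments
    k = _bins(frequencies, seg_len, sample_rate_hz)
    segs = x.reshape(n_segments, seg_len)
    spec = np.fft.rfft(segs, axis=1)
    amps = spec[:, k] * (2.0 / seg_len)
    amps[:, k == 0] /= 2.0
    return amps


def rayleigh_p(R, n_segments: int, exact: bool = False):
    """Rayleigh-test p value from vector strength R over M segments.

    Default is the large-M exponential approximation ``exp(-M R^2)``; with
    ``exact=True`` the finite-M series correction (Greenwood-Durand) is
    applied.
    """
    K = n_segments * np.square(R)
    p = np.exp(-K)
    if exact:
        M = n_segments
        p = p * (
            1.0
            + (2.0 * K - K**2) / (4.0 * M)
            - (24.0 * K - 132.0 * K**2 + 76.0 * K**3 - 9.0 * K**4)
            / (288.0 * M**2)
        )
    return np.clip(p, np.finfo(float).tiny, 1.0)


def rayleigh_test(
    record,
    frequency,
    n_segments: int = 12,
    sample_rate_hz: float | None = None,
    exact: bool = False,
):
    """Vector strength and p value of phase stability across segments.

    The phase of the component is measured in each of ``n_segments`` coherent
    sub-records; ``R`` is the resultant length of the unit phasors and
    ``p = exp(-M R^2)``.  Fewer than 4 segments is rejected as underpowered.
    """
    if n_segments < 4:
        raise ValueError("Rayleigh test with fewer than 4 segments is underpowered")
    if sample_rate_hz is None:
        raise ValueError("sample_rate_hz is required")
    ph = segment_phasors(record, frequency, sample_rate_hz, n_segments)
    unit = ph / np.abs(ph)
    R = np.abs(unit.mean(axis=0))
    p = rayleigh_p(R, n_segments, exact=exact)
    if np.isscalar(frequency) or np.asarray(frequency).ndim == 0:
        return float(R[0]), float(p[0])
    return R, p


@dataclass
class ComponentSpectrum:
    """Component estimates of one record at stimulus-locked frequencies."""

    frequencies_hz: np.ndarray
    complex_amplitudes: np.ndarray  # cosine convention, record units (nm)
    n_segments: int
    rayleigh_R: np.ndarray
    p_value: np.ndarray
    significant: np.ndarray
    alpha: float
    phasor_sem: np.ndarray | None = None  # complex-amplitude standard error

    @property
    def amplitudes(self) -> np.ndarray:
        return np.abs(self.complex_amplitudes)

    @property
    def phases_cycles(self) -> np.ndarray:
        return np.mod(np.angle(self.complex_amplitudes) / (2 * np.pi), 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies_hz,
                "amplitude_nm": self.amplitudes,
                "phase_cycles": self.phases_cycles,
                "rayleigh_R": self.rayleigh_R,
                "p_value": self.p_value,
                "significant": self.significant,
            }
        )


def analyze_spectrum(
    record,
    frequencies,
    sample_rate_hz: float,
    n_segments: int = 12,
    alpha: float = 0.001,
    exact_rayleigh: bool = False,
) -> ComponentSpectrum:
    """Full coherent analysis: amplitudes, phases and Rayleigh significance.

    The per-component standard error of the complex amplitude is estimated
    from the segment-to-segment scatter of the phasors and is used downstream
    as an inverse-variance weight.
    """
    if n_segments < 4:
        raise ValueError("Rayleigh test with fewer than 4 segments is underpowered")
    f = np.atleast_1d(np.asarray(frequencies, dtype=float))
    amps = coherent_dft(record, f, sample_rate_hz)
    ph = segment_phasors(record, f, sample_rate_hz, n_segments)
    unit = ph / np.where(np.abs(ph) > 0, np.abs(ph), 1.0)
    R = np.abs(unit.mean(axis=0))
    p = rayleigh_p(R, n_segments, exact=exact_rayleigh)
    scatter = ph.var(axis=0, ddof=1) / 2.0  # per-quadrature variance
    sem = np.sqrt(scatter / n_segments)
    return ComponentSpectrum(
        frequencies_hz=f,
        complex_amplitudes=amps,
        n_segments=n_segments,
        rayleigh_R=R,
        p_value=p,
        significant=p < alpha,
        alpha=alpha,
        phasor_sem=sem,
    )
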