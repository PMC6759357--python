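"""Enumeration, attribution, correction and phase prediction of DP2 spectra.

A rectifying nonlinearity driven by an N-tone zwuis complex produces N^2
second-order distortion products (DP2s) at ``f_k + f_m`` (k >= m, including
the second harmonics ``2 f_k``) and ``f_k - f_m`` (k > m).  Under a
uniqueness-certified stimulus each DP2 frequency maps back to exactly one
parent pair, which is what makes the bilinear input retrieval possible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .design import ZwuisStimulus, enumerate_dp_frequencies, validate_uniqueness
from .spectra import analyze_spectrum

__all__ = [
    "COMBINATORIAL_DB",
    "wrap_cycles",
    "attribute_parents",
    "dp2_frequency_table",
    "measure_dp2",
    "correct_combinatorial",
    "predict_phase",
    "apply_band_limit",
]

#: Exact combinatorial deficit of second harmonics under a quadratic
#: rectifier: the 2 f_k term carries half the amplitude of a mixed term.
COMBINATORIAL_DB = 20.0 * np.log10(2.0)


def wrap_cycles(x):
    """Wrap phase (cycles) to the interval (-0.5, 0.5], 0.5 mapped positive."""
    return np.asarray(x) - np.ceil(np.asarray(x) - 0.5)


def attribute_parents(dp_frequency_hz: float, stimulus: ZwuisStimulus):
    """Unique parent signature ``(k, m, sign)`` of a DP2 frequency.

    Requires a uniqueness-passing stimulus; a frequency that matches no
    order-2 combination raises ``ValueError``.
    """
    cert = validate_uniqueness(stimulus.multipliers)
    if not cert.passed:
        raise ValueError("stimulus fails the uniqueness certificate")
    base = stimulus.base_frequency_hz
    mult = dp_frequency_hz / base
    if abs(mult - round(mult)) > 1e-6:
        raise ValueError(f"{dp_frequency_hz} Hz is not a multiple of the base")
    mult = int(round(mult))
    matches = [
        sig for sig, val in enumerate_dp_frequencies(stimulus.multipliers, 2).items()
        if val == mult
    ]
    if not matches:
        raise ValueError(f"{dp_frequency_hz} Hz is not a DP2 of this stimulus")
    assert len(matches) == 1, "multiple signatures under a PASS certificate"
    return matches[0]


def dp2_frequency_table(stimulus: ZwuisStimulus) -> pd.DataFrame:
    """All order-2 combination frequencies of a stimulus, with signatures."""
    rows = []
    for (k, m, sign), mult in enumerate_dp_frequencies(stimulus.multipliers, 2).items():
        rows.append(
            {
                "parent_k": k,
                "parent_m": m,
                "sign": sign,
                "multiple": mult,
                "frequency_hz": mult * stimulus.base_frequency_hz,
                "is_second_harmonic": k == m and sign == "+",
            }
        )
    df = pd.DataFrame(rows).sort_values("frequency_hz").reset_index(drop=True)
    return df


def measure_dp2(
    record,
    stimulus: ZwuisStimulus,
    n_segments: int = 12,
    alpha: float = 0.001,
    require_certificate: bool = True,
) -> pd.DataFrame:
    """Measure the full DP2 catalog of a record.

    Returns one row per order-2 combination below Nyquist with magnitude
    (dB re 1 nm), phase (cycles), Rayleigh statistics, and an amplitude
    standard-error column used as fitting weight downstream.
    """
    cert = validate_uniqueness(stimulus.multipliers)
    if require_certificate and not cert.passed:
        raise ValueError("stimulus fails the uniqueness certificate")
    df = dp2_frequency_table(stimulus)
    if not cert.passed:
        # foreign stimulus: drop combinations colliding with primaries/DP2s
        counts = df["multiple"].value_counts()
        bad = set(counts[counts > 1].index) | set(stimulus.multipliers)
        n_bad = int(df["multiple"].isin(bad).sum())
        if n_bad:
            import warnings

            warnings.warn(f"dropping {n_bad} colliding DP2 entries")
        df = df[~df["multiple"].isin(bad)].reset_index(drop=True)
    nyq = stimulus.sample_rate_hz / 2.0
    df = df[df["frequency_hz"] < nyq].reset_index(drop=True)
    spec = analyze_spectrum(
        record,
        df["frequency_hz"].to_numpy(),
        stimulus.sample_rate_hz,
        n_segments=n_segments,
        alpha=alpha,
    )
    amp = spec.amplitudes
    df["amplitude_nm"] = amp
    df["magnitude_db"] = 20.0 * np.log10(np.maximum(amp, np.finfo(float).tiny))
    df["phase_cycles"] = spec.phases_cycles
    df["rayleigh_R"] = spec.rayleigh_R
    df["p_value"] = spec.p_value
    df["significant"] = spec.significant
    # dB-domain standard error from the segment phasor scatter
    sem = spec.phasor_sem
    df["sigma_db"] = 20.0 / np.log(10.0) * np.divide(
        sem, np.maximum(amp, np.finfo(float).tiny)
    )
    df.attrs["n_segments"] = n_segments
    df.attrs["alpha"] = alpha
    df.attrs["base_frequency_hz"] = stimulus.base_frequency_hz
    return df


def correct_combinatorial(dp2set: pd.DataFrame) -> pd.DataFrame:
    """Add ``magnitude_db_corrected``: +20 log10(2) dB on second harmonics.

    Idempotent: re-applying to an already-corrected table is a no-op.
    """
    df = dp2set.copy()
    if df.attrs.get("combinatorial_corrected", False):
        return df
    if len(df) == 0:
        df["magnitude_db_corrected"] = pd.Series(dtype=float)
    else:
        df["magnitude_db_corrected"] = df["magnitude_db"] + np.where(
            df["is_second_harmonic"], COMBINATORIAL_DB, 0.0
        )
    df.attrs = dict(dp2set.attrs)
    df.attrs["combinatorial_corrected"] = True
    return df


def predict_phase(
    dp2set: pd.DataFrame,
    input_phases_cycles,
    polarity: int = -1,
    include_polarity_offset: bool = True,
) -> pd.DataFrame:
    """Predict DP2 phases from per-primary input phases.

    Sum-type DP2s (and harmonics) predict ``phi_k + phi_m``; difference-type
    predict ``phi_k - phi_m`` with k the higher-frequency parent (the
    conjugated term of the product-to-sum identity).  Negative-polarity
    rectification adds 0.5 cycles when ``include_polarity_offset``; with the
    offset excluded the low-frequency residual itself exposes the polarity.
    Entries with a missing parent phase are flagged and excluded from fits.
    """
    if polarity not in (+1, -1):
        raise ValueError("polarity must be +1 or -1")
    df = dp2set.copy()
    ph = np.asarray(input_phases_cycles, dtype=float)
    k = df["parent_k"].to_numpy()
    m = df["parent_m"].to_numpy()
    ok = np.isfinite(ph[k]) & np.isfinite(ph[m])
    sign = np.where(df["sign"].to_numpy() == "+", 1.0, -1.0)
    pred = ph[k] + sign * ph[m]
    if include_polarity_offset and polarity == -1:
        pred = pred + 0.5
    df["predicted_phase_cycles"] = np.mod(pred, 1.0)
    df["phase_valid"] = ok
    df["phase_residual_cycles"] = wrap_cycles(
        df["phase_cycles"].to_numpy() - pred
    )
    df.loc[~ok, ["predicted_phase_cycles", "phase_residual_cycles"]] = np.nan
    df.attrs = dict(dp2set.attrs)
    return df


def apply_band_limit(
    dp2set: pd.DataFrame, cf_hz: float, fraction: float = 0.5
) -> pd.DataFrame:
    """Retain DP2s at or below ``fraction * cf_hz`` (closed boundary).

    Below CF/2 the travelling wave is fast and non-dispersive, so spatially
    distributed DP2 generation does not interfere; above it the vector sum
    over generation loci obscures the source magnitudes.
    """
    df = dp2set[dp2set["frequency_hz"] <= fraction * cf_hz].reset_index(drop=True)
    df.attrs = dict(dp2set.attrs)
    df.attrs["band_limit_hz"] = fraction * cf_hz
    df.attrs["n_band_limited"] = len(df)
    return df
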