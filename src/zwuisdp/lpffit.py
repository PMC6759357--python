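"""Joint magnitude/phase fitting of a first-order low-pass filter to DP2 data.

The regularized DP2 spectrum of OHC-region vibration follows a first-order
low-pass: magnitude ``K - 10 log10(1 + (f/fc)^2)`` dB and phase
``-atan(f/fc)/(2 pi)`` cycles, with a high-frequency slope of -6 dB/octave
and a -0.25-cycle asymptote.  The corner frequency ``fc`` of the joint fit
is the in vivo estimate of the OHC motility bandwidth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "LPFFit",
    "lpf_magnitude_db",
    "lpf_phase_cycles",
    "posthoc_input_correction",
    "fit_first_order_lpf",
    "corner_vs_cf_report",
]


def lpf_magnitude_db(f_hz, fc_hz, gain_db=0.0):
    return gain_db - 10.0 * np.log10(1.0 + (np.asarray(f_hz, float) / fc_hz) ** 2)


def lpf_phase_cycles(f_hz, fc_hz):
    return -np.arctan(np.asarray(f_hz, float) / fc_hz) / (2.0 * np.pi)


@dataclass
class LPFFit:
    corner_frequency_hz: float
    gain_db: float
    polarity_offset_cycles: float
    explained_variance_fraction: float  # joint, weighted
    explained_variance_magnitude: float
    explained_variance_phase: float
    n_points: int
    weighting_spec: str
    covariance: np.ndarray  # over (log2 fc, K)
    residual_rms_db: float


def posthoc_input_correction(
    dp2set: pd.DataFrame, effective_input
) -> pd.DataFrame:
    """Remove residual input-inequality from corrected DP2 magnitudes.

    ``D_km <- D_km - (L_k - mean L) - (L_m - mean L)``: what the DP2
    magnitudes would have been had the effective input been perfectly equal.
    Phases are untouched — they do not depend on input equalization.
    Entries with an unresolved parent level are dropped.
    """
    if "magnitude_db_corrected" not in dp2set:
        raise ValueError("apply correct_combinatorial first")
    df = dp2set.copy()
    L = np.asarray(effective_input.levels_db, dtype=float)
    dev = L - L.mean()
    k = df["parent_k"].to_numpy()
    m = df["parent_m"].to_numpy()
    ok = np.isfinite(dev[k]) & np.isfinite(dev[m])
    df["magnitude_db_input_corrected"] = (
        df["magnitude_db_corrected"].to_numpy() - dev[k] - dev[m]
    )
    df = df[ok].reset_index(drop=True)
    df.attrs = dict(dp2set.attrs)
    return df


def fit_first_order_lpf(
    frequencies_hz,
    magnitudes_db,
    phase_residuals_cycles=None,
    weights=None,
    s_db_per_cycle: float = 40.0,
    polarity_offset_cycles: float = 0.0,
    fc_grid_hz=None,
) -> LPFFit:
    """Fit ``(fc, K)`` jointly to magnitudes and phase residuals.

    Minimizes the weighted sum of squared magnitude residuals (dB) plus
    squared phase residuals converted to dB-equivalent units by
    ``s_db_per_cycle`` (default 40 dB/cycle, i.e. 0.025 cycle = 1 dB).  The
    optimizer works in ``log2 fc`` with an octave-spaced multi-start grid.
    ``phase_residuals_cycles`` should already have the polarity offset
    removed (or pass it via ``polarity_offset_cycles``).  Explained variance
    is reported jointly on the weighted stacked data and separately per part.
    """
    f = np.asarray(frequencies_hz, dtype=float)
    d = np.asarray(magnitudes_db, dtype=float)
    if f.size != d.size:
        raise ValueError("frequency/magnitude length mismatch")
    if f.size < 4:
        raise ValueError("need at least 4 points")
    span = np.log2(f.max() / f.min())
    if span < 1.5:
        raise ValueError(f"points span only {span:.2f} octaves (< 1.5)")
    w = np.ones_like(f) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w / w.mean())
    have_phase = phase_residuals_cycles is not None
    if have_phase:
        psi = np.asarray(phase_residuals_cycles, float) - polarity_offset_cycles
        if psi.size != f.size:
            raise ValueError("phase length mismatch")

    if fc_grid_hz is None:
        fc_grid_hz = 250.0 * 2.0 ** np.arange(0, 7)  # 0.25-16 kHz

    def residuals(theta):
        fc = 2.0 ** theta[0]
        r = sw * (d - lpf_magnitude_db(f, fc, theta[1]))
        if have_phase:
            r = np.concatenate([r, sw * s_db_per_cycle * (psi - lpf_phase_cycles(f, fc))])
        return r

    def k_closed_form(fc):
        return float(np.sum(w * (d + 10 * np.log10(1 + (f / fc) ** 2))) / np.sum(w))

    best = None
    for fc0 in fc_grid_hz:
        th0 = np.array([np.log2(fc0), k_closed_form(fc0)])
        sol = least_squares(residuals, th0, method="lm", max_nfev=400)
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None or not np.isfinite(best.cost):
        raise RuntimeError("low-pass fit failed to converge from every start")
    fc = float(2.0 ** best.x[0])
    K = float(best.x[1])

    r = residuals(best.x)
    y_mag = sw * d
    y_all = [y_mag]
    if have_phase:
        y_all.append(sw * s_db_per_cycle * psi)
    y = np.concatenate(y_all)
    ss_res = float(np.sum(r**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    ev = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    m_model = lpf_magnitude_db(f, fc, K)
    ev_mag = 1.0 - np.sum(w * (d - m_model) ** 2) / max(
        np.sum(w * (d - np.average(d, weights=w)) ** 2), np.finfo(float).tiny
    )
    if have_phase:
        p_model = lpf_phase_cycles(f, fc)
        ev_ph = 1.0 - np.sum(w * (psi - p_model) ** 2) / max(
            np.sum(w * (psi - np.average(psi, weights=w)) ** 2),
            np.finfo(float).tiny,
        )
    else:
        ev_ph = float("nan")

    dof = max(y.size - 2, 1)
    s2 = ss_res / dof
    J = best.jac
    cov = np.linalg.pinv(J.T @ J) * s2
    return LPFFit(
        corner_frequency_hz=fc,
        gain_db=K,
        polarity_offset_cycles=polarity_offset_cycles,
        explained_variance_fraction=float(ev),
        explained_variance_magnitude=float(ev_mag),
        explained_variance_phase=float(ev_ph),
        n_points=int(f.size),
        weighting_spec=f"inverse-variance; s={s_db_per_cycle} dB/cycle",
        covariance=cov,
        residual_rms_db=float(np.sqrt(ss_res / y.size)),
    )


def corner_vs_cf_report(fits, cfs_hz) -> pd.DataFrame:
    """Octave distance ``log2(CF/fc)`` per recording, with cohort summary.

    The summary row carries the mean and SD across recordings in the
    ``octaves_below_cf`` / ``octaves_sd`` columns.
    """
    fits = list(fits)
    cfs = list(cfs_hz)
    if not fits or len(fits) != len(cfs):
        raise ValueError("need one CF per fit")
    rows = []
    for fit, cf in zip(fits, cfs):
        fc = fit.corner_frequency_hz if isinstance(fit, LPFFit) else float(fit)
        rows.append(
            {
                "cf_hz": cf,
                "corner_frequency_hz": fc,
                "octaves_below_cf": float(np.log2(cf / fc)),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["mean_octaves"] = float(df["octaves_below_cf"].mean())
    df.attrs["sd_octaves"] = float(df["octaves_below_cf"].std(ddof=1)) if len(df) > 1 else 0.0
    return df
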