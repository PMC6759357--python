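"""Retrieval of the effective OHC input from DP2 spectra, and equalization.

The amplitude of a DP2 is proportional to the product of its parents'
amplitudes at the input of the rectifier, so in the log domain

    D_km = L_k + L_m + F(f_km) + C

where ``L_k`` are the per-primary effective input levels, ``F`` collects the
common filtering of the DP2 frequency (the motile low-pass), and ``C`` is a
scale constant.  With a rich, uniquely attributed DP2 catalog this is an
overdetermined linear system: the effective input — which cannot be measured
directly — is recovered by weighted least squares.  Identifiability anchors:
``mean(L_k)`` fixed (default: mean stimulus level), ``F`` at the lowest band
zero.  The retrieved levels drive the iterative stimulus adjustment that
equalizes the input and regularizes the DP2 spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .design import ZwuisStimulus
from .dp2 import wrap_cycles

__all__ = [
    "EffectiveInput",
    "fit_bilinear_levels",
    "fit_primary_phases",
    "equalization_step",
    "run_equalization_loop",
    "assign_octave_bands",
]


@dataclass
class EffectiveInput:
    levels_db: np.ndarray
    level_uncertainties_db: np.ndarray
    phases_cycles: np.ndarray | None
    band_offsets_db: dict
    band_edges_hz: np.ndarray
    reference_convention: str
    n_dp2_used: int
    residual_rms_db: float
    underdetermined: list = field(default_factory=list)
    constant_db: float = 0.0

    @property
    def range_db(self) -> float:
        return float(np.max(self.levels_db) - np.min(self.levels_db))


def assign_octave_bands(frequencies_hz, octave_fraction: float = 1.0):
    """Octave-wide (or fractional-octave) band indices, lowest band 0."""
    f = np.asarray(frequencies_hz, dtype=float)
    f0 = f.min()
    idx = np.floor(np.log2(f / f0) * octave_fraction + 1e-12).astype(int)
    return idx, f0


def _hat_basis(frequencies_hz, octave_fraction: float = 1.0):
    """Piecewise-linear (hat-function) basis over octave-spaced log2-f knots.

    Returns ``(B, knots_hz)`` with ``B[i, j]`` the weight of knot ``j`` for
    frequency ``i``; rows sum to 1.  A smooth frequency-common term expanded
    in this basis follows a first-order filter closely while remaining a
    linear least-squares problem.
    """
    f = np.asarray(frequencies_hz, dtype=float)
    x = np.log2(f)
    step = 1.0 / octave_fraction
    n_seg = max(int(np.ceil((x.max() - x.min()) / step)), 1)
    # knots at log-frequency quantiles: every segment is supported by data
    knots = np.unique(np.quantile(x, np.linspace(0.0, 1.0, n_seg + 1)))
    if knots.size < 2:
        knots = np.array([x.min(), x.min() + 1.0])
    n_k = knots.size
    B = np.zeros((f.size, n_k))
    seg = np.clip(np.searchsorted(knots, x, side="right") - 1, 0, n_k - 2)
    w = (x - knots[seg]) / (knots[seg + 1] - knots[seg])
    B[np.arange(f.size), seg] = 1.0 - w
    B[np.arange(f.size), seg + 1] = w
    return B, 2.0**knots


def _weights(df: pd.DataFrame) -> np.ndarray:
    if "sigma_db" in df and np.all(np.isfinite(df["sigma_db"])) and (
        df["sigma_db"].to_numpy() > 0
    ).all():
        return 1.0 / np.square(df["sigma_db"].to_numpy())
    return np.ones(len(df))


def fit_bilinear_levels(
    dp2set: pd.DataFrame,
    n_primaries: int,
    anchor_db: float,
    mode: str = "octave",
    octave_fraction: float = 1.0,
    significant_only: bool = True,
) -> EffectiveInput:
    """Invert the bilinear DP2 model for the per-primary input levels.

    ``mode="octave"`` (default) expands the common frequency term ``F`` in a
    piecewise-linear basis over octave-spaced log-frequency knots (value at
    the lowest knot pinned to 0); ``mode="bands"`` uses free piecewise-
    constant octave-band offsets; ``mode="parametric"`` replaces them with
    the first-order low-pass form ``F(f) = -10 log10(1 + (f/fc)^2)`` with
    ``fc`` fitted jointly.  Expects the combinatorially corrected magnitudes.
    """
    df = dp2set
    if "magnitude_db_corrected" not in df:
        raise ValueError("apply correct_combinatorial first")
    if significant_only:
        df = df[df["significant"]]
    df = df.reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("no significant DP2s to fit")
    k = df["parent_k"].to_numpy()
    m = df["parent_m"].to_numpy()
    support = np.bincount(np.r_[k, m], minlength=n_primaries)
    under = [int(i) for i in np.flatnonzero(support < 2)]
    d = df["magnitude_db_corrected"].to_numpy()
    w = _weights(df)
    sw = np.sqrt(w)

    # level part: L = anchor + P l, P spanning the zero-mean subspace
    P = np.vstack([np.eye(n_primaries - 1), -np.ones(n_primaries - 1)])
    A_lvl = np.zeros((len(df), n_primaries))
    np.add.at(A_lvl, (np.arange(len(df)), k), 1.0)
    np.add.at(A_lvl, (np.arange(len(df)), m), 1.0)
    X_lvl = A_lvl @ P

    bands, f0 = assign_octave_bands(df["frequency_hz"], octave_fraction)
    n_bands = int(bands.max()) + 1
    edges = f0 * 2.0 ** (np.arange(n_bands + 1) / octave_fraction)

    if mode in ("octave", "bands"):
        if mode == "octave":
            B, knots = _hat_basis(df["frequency_hz"], octave_fraction)
            edges = knots
        else:
            B = np.zeros((len(df), n_bands))
            B[np.arange(len(df)), bands] = 1.0
        n_bands = B.shape[1]
        X = np.hstack([X_lvl, B[:, 1:], np.ones((len(df), 1))])
        y = d - 2.0 * anchor_db
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"rank-deficient bilinear system; primaries with <2 "
                f"significant DP2s: {under}"
            )
        theta, *_ = np.linalg.lstsq(sw[:, None] * X, sw * y, rcond=None)
        resid = y - X @ theta
        nl = n_primaries - 1
        l = P @ theta[:nl]
        offs = np.concatenate([[0.0], theta[nl:nl + n_bands - 1]])
        const = theta[-1]
        dof = max(len(df) - X.shape[1], 1)
        s2 = float(np.sum(w * resid**2) / np.sum(w) * len(df) / dof)
        cov = np.linalg.pinv((sw[:, None] * X).T @ (sw[:, None] * X)) * s2
        lvl_cov = P @ cov[:nl, :nl] @ P.T
        lvl_unc = np.sqrt(np.maximum(np.diag(lvl_cov), 0.0))
        band_offsets = {int(b): float(offs[b]) for b in range(n_bands)}
    elif mode == "parametric":
        f = df["frequency_hz"].to_numpy()

        def model(th):
            l = P @ th[: n_primaries - 1]
            fc = 2.0 ** th[-2]
            C = th[-1]
            return (
                (l[k] + l[m]) + 2.0 * anchor_db
                - 10.0 * np.log10(1.0 + (f / fc) ** 2) + C
            )

        def fun(th):
            return sw * (d - model(th))

        th0 = np.zeros(n_primaries + 1)
        th0[-2] = np.log2(np.median(f))
        th0[-1] = np.median(d) - 2.0 * anchor_db
        sol = least_squares(fun, th0)
        l = P @ sol.x[: n_primaries - 1]
        fc = 2.0 ** sol.x[-2]
        const = sol.x[-1]
        resid = d - model(sol.x)
        band_offsets = {"fc_hz": float(fc)}
        J = sol.jac
        dof = max(len(df) - len(sol.x), 1)
        s2 = float(np.sum(sol.fun**2) / dof)
        cov = np.linalg.pinv(J.T @ J) * s2
        nl = n_primaries - 1
        lvl_cov = P @ cov[:nl, :nl] @ P.T
        lvl_unc = np.sqrt(np.maximum(np.diag(lvl_cov), 0.0))
    else:
        raise ValueError(f"unknown mode {mode!r}")

    rms = float(np.sqrt(np.sum(w * resid**2) / np.sum(w)))
    return EffectiveInput(
        levels_db=anchor_db + l,
        level_uncertainties_db=lvl_unc,
        phases_cycles=None,
        band_offsets_db=band_offsets,
        band_edges_hz=edges,
        reference_convention=f"mean(L)={anchor_db:.3f} dB; F(lowest band)=0",
        n_dp2_used=len(df),
        residual_rms_db=rms,
        underdetermined=under,
        constant_db=float(const),
    )


def fit_primary_phases(
    dp2set: pd.DataFrame,
    polarity: int = -1,
    anchor_index: int = 0,
    anchor_phase_cycles: float = 0.0,
    n_primaries: int | None = None,
    octave_fraction: float = 1.0,
    significant_only: bool = True,
):
    """Least-squares per-primary input phases from DP2 phases.

    Model: ``psi_km = phi_k +/- phi_m + Psi_b(f_km) + rho`` (plus 0.5 cycles
    for negative polarity), solved on wrapped residuals with an
    iterated-rewrap linear solve followed by a nonlinear polish, avoiding
    wrap discontinuities.  Gauge: one primary phase anchored, lowest-band
    offset zero.  Returns ``(phases_cycles, band_offsets, rho, rms_cycles)``.
    """
    df = dp2set
    if significant_only:
        df = df[df["significant"]]
    if "phase_valid" in df:
        df = df[df["phase_valid"]]
    df = df.reset_index(drop=True)
    k = df["parent_k"].to_numpy()
    m = df["parent_m"].to_numpy()
    if n_primaries is None:
        n_primaries = int(max(k.max(), m.max())) + 1
    support = np.bincount(np.r_[k, m], minlength=n_primaries)
    if np.any(support < 2):
        raise ValueError(
            f"underdetermined phases for primaries {np.flatnonzero(support < 2).tolist()}"
        )
    sign = np.where(df["sign"].to_numpy() == "+", 1.0, -1.0)
    # fit the raw phases; the polarity offset is folded into rho afterwards,
    # so both polarity conventions share the identical numerical problem
    psi = df["phase_cycles"].to_numpy().astype(float)
    w = _weights(df)
    sw = np.sqrt(w)
    B, _knots = _hat_basis(df["frequency_hz"], octave_fraction)
    n_bands = B.shape[1]

    # unknowns: phi (except anchor), Psi at knots (except the first), rho
    free = [i for i in range(n_primaries) if i != anchor_index]
    col = {p: i for i, p in enumerate(free)}
    n_free = len(free)
    X = np.zeros((len(df), n_free + n_bands - 1 + 1))
    base = np.full(len(df), 0.0)
    for r in range(len(df)):
        for p, s in ((k[r], 1.0), (m[r], sign[r])):
            if p == anchor_index:
                base[r] += s * anchor_phase_cycles
            else:
                X[r, col[p]] += s
        X[r, n_free:n_free + n_bands - 1] = B[r, 1:]
    X[:, -1] = 1.0

    # initialize by alternating phasor synchronization: unknown unit phasors
    # u_p = exp(i 2 pi phi_p) and per-band constants soak up Psi + rho
    bands_c, _f0 = assign_octave_bands(df["frequency_hz"], octave_fraction)
    u = np.ones(n_primaries, dtype=complex)
    u[anchor_index] = np.exp(2j * np.pi * anchor_phase_cycles)
    e_obs = np.exp(2j * np.pi * psi)
    cb = np.ones(int(bands_c.max()) + 1, dtype=complex)
    for _ in range(200):
        pred = u[k] * np.where(sign > 0, u[m], np.conj(u[m]))
        z = e_obs * np.conj(pred)
        for b in np.unique(bands_c):
            acc = np.sum(w[bands_c == b] * z[bands_c == b])
            if abs(acc) > 0:
                cb[b] = acc / abs(acc)
        u_new = u.copy()
        for p in range(n_primaries):
            if p == anchor_index:
                continue
            rows = np.flatnonzero(((k == p) | (m == p)) & (k != m))
            ests = []
            for r in rows:
                e = e_obs[r] * np.conj(cb[bands_c[r]])
                if k[r] == p:
                    ests.append(w[r] * (e * (np.conj(u[m[r]]) if sign[r] > 0 else u[m[r]])))
                else:  # m[r] == p
                    ests.append(
                        w[r] * (e * np.conj(u[k[r]]) if sign[r] > 0
                                else u[k[r]] * np.conj(e))
                    )
            if ests:
                acc = np.sum(ests)
                if abs(acc) > 0:
                    u_new[p] = acc / abs(acc)
        if np.max(np.abs(u_new - u)) < 1e-13:
            u = u_new
            break
        u = u_new
    theta = np.zeros(X.shape[1])
    phi0 = np.angle(u) / (2 * np.pi)
    for p, i in col.items():
        theta[i] = phi0[p]
    # initialize the smooth offset term from the synchronization phasors so
    # no residual starts at the wrap boundary
    pred = u[k] * np.where(sign > 0, u[m], np.conj(u[m]))
    z = e_obs * np.conj(pred)
    knot_phase = np.zeros(n_bands)
    for j in range(n_bands):
        acc = np.sum(w * B[:, j] * z)
        knot_phase[j] = np.angle(acc) / (2 * np.pi) if abs(acc) > 0 else 0.0
    theta[-1] = knot_phase[0]
    theta[n_free:n_free + n_bands - 1] = wrap_cycles(knot_phase[1:] - knot_phase[0])
    for _ in range(60):
        new, *_ = np.linalg.lstsq(
            sw[:, None] * X,
            sw * (X @ theta + wrap_cycles(psi - base - X @ theta)),
            rcond=None,
        )
        if np.max(np.abs(new - theta)) < 1e-12:
            theta = new
            break
        theta = new

    def fun(th):
        return sw * wrap_cycles(psi - base - X @ th)

    sol = least_squares(fun, theta)
    theta = sol.x
    resid = wrap_cycles(psi - base - X @ theta)
    rms = float(np.sqrt(np.sum(w * resid**2) / np.sum(w)))
    phases = np.empty(n_primaries)
    phases[anchor_index] = anchor_phase_cycles
    for p, i in col.items():
        phases[p] = theta[i]
    offsets = np.concatenate([[0.0], theta[n_free:n_free + n_bands - 1]])
    rho = float(theta[-1]) - (0.5 if polarity == -1 else 0.0)
    return np.mod(phases, 1.0), {int(b): float(offsets[b]) for b in range(n_bands)}, rho, rms


def equalization_step(
    stimulus: ZwuisStimulus,
    effective_input: EffectiveInput,
    mu: float = 1.0,
) -> ZwuisStimulus:
    """One stimulus adjustment toward a flat effective input.

    Subtracts the retrieved level deviations (damped by ``mu``) from the
    component levels and renormalizes so the mean level in dB SPL is
    unchanged; frequencies and phases are untouched.
    """
    if not 0.0 < mu <= 1.0:
        raise ValueError("mu must lie in (0, 1]")
    L = np.asarray(effective_input.levels_db, dtype=float)
    cur = np.asarray(stimulus.levels_db_spl, dtype=float)
    new = cur - mu * (L - L.mean())
    new = new - new.mean() + cur.mean()
    return stimulus.replace_levels(new)


def run_equalization_loop(
    stimulus: ZwuisStimulus,
    source,
    analyzer,
    max_iter: int = 4,
    tol_db: float = 1.0,
    mu: float = 1.0,
    retrieval_kwargs: dict | None = None,
):
    """Iterate measure -> retrieve -> adjust until the input is flat.

    ``source(stimulus, iteration)`` returns a record; ``analyzer(record,
    stimulus)`` returns the corrected, band-limited DP2 table.  Stops when
    ``max|L_k - mean L| < tol_db`` or after ``max_iter`` adjustments.  If the
    input range grows two steps running the step gain is halved.  Returns the
    full trajectory, one entry per measurement.
    """
    kw = dict(retrieval_kwargs or {})
    trajectory = []
    grow = 0
    prev_range = None
    for it in range(max_iter + 1):
        record = source(stimulus, it)
        table = analyzer(record, stimulus)
        eff = fit_bilinear_levels(
            table,
            n_primaries=stimulus.n_components,
            anchor_db=float(np.mean(stimulus.levels_db_spl)),
            **kw,
        )
        dev = np.max(np.abs(eff.levels_db - eff.levels_db.mean()))
        scatter = _band_scatter_db(table)
        trajectory.append(
            {
                "iteration": it,
                "stimulus": stimulus,
                "dp2": table,
                "effective_input": eff,
                "max_abs_deviation_db": float(dev),
                "dp2_scatter_db": scatter,
                "mu": mu,
            }
        )
        if dev < tol_db or it == max_iter:
            break
        if prev_range is not None and eff.range_db > prev_range:
            grow += 1
            if grow >= 2:
                mu = mu / 2.0
                import warnings

                warnings.warn(f"equalization diverging; damping step to mu={mu}")
                grow = 0
        else:
            grow = 0
        prev_range = eff.range_db
        stimulus = equalization_step(stimulus, eff, mu=mu)
    return trajectory


def _band_scatter_db(table: pd.DataFrame) -> float:
    """Mean within-octave-band spread (std) of corrected DP2 magnitudes."""
    df = table[table["significant"]] if "significant" in table else table
    if len(df) < 2:
        return float("nan")
    col = (
        "magnitude_db_corrected"
        if "magnitude_db_corrected" in df
        else "magnitude_db"
    )
    bands, _ = assign_octave_bands(df["frequency_hz"])
    out = []
    for b in np.unique(bands):
        v = df[col].to_numpy()[bands == b]
        if v.size >= 2:
            out.append(np.std(v))
    return float(np.mean(out)) if out else float("nan")
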