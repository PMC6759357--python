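#!/usr/bin/env python
"""DP2 spectrum of a zwuis-driven recording and its 6-dB/octave roll-off.

Designs a 12-tone zwuis below CF/2 (CF = 16 kHz), records 12 s of synthetic
OHC-region vibration at the default noise floor, measures all 144 uniquely
attributable DP2s, and fits the first-order roll-off.  Writes the DP2 table
under results/.
"""

from pathlib import Path

import numpy as np

from zwuisdp import (
    DesignConstraints,
    SimConfig,
    apply_band_limit,
    correct_combinatorial,
    design_zwuis,
    fit_first_order_lpf,
    measure_dp2,
    simulate_recording,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

CF = 16000.0
constraints = DesignConstraints(
    n_components=12, f_min_hz=2000.0, f_max_hz=12000.0, cf_hz=CF, seed=1
)
stim = design_zwuis(constraints)
print(
    f"designed {stim.n_components} components, "
    f"{stim.component_frequencies_hz.min():.0f}-"
    f"{stim.component_frequencies_hz.max():.0f} Hz, all DP2s uniquely attributable"
)

cfg = SimConfig(seed=1)
res = simulate_recording(stim, cfg)
table = correct_combinatorial(measure_dp2(res.record_nm, stim))
table = apply_band_limit(table, CF)
table.to_csv(OUT / "dp2_spectrum.csv", index=False)

sig = table[table["significant"]]
print(
    f"{len(sig)}/{len(table)} DP2s Rayleigh-significant below CF/2 "
    f"(alpha = {table.attrs['alpha']})"
)
fit = fit_first_order_lpf(
    sig["frequency_hz"].to_numpy(),
    sig["magnitude_db_corrected"].to_numpy(),
    weights=1.0 / np.square(sig["sigma_db"].to_numpy()),
)
print(
    f"magnitude-only first-order fit: corner {fit.corner_frequency_hz:.0f} Hz "
    f"(ground truth {cfg.corner_frequency_hz:.0f} Hz), "
    f"EV {fit.explained_variance_magnitude:.2f}"
)
print("high-frequency roll-off approaches 6 dB/octave, as expected for a "
      "rectifier followed by a first-order low-pass")
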