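#!/usr/bin/env python
"""Two-tone rectification demo: the envelope-following motile component.

Drives the synthetic cochlea with the classic 4600 + 5400 Hz pair at
70 dB SPL and shows that the negative-going rectified pathway produces (i) a
low-frequency displacement component that tracks the inverted stimulus
envelope and (ii) a quadratic difference tone at 800 Hz.  Writes a decimated
waveform excerpt and a component table under results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import hilbert

from zwuisdp import (
    SimConfig,
    ZwuisStimulus,
    apply_first_order_lpf,
    coherent_dft,
    simulate_recording,
)
from zwuisdp.design import sound_pressure_pa

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

stim = ZwuisStimulus(
    base_frequency_hz=200.0,
    multipliers=[23, 27],  # 4600 and 5400 Hz
    levels_db_spl=[70.0, 70.0],
    phases_cycles=[0.0, 0.0],
    duration_s=1.0,
    sample_rate_hz=111600.0,
)
cfg = SimConfig(duration_s=1.0, seed=0)
res = simulate_recording(stim, cfg)

# envelope-following component: low-pass both record and squared envelope
p = sound_pressure_pa(stim)
env2 = np.abs(hilbert(p)) ** 2
lo = apply_first_order_lpf(res.record_nm, 2000.0, cfg.sample_rate_hz)
ref = -apply_first_order_lpf(
    apply_first_order_lpf(env2, 2000.0, cfg.sample_rate_hz), 2000.0,
    cfg.sample_rate_hz,
)
r = np.corrcoef(lo - lo.mean(), ref - ref.mean())[0, 1]

probe = [800.0, 4600.0, 5400.0, 10000.0]
amps = np.abs(coherent_dft(res.record_nm, probe, cfg.sample_rate_hz))
table = pd.DataFrame(
    {
        "frequency_hz": probe,
        "component": ["f2-f1", "f1", "f2", "f1+f2"],
        "amplitude_nm": amps,
    }
)
table.to_csv(OUT / "two_tone_components.csv", index=False)

step = 50  # ~2.2 kHz excerpt sampling is enough to draw the envelope
excerpt = slice(0, int(0.02 * cfg.sample_rate_hz))
pd.DataFrame(
    {
        "time_s": res.time_s[excerpt][::step],
        "displacement_nm": res.record_nm[excerpt][::step],
        "lowpassed_nm": lo[excerpt][::step],
    }
).to_csv(OUT / "two_tone_waveform_excerpt.csv", index=False)

print(f"correlation of low-passed record with inverted squared envelope: {r:.3f}")
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print(
    "the 800-Hz quadratic difference tone and the envelope-following "
    "component are signatures of rectification in the motile path"
)
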