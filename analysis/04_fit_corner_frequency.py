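#!/usr/bin/env python
"""Corner frequencies of a synthetic cohort: the full pipeline per recording.

Runs the closed-loop experiment end to end (design, equalize, post-hoc
correct, joint magnitude/phase fit) for five synthetic recording sites with
characteristic frequencies between 13 and 25 kHz and ground-truth motile
corners drawn from 2.1-3.3 kHz.  Reports fitted corners, explained
variances, and the octave distance between corner and CF.
"""

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from zwuisdp import RunConfig, corner_vs_cf_report, run_all
from zwuisdp.lpffit import LPFFit

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

rng = np.random.default_rng(2024)
cfs = np.linspace(13000.0, 25000.0, 5)
true_fcs = rng.uniform(2100.0, 3300.0, size=5)

rows = []
for i, (cf, fc_true) in enumerate(zip(cfs, true_fcs)):
    base = RunConfig(seed=100 + i)
    cfg = dataclasses.replace(
        base,
        design=dataclasses.replace(
            base.design, f_min_hz=max(cf / 8.0, 1500.0), f_max_hz=cf, cf_hz=cf
        ),
        sim=dataclasses.replace(base.sim, corner_frequency_hz=float(fc_true)),
    )
    rep = run_all(cfg)
    rows.append(
        {
            "cf_hz": cf,
            "true_corner_hz": fc_true,
            "fitted_corner_hz": rep["corner_frequency_hz"],
            "explained_variance": rep["explained_variance"],
            "octaves_below_cf": rep["octaves_below_cf"],
            "n_dp2": rep["n_dp2_used"],
        }
    )

df = pd.DataFrame(rows)
df.to_csv(OUT / "corner_frequencies.csv", index=False)

report = corner_vs_cf_report(df["fitted_corner_hz"].tolist(), df["cf_hz"].tolist())
print(df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
err = np.abs(df["fitted_corner_hz"] / df["true_corner_hz"] - 1)
print(
    f"corner recovery: median |error| {100 * err.median():.1f}%; "
    f"corners lie {report.attrs['mean_octaves']:.1f} +/- "
    f"{report.attrs['sd_octaves']:.1f} octaves below CF; "
    f"explained variance {df['explained_variance'].min():.2f}-"
    f"{df['explained_variance'].max():.2f}"
)
print("a corner a few kHz below CF means the motile response follows the "
      "stimulus envelope rather than its fine structure at this location")
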