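# zwuisdp

**System identification of outer-hair-cell motility from distortion-product
spectra.**

Outer hair cells (OHCs) of the mammalian cochlea convert sound-evoked hair
bundle deflection into somatic length changes (electromotility). Whether
this motile feedback can operate cycle by cycle at high frequencies is
limited by low-pass filtering of the receptor potential — the classic *RC
problem*. Because the OHC transduction current is strongly rectified, the
motile response carries second-order distortion products (DP2s) at the sums
and differences `f_k ± f_m` of the stimulus frequencies, and the shape of
the DP2 spectrum exposes the filter that sits between rectification and
motion. This package implements, end to end and fully in silico, the
analysis chain that turns single-point vibration recordings into an
estimate of the OHC corner frequency:

1. **Zwuis stimulus design** — multitone complexes whose component
   frequencies are integer multiples of a base frequency, chosen so that
   every intermodulation product up to third order is uniquely attributable
   to its parent primaries. An N-tone zwuis yields exactly N² distinct
   DP2s.
2. **Synthetic cochlea** — shaped input → memoryless rectifier (quadratic,
   half-wave or Boltzmann; negative polarity by default) → first-order
   low-pass motile path, summed with a linear vibration path and a flat
   displacement noise floor (30 pm/√Hz), sampled at 111.6 kHz.
3. **Coherent spectral analysis** — leakage-free DFT at stimulus-locked
   frequencies with Rayleigh phase-stability tests (`p = exp(−M R²)` over
   M record segments).
4. **DP2 catalog** — parent attribution, the +6.02 dB (= 20 log₁₀2)
   combinatorial correction of second harmonics, the CF/2 band limit that
   avoids travelling-wave interference, and phase predictions
   `φ_k ± φ_m (+ ½ cycle for negative polarity)`.
5. **Effective-input retrieval and equalization** — the bilinear law
   `D_km = L_k + L_m + F(f_km) + C` (DP2 amplitude ∝ product of parent
   amplitudes) inverted by weighted linear least squares for the per-primary
   input levels `L_k`, which drive an iterative stimulus adjustment that
   flattens the input at the bundle and regularizes the DP2 spectrum.
6. **Corner-frequency estimation** — joint weighted fit of
   `|H| = K − 10 log₁₀(1 + (f/f_c)²)` dB and `∠H = −atan(f/f_c)/2π` cycles
   to the corrected DP2 magnitudes and phase residuals.

## Worked example

The full closed-loop experiment on the synthetic cochlea (ground-truth
corner 2500 Hz at a 16-kHz characteristic frequency):

```
$ zwuisdp run-all --seed 1 --out runs/demo
fc = 2471 Hz (2.7 octaves below CF), EV = 0.99
```

The run designed a 12-s, 12-tone zwuis below CF/2, equalized the effective
OHC input in one adjustment (input range 3.3 dB → 0.2 dB), applied the
combinatorial and post-hoc input corrections, and jointly fitted the
first-order low-pass: the corner estimate (2471 Hz) lands within ~1% of the
simulated truth, 2.7 octaves below CF, with 99% of the weighted
magnitude/phase variance explained. The same pipeline over a five-member
synthetic cohort (`python analysis/04_fit_corner_frequency.py`, CFs
13–25 kHz, true corners 2.1–3.3 kHz) prints

```
corner recovery: median |error| 0.4%; corners lie 2.7 +/- 0.3 octaves below CF
```

— a corner that far below CF means the motile response follows the
stimulus envelope rather than its cycle-by-cycle fine structure.

The numbered scripts under `analysis/` walk through the stages (two-tone
rectification demo, DP2 spectrum and its 6-dB/octave roll-off, closed-loop
equalization, cohort fits) and write their tables under `results/`.

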