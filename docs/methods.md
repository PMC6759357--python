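# Methods

## Signal model

A recording is modeled as

```
d(t) = g_lin · u_lin(t) + g_mot · LPF_fc[ NL(u(t)) ] + n(t)
```

where `u(t)` is the acoustic zwuis stimulus (Pa) after a per-frequency
complex input shaping (standing in for middle-ear transfer and intracochlear
propagation), `NL` is a memoryless rectifier, `LPF_fc` a first-order
low-pass with corner `fc`, `g_lin`/`g_mot` the linear-path and motile gains
(nm/Pa), and `n(t)` white displacement noise with one-sided density 30
pm/√Hz. Displacement is in nm, positive away from the probe. The default
rectifier is quadratic-plus-linear, `v = c1·u − c2·u²` (negative polarity):
the DP2 analysis only sees the even-order term, so the quadratic family is
sufficient; half-wave and Boltzmann options exist to confirm that the
first-order-filter conclusion does not depend on the rectifier shape, which
is not observable from DP2s alone.

Key defaults: `fc = 2500 Hz`, `c1 = 1`, `c2 = 50 /Pa`, `g_mot = 20 nm`,
`g_lin = 50 nm/Pa`, sample rate 111.6 kHz, record length 12 s analyzed in
twelve 1-s coherent segments, component levels 60 dB SPL (within the
55–65 dB range used for narrow-band stimulation in vivo), narrow-band
stimuli of 10–15 components below CF/2, broad-band survey stimuli of 43
components over 0.4–30 kHz. With these settings the mixed DP2s sit roughly
20–40 dB above the per-bin noise floor of a 12-s record, comparable to
reported in vivo OHC-region spectra. The low-pass is applied exactly in the
frequency domain (each DFT bin multiplied by `1/(1 + i f/fc)`), which is
legitimate on coherent records and makes bin-wise contracts reproducible to
machine precision; an IIR implementation would add discretization error
without adding realism.

## Zwuis uniqueness rule

Component frequencies are distinct integer multiples `n_k` of the base
frequency `1/T_segment`, so every component and every distortion product
completes an integer number of cycles per analysis window. The uniqueness
rule enforced by default is:

* all order-2 combination multiples (`n_k + n_m`, `n_k − n_m`, `2 n_k`)
  are mutually distinct and distinct from every primary;
* all order-3 combination multiples are distinct from every primary.

This protects exactly what the analysis uses — unambiguous attribution of
every DP2 and uncontaminated primaries — while remaining feasible for
realistic component counts. Requiring the order-3 products to be mutually
distinct as well (`strict=True`) is available but combinatorially
infeasible beyond a handful of components: an N-tone set has ~4N³/3
order-3 multiples, and for N ≥ 10 on a 1-Hz grid the expected number of
birthday collisions among them is far above one for any admissible band, so
no such set exists to be found in practice. The search itself is a seeded,
jittered-stratified draw (one integer per equal-width stratum, which also
reproduces the ~705-Hz mean spacing statistic of a 43-tone 0.4–30-kHz
complex) with depth-first backtracking against an incrementally maintained
collision set.

## Spectral analysis and significance

Analysis frequencies must be integer multiples of the reciprocal record
duration; anything else is rejected rather than estimated, because spectral
leakage would contaminate neighboring DP2 bins. Component significance uses
the Rayleigh test on the phase of the component across M = 12 coherent
segments: `R` is the resultant length of the unit phasors and
`p = exp(−M R²)`, with the Greenwood–Durand finite-M correction available
behind a flag. `alpha = 0.001` per component, with no multiplicity
correction across DP2 bins — per-component significance is what enters the
fits, and the Type-I inflation this admits is bounded in the test suite
(≤ 1.2 α on pure-noise bins). The per-component dB uncertainty used as an
inverse-variance weight downstream is estimated from the segment-to-segment
scatter of the complex amplitude.

## Effective-input retrieval

In the log domain the bilinear law reads `D_km = L_k + L_m + F(f_km) + C`.
The frequency-common term `F` is expanded in a piecewise-linear basis over
log-frequency knots placed at quantiles of the DP2 frequencies, one knot
per octave on average ("octave" mode). Piecewise-constant octave bands
("bands" mode) were rejected as the default: with a 2.5-kHz corner cutting
through the DP2 band, the unmodeled within-band slope of the filter leaks
more than 1 dB into the retrieved levels, while the linear spline keeps the
leak below ~0.05 dB and remains an ordinary weighted linear least-squares
problem. A "parametric" mode replaces `F` with the first-order form
`−10 log₁₀(1+(f/fc)²)` fitted jointly. Identifiability anchors, stated in
every report: `mean(L_k)` fixed to the declared anchor (default the mean
stimulus level) and `F = 0` at the lowest knot. Only Rayleigh-significant,
combinatorially corrected DP2s enter, weighted by inverse variance.

Primary *phases* are retrieved from `ψ_km = φ_k ± φ_m + Ψ(f_km) + ρ`
(+½ cycle under negative polarity, folded into `ρ` so both polarity
conventions share the identical numerical problem). The solver first runs
an alternating phasor-synchronization pass (unit phasors per primary,
per-band constants) to land every wrapped residual away from the ±½-cycle
boundary, then iterates a rewrapped linear solve and finishes with a
Gauss–Newton polish on the wrapped residuals. Gauge: one primary phase
anchored, lowest knot zero.

The equalization loop subtracts the retrieved level deviations from the
stimulus levels (renormalized so the mean dB SPL is unchanged), with an
optional damping gain and a divergence guard that halves the gain if the
input range grows two steps running. Defaults `max_iter = 4`,
`tol_db = 1`, matching experimental practice of converging within four
presentations; the stopping tolerance itself is this package's own
choice.

## Corner-frequency fit

The joint objective stacks weighted magnitude residuals (dB) and phase
residuals (cycles) scaled by `s = 40 dB/cycle` (0.025 cycle ≡ 1 dB; the
relative weighting of magnitude and phase has no standard value, so `s` is
a declared, configurable default; on noiseless data the estimate is exactly
invariant to it, and on noisy data a twofold change moves the corner by
< 2%). The optimizer works in `log₂ fc` with an octave-spaced multi-start
grid from 0.25 to 16 kHz. Explained variance is reported jointly on the
weighted stacked data and also magnitude-only, since there is no single
standard definition for joint fits. The polarity offset of the phase data (0 or ½
cycle) is chosen by fitting both and keeping the better. Before the fit,
DP2 magnitudes are corrected post hoc for residual input inequality,
`D_km ← D_km − (L_k − L̄) − (L_m − L̄)`; phases are unaffected by input
inequality and are left untouched. Phase predictions default to the known
input phases (stimulus phases plus shaping phase); predicting from the
phases retrieved out of the DP2 catalog itself is supported
(`phase_source="retrieved"`) and recovers the corner slightly less
precisely, since retrieval noise enters the residuals.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis relies on:
uniquely attributable DP2s, the 6-dB combinatorial deficit of second
harmonics, bilinear level scatter, the ½-cycle phase signature of negative
rectification, first-order filtering, a realistic noise floor, and a
non-flat, unknown input shaping. It deliberately omits travelling-wave
propagation and the spatially distributed, interfering DP2 generation that
dominates above CF/2 — the analysis handles that regime by exclusion (the
CF/2 band limit), not by modeling, so passing tests say nothing about DP2
behavior near CF. It also cannot validate the physiological
interpretation of the rectifier; only that *if* motility is a rectifier
followed by a first-order filter, the pipeline recovers its corner
accurately (median error well under 5% at study noise levels) from
realizable recordings.

## Problem sizes and numerics

Default test and demo runs use 10–12 components; recovery statistics use
fifty 12-s records; desk-scale variants (`scale = 0.1`) shorten records to
1.2 s with the base frequency raised tenfold so coherence and segment
counts are preserved. All randomness flows from explicit integer seeds
(stimulus search, phases, noise); reruns are byte-identical. Degenerate
inputs are rejected loudly: non-coherent durations, non-bin-aligned
analysis frequencies, fewer than 4 Rayleigh segments, fits with fewer than
4 points or spanning under 1.5 octaves, rank-deficient retrieval systems
(reported with the offending primaries).

## Known limitations

* The uniqueness rule for order-3 products is a reconstruction (see above);
  both the default and the strict variant are implemented.
* The retrieval model with free `F` and the joint-parametric variant are
  both in-house formulations with no external reference implementation;
  they agree on recovery benchmarks.
* Octave distances and explained variances from the synthetic cohort
  characterize the pipeline, not gerbil physiology; real-data values depend
  on preparations this package does not model.
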