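# Methods

This note documents the models, the numerical choices and the limits of the
`fearloop` package: what each stage computes, which parameters matter, what
the virtual participant does and does not emulate, and where the design was
genuinely open.

## Signal chain

EEG is handled as a channels × time block in microvolts at 500 Hz on a
32-channel 10–20 montage (the extended set with FT9/FT10 and TP9/TP10). The
cleaning chain is, in order:

1. **Bandpass** — Butterworth, order 4, 1–40 Hz, applied zero-phase
   (forward–backward, `sosfiltfilt`). Zero-phase application was chosen
   because the downstream analysis windows are only 500 ms and group delay
   would bias band powers. Forward–backward filtering squares the magnitude
   response; the measured 50 Hz amplitude attenuation of this design at
   fs = 500 Hz is ~18.2 dB (passband gain at 10 Hz is unity to within 2%).
   A steeper stopband would need a higher filter order.
2. **Common-average reference** — subtract the instantaneous across-channel
   mean; idempotent, leaves across-channel means below 1e-9 µV.
3. **Baseline correction** — per channel, subtract the mean over the 5 s
   preceding the first marker from the entire signal. The chain order
   (filter → CAR → baseline) follows the acquisition narrative this package
   models; with a 1 Hz high-pass in front, the baseline step only matters
   for any residual slow offset.

**Channel QC.** A channel's robust amplitude is the scaled median absolute
deviation of its signal; the deviation score is a robust z of these
amplitudes across channels (|amp − median| / (1.4826·MAD)), thresholded at
5.0 by default — a PREP-style convention; the scores are scale-equivariant.
Flagged channels are replaced by inverse-distance-weighted (power 2)
combinations of the good channels on an idealized unit-sphere montage.
Inverse-distance weighting was chosen over spherical splines as a simpler,
dependency-free interpolant that is adequate at 32 channels; it is exposed
as a function argument and can be swapped. The montage coordinates are
constructed analytically from the standard 10–20 angular layout (outer ring
at 72° inclination, inferior temporal row at 90°, intermediate sites as
spherical midpoints of their grid neighbours); they are idealized, not
digitized, positions.

## Features

Spectra use Welch's method with a Hann taper and 50% overlap. The segment
length adapts to the window: sub-second windows use one full-length segment
(500 ms at 500 Hz → 2 Hz resolution), longer epochs use 2-s segments
(0.5 Hz resolution). Band power is the trapezoidal integral of the PSD over
the band, with band edges interpolated so disjoint bands tile the spectrum
additively.

Two alpha conventions coexist deliberately: the asymmetry index uses
8–13 Hz, while the topography/offline band table uses delta 0–4, theta 4–8,
alpha 8–12, beta 12–30, gamma 30–45 Hz. Both are configurable; the defaults
differ by context on purpose. The gamma band is retained as labeled even
though the 1–40 Hz bandpass truncates content above 40 Hz.

`FAA = ln(right) − ln(left)` alpha power; antisymmetric, zero at equality,
negative under relatively greater right-hemisphere activation. The
calibration vector is 4 FAA values + mean HR (5 entries); the offline vector
is 160 band powers (channel-major, band order δ θ α β γ) followed by the 4
FAA values (164 entries), serialized in that fixed order with named columns.

Heart rate from raw PPG: the waveform is bandpass-filtered to the pulse band
(0.7–8 Hz) before prominence-based systolic peak detection with a refractory
distance; each 5-s block reports 60 / mean inter-peak interval, and blocks
with fewer than two peaks carry the previous value and are flagged. The
sparse series is aligned to the EEG grid by linear interpolation with
constant extrapolation. For full windows, the window mean of the upsampled
series equals the mean of the raw 5-s values, so either convention yields
the same online feature.

## Calibration and control

The pretest (90 s neutral + 90 s maximal stimulus) yields 180 trials per
condition at 500-ms windows. Features are standardized with the pooled
calibration scaler and the same scaler is reused online for scale
stability. The classifier is a linear-kernel SVM (C = 1 by default): linear
decision values are in margin units, which is what makes the fixed ±0.5
control margins meaningful. An RBF kernel is available but changes the
distance scale. The decision sign is calibrated after fitting so the
fear-class mean distance is positive regardless of label encoding.
Models serialize as JSON metadata plus a binary sidecar; reloaded models
reproduce distances bit-identically.

The controller maps the 30-s mean distance through strict inequalities:
below −0.5 → increase, above +0.5 → decrease, otherwise (including exactly
±0.5) → keep. Levels clamp at 1 and 5 (saturation; no wraparound, no early
stop). The stimulus template is a pure function of the level — counts
(10/10/1 up to 100/100/5) and a 10% size increment per level — so increases
and decreases are exactly reversible. Online windows are filtered and
re-referenced but not baseline-corrected: a pulled 30-s window has no
pre-marker interval, and the 1 Hz high-pass already removes the offset that
baseline correction targets. The 4-point rating scale (1 no fear … 4 high
fear) is used throughout; agreement scoring: increase ↔ {1,2}, decrease ↔
{3,4}, keep ↔ {2,3}.

In the max-margin regime the magnitude of the mean distance is not
proportional to raw class separation (support vectors pin the decision
values near ±1 once classes are widely separable); distances grow with
separation while the classes overlap and saturate thereafter. This is a
property of margin classifiers, not a defect, and is covered by tests.

## The virtual participant

The simulator exists to make every stage testable without hardware. Latent
fear follows a logistic dose-response in stimulus level with geometric
habituation per exposure:

```
fear = 1 / (1 + exp(-sensitivity · (level - level_midpoint)))
       · (1 - habituation_rate)^exposures
```

Defaults: sensitivity 2.0, midpoint 3.0, habituation 0.03 — a participant
whose response saturates above level 3, the regime of interest for
closed-loop regulation.

EEG per channel is 1/f noise (spectral shaping, exponent 1.0, 2 µV sd) plus
five sinusoidal band oscillators (2, 6, 10, 20, 35 Hz) with random phases.
Fear couples in with fixed directions: right-frontal alpha (F4, F8, FC6,
FT10) amplitude × (1 − asymmetry_gain·fear), so the implied FAA is
2·ln(1 − asymmetry_gain·fear) in power units; frontal theta ×
(1 + 0.3·fear); alpha/beta/gamma globally × (1 − 0.2·fear). The 0.3 and 0.2
couplings are free synthetic constants mirroring observed directions, not
measured effect sizes. HR is baseline (70 bpm) + arousal gain (15 bpm per
unit fear) − a bradycardia drop (6 bpm per level) above level 4, with 1 bpm
Gaussian jitter on a 5-s cadence; PPG can be synthesized as a pulse train at
the instantaneous rate. Ratings quantize fear uniformly into the 4-point
scale with ties broken downward. All generation is driven by
`numpy.random.default_rng` (PCG64) and is bit-reproducible under a seed.

What the simulator does **not** emulate: ocular/muscle artifacts, electrode
drift and impedance changes, non-stationary background spectra, broadband
oscillatory bursts, HR variability structure, inter-individual montage
differences, and novelty-driven early HR elevation. Tests passing on this
generator therefore demonstrate correctness of the computation chain and
the control logic under the stated signal model — not performance on real
recordings, where class separations are far smaller and artifacts dominate
the error budget.

## Offline analyses

Epoch rejection drops 30-s epochs whose per-channel peak-to-peak exceeds
200 µV (the threshold is a configurable convention; "excessively high
voltage" has no canonical number). Levels 1–2 form the low class, 4–5 the
high class, level 3 is excluded. Classification is nested: z-scoring and a
3-fold grid search live inside each outer training fold of a stratified,
seeded 5-fold scheme; reported accuracy/F1 are outer-fold mean ± sd in
percent. The outer 5-fold scheme is the primary metric; a single 80/20
split is a special case the user can run manually. Grid spaces are small
documented defaults (SVM: C ∈ {0.1, 1, 10}, kernel ∈ {linear, rbf}; RF:
depth ∈ {none, 5}; XGBoost: 50–100 trees, depth 2–4). Feature importance
comes from ensemble impurity importances, or |hyperplane weight| on
standardized features for the linear SVM, from a final refit that does not
enter the reported metrics.

Level statistics use Welch (unequal-variance) t-tests over all level pairs
— level groups have unequal sizes by construction — with Benjamini–Hochberg
adjustment; HR enters as exactly the 10 per-run 30-s window means.
Correlation matrices are Pearson (a rank-correlation option exists where
monotonic rather than linear association is wanted) with a BH mask at
alpha 0.05; zero-variance variables are flagged undefined and excluded from
the family. The BH step is a thin wrapper over a standard step-up
implementation and is verified against a brute-force enumeration oracle in
the tests.

## Problem sizes and determinism

The shipped tests and the acceptance script run entirely on simulated data:
one 180-s pretest per classifier, 60 thirty-second epochs for the offline
dataset, 20 seeded closed-loop runs of 10 iterations, 200-run null
calibrations for the type-I checks, and 1,000 random vectors for the BH
oracle. These sizes were chosen so the full suite completes in about a
minute on one CPU while keeping Monte-Carlo noise well inside the asserted
tolerances. Every stochastic path takes an explicit seed.

## Known limitations

* XDF reading requires the optional `pyxdf` dependency; without it only the
  text dialect is available. There is no EDF/BDF support and no live
  streaming transport.
* The ±0.5 margins assume linear-SVM decision units; swapping in an RBF
  kernel without recalibrating the margins changes the controller's
  operating point.
* The order-4 bandpass leaves ~18 dB of stopband attenuation at 50 Hz even
  zero-phase; mains interference beyond that level would need a notch or a
  higher-order design.
* Inverse-distance interpolation underestimates spatial high-frequency
  structure relative to spherical splines; acceptable at 32 channels,
  not recommended for dense montages.
* Offline classification numbers obtained on the simulator characterize the
  pipeline, not any real population; only orderings (e.g. whole-scalp band
  power ≥ FAA-only) and chance-level nulls are meaningful claims at desk
  scale.
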