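# fearloop

Closed-loop neuroadaptive exposure control from EEG frontal alpha asymmetry
and heart rate.

`fearloop` is a desk-scale implementation of the computation stack behind
neuroadaptive virtual-reality exposure therapy for spider phobia: an
individualized fear-state classifier is calibrated from a short pretest, and
a closed-loop controller then grades the intensity of a 5-level spider
stimulus from the classifier's signed distance to its decision boundary.
Because such systems are normally driven by VR hardware and live EEG
amplifiers, the package ships a virtual participant — a generative model of
fear-modulated EEG, heart rate and subjective ratings — so the entire loop
can be exercised, tested and analyzed offline.

It is aimed at researchers in affective neurotechnology and biosignal
processing who want a reproducible, hardware-free reference of the method:
the signal chain, the control logic and the statistical analyses, end to end.

## The method

**Fear marker.** Frontal alpha asymmetry (FAA) over homologous electrode
pairs,

```
FAA = ln P_alpha(right) - ln P_alpha(left)
```

with alpha = 8–13 Hz. Alpha power is inversely related to cortical
activation, so negative FAA indicates relatively greater right-frontal
activation — the signature of withdrawal-related states such as fear. Four
pairs are used (F3/F4, F7/F8, FC5/FC6, FT9/FT10), plus the mean heart rate,
giving a 5-dimensional feature vector per 500-ms window.

**Calibration.** A pretest records 90 s of a neutral scene and 90 s of the
maximal spider stimulus. Each phase is cut into non-overlapping 500-ms
windows (180 trials per condition); a linear-kernel SVM is trained on the
standardized trials. The classifier exposes a *signed distance* to its
hyperplane: positive = fear side, negative = relaxed side.

**Control.** The main run is a loop of 10 iterations. Each iteration pulls
the last 30 s of EEG+HR, averages the signed distance over its 500-ms
sub-windows, and maps the mean through fixed margins: below −0.5 the
stimulus level is increased, above +0.5 it is decreased, inside the margin
it is kept. Five levels grade the scene from 10 floor / 10 wall / 1 web-net
spider (level 1) to 100 / 100 / 5 (level 5), with spider size scaled by 10%
per level. Participants rate their fear on a 4-point scale each iteration;
an increase agrees with ratings 1–2, a decrease with 3–4, a keep with 2–3.

**Offline analyses.** 30-s epochs labeled by level feed Welch band powers
(delta/theta/alpha/beta/gamma × 32 channels = 160 features) plus the 4 FAA
indices (164 total); low (levels 1–2) vs high (levels 4–5) fear is
classified with nested cross-validation (inner 3-fold grid search, outer
stratified 5-fold) using SVM, random forest and gradient boosting. Level
statistics use Welch t-tests and Pearson correlations, all
Benjamini–Hochberg corrected.

## Worked example

```python
import numpy as np
from fearloop import (
    ParticipantParams, VirtualParticipant, simulate_session,
    build_calibration_dataset, train_fear_classifier, run_adaptive_loop,
)

params = ParticipantParams(seed=1)          # moderate-fear virtual participant
session, _ = simulate_session(params, "pretest", seed=100)
data = build_calibration_dataset(session)   # 360 trials, 180 per condition
model = train_fear_classifier(data)
print(data.X.shape, model.training_accuracy)

participant = VirtualParticipant(params, seed=3)
state = run_adaptive_loop(participant, model)
print([e.level for e in state.history])
print([round(e.mean_distance, 2) for e in state.history])
```

prints

```
(360, 5) 1.0
[2, 3, 2, 3, 3, 3, 3, 3, 3, 3]
[-1.56, -0.87, 0.86, -0.72, 0.47, -0.15, 0.31, 0.47, 0.23, -0.02]
```

The loop escalates while the participant reads as relaxed (large negative
distances), overshoots once onto the fear side (+0.86, level drops back),
then settles inside the ±0.5 margin around level 3 — the participant's
logistic fear midpoint.

The same workflow is available from the shell:

```
fearloop simulate --protocol pretest --seed 1 --out work/
fearloop calibrate --session work/pretest_session --out work/
fearloop run-loop --model work/fear_classifier --simulate --seed 3 --out work/
fearloop analyze --session work/main_session --truth work/main_truth.csv --out work/analysis
fearloop report --analysis-dir work/analysis
```

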