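# exogait

Sensing software for exoskeleton-assisted crutch gait, hardware-free.

Users of lower-limb exoskeletons almost always walk with forearm crutches,
and assessing them outside a motion-capture lab requires wearable sensing: a
pair of instrumented crutches (uniaxial load cell + IMU each) and a pair of
3D-printed insoles (three force-sensitive resistors + IMU each), streaming
JSON packets to a central unit that timestamps them on a master clock.
`exogait` implements the complete analysis stack for such a system —
synchronization, gait-phase estimation, biomechanics, event detection and
validation statistics — together with a ground-truth synthetic multi-sensor
gait generator so every stage can be developed and tested without hardware.

## What it computes

**Fuzzy-logic gait phases.** Raw FSR readings `F_i` from the six placements
(heel, first and fifth metatarsal of each foot) are normalized by the sum of
readings in scope, `F*_i = F_i / Σ F_i` (per foot by default), which makes
the pipeline robust to sensor saturation, drift and user weight without
calibration. Each normalized reading is graded by a sigmoid membership
function

```
μ(F*) = 1 / (1 + exp(−s (F* − F0)))        s = 0.15, F0 = 0.45
High = μ(F*),  Low = 1 − μ(F*)
```

and an eight-row rule base (one High/Low pattern per gait phase: heel
strike, loading response, mid-stance, terminal stance, pre-swing, initial /
mid / terminal swing) is evaluated with min-AND conjunction. The phase with
the largest grade wins; the sum of the eight grades is an internal
consistency check. Rules for the opposite side are obtained by mirroring
the left/right placement conditions.

**Anteroposterior center of pressure.** From one insole's three sensors,

```
y_CoP = (y_H·F_H + y_M1·F_M1 + y_M5·F_M5) / (F_H + F_M1 + F_M5)
```

with the mediolateral coordinate computed analogously; samples with a
vanishing load sum (swing) are flagged invalid instead of divided.

**Crutch ground reaction forces.** The load cell measures the force along
the crutch shaft; the IMU orientation rotates that axial vector into world
vertical / anteroposterior / mediolateral components (norm-preserving).

**Gait events.** Heel strikes are local maxima of the heel FSR trace
(prominence- and refractory-gated); the marker-based reference method takes
extrema of the signed anteroposterior heel- and toe-to-sternum offsets.

**Validation statistics.** Paired-method comparison with Shapiro–Wilk
normality gating, Wilcoxon signed-rank testing, RMSE, Pearson correlation,
median/IQR of differences and Bland–Altman limits of agreement
(bias ± 1.96 SD).

## Worked example

```python
import numpy as np
from exogait import (
    GaitSimConfig, simulate_session, classify_sequence,
    detect_heel_strikes_fsr, stride_metrics,
    PairedComparison, agreement, butterworth_filter, FilterSpec,
)
from exogait.biomech_metrics import match_events

cfg = GaitSimConfig(n_strides=10, seed=1)          # 2% FSR noise, 130 Hz
session, truth = simulate_session(cfg)

heel = np.array([f.channels["left_insole_fsr_heel"] for f in session.frames])
heel = butterworth_filter(heel, cfg.sample_rate, FilterSpec(order=2, cutoff_hz=10))
events = detect_heel_strikes_fsr(truth.timestamps, heel, "left",
                                 min_prominence=0.1 * cfg.fsr_full_scale)
metrics = stride_metrics(events)

detected, reference = zip(*match_events([e.time for e in events],
                                        truth.heel_strikes["left"]))
report = agreement(PairedComparison(np.array(detected), np.array(reference),
                                    "heel strikes: FSR vs truth"))
```

Output:

```
detected 10 left heel strikes (ground truth: 10)
mean cycle duration 3.58 s (simulated 3.33 +/- 1.16 s)
timing bias +10.6 ms, RMSE 10.9 ms, limits of agreement [+5.5, +15.7] ms
fuzzy phase labels match ground truth on 73% of frames
```

The detector recovers all ten simulated heel strikes; the ~11 ms timing
RMSE is dominated by the zero-phase filter's interaction with the
asymmetric impact transient plus 130 Hz sampling. The 73% frame-level
agreement counts every frame, including the crossfade windows around the
eight phase boundaries of each ~3.3 s cycle where no crisp label is
well-defined; away from those windows agreement is 100% on noiseless gait
(see the simulator closure tests).

The same operations are available from the shell:

```
exogait simulate --strides 10 --seed 1 --out session.csv --truth truth.csv
exogait segment session.csv labels.csv
exogait cop --side left session.csv cop.csv
exogait grf --side left session.csv grf.csv
exogait events --side left session.csv events.csv
exogait validate --a cop.csv --b reference.csv --metric y_cop_mm
```

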