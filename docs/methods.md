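# Methods

## Scope and data model

`exogait` models a four-peripheral wearable recording system for
exoskeleton-assisted crutch gait: two instrumented insoles (FSRs at the
heel, first and fifth metatarsal, plus an IMU) and two instrumented
crutches (uniaxial load cell along the shaft, plus an IMU). Peripherals
stream JSON packets; a central unit timestamps each packet on arrival with
its own clock (master-clock timestamping), which sidesteps per-device
clock drift at the cost of absolute sampling-instant accuracy. Frames are
assembled per timeout window: the window anchored at the earliest
unconsumed packet closes as soon as every active peripheral has reported,
or after `timeout_window` seconds, in which case the frame is emitted with
`complete=False` and downstream consumers (phase estimation, control)
refuse to act on it. The default window is two nominal sample intervals
(≈15.4 ms at 130 Hz): one late packet is tolerated, two mark the stream
incomplete. Frame timestamps equal the anchoring packet's arrival time, so
assembly is causal. Channel values are carried at four decimal places end
to end (the wire format), and CSV round-trips are lossless at that
precision. Missing channels are explicit missing values, never zeros.

## Fuzzy gait-phase estimation

Readings are normalized by the sum of readings in scope. The scope is
per-foot (n = 3) by default: with global (n = 6) normalization no reading
can exceed the 0.45 threshold during double support, so every condition
would read Low and the rules lose their contrast; per-foot normalization
preserves it. Global scope remains selectable.

The membership function is the sigmoid `μ(F*) = 1/(1+exp(−s(F*−F0)))`
with `s = 0.15`, `F0 = 0.45` applied to the [0, 1]-normalized reading.
On that scale the slope is shallow, so grades compress toward 0.5 and the
sum of the eight phase grades sits near 4 rather than the nominal 1 that a
crisp rule base would produce. Argmax ordering — and therefore every
classification — is unaffected, so the literal form is kept as the
default; a percent-scale configuration (`FuzzyConfig.rescaled()`: inputs
×100, `F0 = 45`) yields near-crisp grades and restores a grade sum near 1
for users who want the consistency check on its nominal scale. The
consistency band defaults to [0.8, 1.2]; frames below it are flagged
`abnormal`, above it `conflicting`, and in both cases still labelled.

The shipped rule base is the eight-row table of High/Low patterns over the
six placements with right-insole outcomes; left-side rules are the mirror
image (left/right placements swapped, outcomes unchanged; mirroring is an
involution). A variant rule base whose heel-strike row requires the right
first metatarsal Low instead of High is shipped alongside
(`rules_eq5_variant`): the two published forms of that rule disagree and
neither is "corrected" here — the rule base is configuration, not code.
Rule evaluation is min-AND over the six conditions; defuzzification is
argmax over the eight grades with exact ties resolved to the earlier row
in cycle order, which makes classification deterministic (the mid-swing /
terminal-swing rows differ only in the heel condition and tie exactly
under a uniformly loaded foot).

## Biomechanics

**CoP.** The insole coordinate frame has its origin at the heel sensor,
+y anteroposterior toward the toes, +x mediolateral, millimetres. Shipped
geometries (small/medium/large; medium: M1 at (30, 160), M5 at (−30, 150))
come from shoe-size anthropometry and are plain configuration. The CoP is
the load-weighted average of sensor coordinates, hence always a convex
combination inside the sensor triangle; samples whose load sum falls below
`min_total` (default 2% of full scale) are invalid rather than divided by
a vanishing total.

**Crutch GRF.** The crutch local frame puts the shaft along +z, so the
identity orientation is a vertical crutch. Decomposition applies the IMU
orientation (unit quaternion, tolerance 1e-6) to `(0, 0, axial)`;
components are reported as (vertical, anteroposterior, mediolateral) in
the world frame. The operation is an isometry: the component norm equals
the axial reading exactly, and rotating back recovers the axial vector.
Both the axial reading and the world components are exposed so either
reporting convention can be produced.

**Events.** Heel strikes are local maxima of the heel FSR trace with a
prominence threshold (default 10% of full scale) and a refractory interval
(default 0.5 s, well under the ~3.3 s cycles of exoskeleton gait). Event
timing is best measured on a zero-phase-filtered trace (2nd-order 10 Hz
Butterworth by default); both the raw and filtered paths are exposed. The
marker reference method uses the *signed* anteroposterior offset of the
heel and toe markers relative to the sternum marker: heel strikes at local
maxima of the heel offset (foot maximally ahead of the trunk at contact),
toe-offs at local minima of the toe offset (foot maximally behind at
lift-off). Detected and reference events are paired by mutual nearest
neighbour within 0.5 s, so a single detection straddling two close true
events contaminates nothing. Stride durations are successive same-side
heel-strike differences; cadence is 60 over the mean duration.

## Synthetic gait generator

The generator emulates the study conditions end to end and emits the
ground truth alongside the recording:

* **Cycle durations** are drawn from a normal distribution truncated to
  positive values, default 3.33 ± 1.16 s (slow exoskeleton-assisted
  stepping). Truncation at zero biases the mean by well under 0.01 s.
* **FSR channels** follow the rule table mechanically: per phase, High
  placements load to a plateau of 60% full scale and Low placements rest
  at a 5% preload (fitted FSRs never read zero). The crisp template holds
  until each phase boundary and then ramps linearly over 80 ms (a causal
  moving average), so the classifier's flip instant coincides with the
  ground-truth label change. Each heel strike adds an impact transient
  whose apex lies exactly at the event time (Gaussian rise, σ = 40 ms,
  apex 80% full scale) and which settles onto the stance plateau without
  dipping below it — the local maximum of the heel trace *is* the event,
  and the plateau carries no spurious high-prominence peaks. Measurement
  noise is additive Gaussian (default SD 2% of full scale), drift is linear
  (default 1% full scale per minute, random sign per channel), and values
  clip at the 85% saturation level, reflecting FSRs that do not reach
  their theoretical maximum.
* **Crutches** carry one raised-cosine axial burst per contralateral step
  (default 300 N peak) while the shaft sweeps a small sagittal arc; the
  arc is sized from the configured transverse-force fraction (default 7%)
  so the emitted truth never exceeds it. Axial noise (1% of peak) and
  orientation noise (2° per Euler angle) are applied to the measurements
  only; the truth is the exact decomposition of the clean signals.
* **Markers** (150 Hz) come from a planar model: the sternum advances at
  the cycle-average speed, each foot is stationary in stance and advances
  one step length at constant velocity during its swing, landing exactly
  at the ground-truth heel strike. The signed AP heel offset therefore
  peaks exactly at heel strike and the toe offset bottoms exactly at
  toe-off.
* **Phase fractions** default to equal eighths of the cycle. Published
  able-bodied fractions skew toward stance, but the quasi-static stepping
  of a rigid-sole exoskeleton does not follow them; equal fractions are a
  neutral, configurable choice.
* The ground-truth event bookkeeping follows the rule table's structure:
  right heel strike at the cycle start, left heel strike where the left
  heel template turns High (terminal-stance onset), toe-offs where each
  foot's template fully unloads. The left foot's fully-unloaded window is
  a single table row, so the simulated left swing is shorter than the
  right; this is a property of the eight-row template, not of the
  analysis.

The CoP sweep generator inverts the weighted-average formula: a circular
reference path inside the sensor triangle is converted to barycentric
weights, scaled by a constant total load (80% of full scale), and emitted
as the FSR triplet — so the noiseless estimate reproduces the path to
numerical precision and any residual error is attributable to the
configured noise. The default radius is 80% of the centroid-to-edge
clearance; paths leaving the triangle are rejected.

What the generator does **not** emulate: real plantar pressure waveforms
under a rigid exoskeleton sole (only their High/Low structure), FSR
hysteresis and nonlinearity, Bluetooth packet loss and jitter (frame
assembly is tested on synthetic packet streams instead), IMU fusion error
structure (orientation noise is white, per-angle), and soft-tissue or
marker-placement artefacts. Passing tests therefore demonstrate the
correctness and noise behaviour of the *algorithms*, not the field
accuracy of any particular hardware.

## Validation statistics

Differences are `a − b`. RMSE, Pearson r (None on zero-variance input,
never a crash), median and IQR of differences, bias and 95% limits of
agreement (bias ± 1.96·SD, sample SD with n−1 throughout) are reported
together with Shapiro–Wilk on the differences and the Wilcoxon signed-rank
p-value (zero differences handled by the Pratt method; ties by average
ranks). When the normality gate does not reject, the Wilcoxon result is
still reported with a note — no silent test switching. The signed-rank
implementation is validated in the test suite against exact enumeration of
all 2^n sign assignments at n ≤ 10. Trial summaries report min, max, mean
and sample SD per metric across repeated trials.

For multi-rate comparisons, each stream is low-pass filtered with a
Butterworth filter (defaults: 2nd order, zero phase; 10 Hz for FSR and
load-cell channels, 6 Hz for marker trajectories — conventional
gait-analysis cutoffs, all configurable) and faster streams are resampled
onto the slowest grid by linear interpolation after an anti-alias low-pass
at 0.4× the target rate. Resampling never extrapolates.

## Validation protocols and problem sizes

`exogait.protocols` (driven by `scripts/acceptance.py` and the acceptance
tests) re-measures the pipeline under stated synthetic conditions:

* **Heel-strike timing:** 3 runs × 6 bouts × 10 strides at 130 Hz, 2%
  full-scale FSR noise, cycle durations 3.33 ± 1.16 s truncated positive;
  detection on zero-phase 10 Hz-filtered heel traces with default
  prominence and refractory; differences pooled over both sides and all
  runs (360 events). Typical pooled RMSE ≈ 11 ms, dominated by the
  filter's interaction with the asymmetric impact transient plus sampling
  quantization.
* **CoP:** 18 circular sweeps (5 s period, 130 Hz) with 2% full-scale
  noise on the medium geometry; anteroposterior RMSE over valid samples,
  typically ≈ 3.2 mm.
* **Crutch GRF:** 18 loading cycles (3 s period, 70% duty) at 300 N peak
  with 1% axial and 2° orientation noise; vertical-component RMSE,
  typically ≈ 3.0 N.

These sizes run in seconds on one CPU while giving hundreds to thousands
of samples per estimate.

## Numerical choices and edge cases

* Sigmoid evaluation clamps the exponent at 700 to avoid overflow; the
  grade is exactly 0 or the closed form elsewhere.
* A zero scope sum in normalization (foot fully unloaded) yields zeros,
  not NaN; rule evaluation then grades that foot's conditions at μ(0).
* `cop_from_fsr` returns an invalid sample (NaN coordinates) rather than
  raising when the foot is unloaded.
* Quaternions must be unit within 1e-6; within tolerance they are
  renormalized before use.
* Event matching is mutual-nearest within 0.5 s; unmatched events are
  excluded from timing RMSE but counted in the match-rate check.
* CSV floats are written at 4 decimals; reading treats empty cells as
  missing, enforces strictly increasing timestamps, and rejects unknown
  columns by name.

## Known limitations

* The shallow default sigmoid makes phase grades nearly degenerate
  (argmax margins of 1e-3 to 1e-2); under heavy noise, per-frame labels
  near phase boundaries are unstable. The rescaled configuration or a
  temporal smoother downstream mitigates this.
* Per-foot normalization cannot distinguish a uniformly loaded foot from
  an unloaded one (both normalize to equal thirds); the rule table's
  intra-foot contrast is what carries the classification.
* The marker model is planar and kinematically idealized; it validates
  the event-extraction logic, not marker-based gait analysis in general.
* Frame assembly assumes packets arrive in non-decreasing master-clock
  order, which the master's own timestamping guarantees by construction.
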