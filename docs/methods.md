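# Methods

## Signal model and scope

The estimator assumes the observed wrist PPG decomposes additively as

    d(n) = clean pulse(n) + (accelerometer-correlated artifact)(n) + v(n),

where the artifact is well approximated by a linear time-invariant
function of the three accelerometer axes and v(n) is white measurement
noise. Heart rate is treated as the frequency of the single strongest
tone of the artifact-reduced signal; harmonic structure of the pulse is
not modeled by the tracker (the band-pass feedback suppresses it).
Reference heart rate, where used, is consumed as a ready-made BPM
series — the package does no ECG processing.

## Stages

**Preprocessing.** Raw recordings (nominally 125 Hz) are decimated to
25 Hz with a zero-phase FIR anti-aliasing low-pass followed by
take-every-q-th (`scipy.signal.decimate`), so the first output sample
aligns with the first input sample and the output length is ceil(n/q);
rationally related rates fall back to polyphase resampling. The PPG is
then band-passed 0.4–4.0 Hz (24–240 BPM) with a 4th-order Butterworth
applied forward–backward. The band was chosen to cover physiological
heart rates while removing baseline wander and high-frequency noise and
is configurable. Accelerometer channels are resampled but never
band-passed: the canceller reads only their signs and expects the raw
motion reference. Non-finite samples are a hard ingest error rather
than being interpolated — a streaming estimator should fail loudly on
corrupt input. When a recording carries two PPG channels they are
averaged before filtering (configurable to first-channel-only).

**Sign-sign cancellation.** Three per-axis weight vectors of length
M = 21 adapt with step size μ = 1e-4. Design points the update rule
leaves open, resolved as follows:

- sign(0) := 0 (three-valued sign), which makes "zero error → no
  update" exact.
- The normalizer sign(u)ᵀsign(u) is the count c of nonzero sign
  entries (equal to M once the delay line is full of nonzero samples);
  if c = 0 for an axis, that axis's update is skipped for the sample,
  and with all three references silent the filter is exactly
  transparent (e ≡ d).
- Weights and delay lines initialize to zero; the first M samples are a
  warm-up transient.
- All three axis updates within one sample use the pre-update weights
  and the same scalar error, so update order is immaterial (asserted in
  tests).
- The NLMS baseline adds a regularizer eps = 1e-8 to the normalization
  term; with eps = 0 an all-zero delay line raises. The pipeline's NLMS
  mode stacks the three axis delay lines into a single 3M-tap filter,
  the textbook multi-reference noise-cancellation form.

The complexity claim is structural, not a benchmark: both filters count
their true multiply operations at run time. The sign-sign output is a
sum of ±weights and each weight increment is one of {−μ/c, 0, +μ/c},
so only the scalar μ/c·sign(e) per active axis is a true multiplication
(3 per sample here, bounded by M); NLMS measures exactly 3M + 1.

**Frequency tracking.** The tracker consumes sign(e(n)) and runs the
five-line resonator/gradient recursion with β = 0.95 (resonator
bandwidth), μ_a = 0.025 (adaptation rate) and, in the noise-robust
variant, L = 5 (averaging length). Choices the recursion leaves open:

- α̂ initializes at cos(2π·f_init/f_s) with f_init = 90 BPM
  (configurable) — mid-range, so the first lock acquisition is short.
- P_x initializes at 1e-6 and the normalized gain μ_a·x(n−1)/(2P_x) is
  capped at unit magnitude for the first second, suppressing the
  start-up transient while P_x is still dominated by its
  initialization.
- α̂ is clamped to ±(1 − 1e-9) after every update so arccos is always
  defined; estimated HR therefore always lies in (0, 60·f_s/2].
- The recursion uses sign(e(n)) and sign(e(n−2)) but not sign(e(n−1)),
  matching the resonator's 1 − z⁻² feed-forward path.
- ᾱ(n) averages the L most recent α̂ values *including* the current
  one; before L estimates exist it averages what is available. With
  L = 1 the variant is bit-identical to the plain tracker.

**Feedback band-pass.** The desired signal handed to the canceller is
the PPG re-filtered by a second-order IIR band-pass centered on the
tracker's current estimate:

    d_hr(n) = α̂(1+β_hr)·d_hr(n−1) − β_hr·d_hr(n−2)
              + 0.5(1−β_hr)(d(n) − d(n−2)),   β_hr = 0.8.

The recursive terms act on the filter's own output — the filter is the
same constrained resonator used by the tracker, with poles at radius
√β_hr; a feed-forward-only reading of the difference equation would not
be a band-pass. At sample n the filter uses the α̂ produced at sample
n−1, which breaks the algebraic loop between the three stages. The
feedback is on by default and disabled by configuration to obtain the
plain cancel-then-track topology.

**Windowing.** Per-sample HR is averaged over 8 s windows advanced by
2 s (the cadence of common treadmill reference traces), timestamps at
the window end; the statistic is the arithmetic mean (median available).
Windows overlapping the first 8 s of signal are emitted but flagged as
warm-up.

## Evaluation metrics

Error1 is the mean absolute difference in BPM over aligned windows;
Error2 is the mean absolute *percentage* error and is reported in
percent — the un-scaled ratio would sit two orders of magnitude below
the BPM error for physiological rates, which is not how such errors are
quoted. Bland–Altman limits of agreement are mean difference ± 1.96·SD
with the sample (n−1) standard deviation; the regression line is the
ordinary least-squares fit of estimate on reference. Series are joined
on timestamps within half a reference step.

## Synthetic data

The generator produces exactly the model class the canceller assumes:
a harmonic pulse train (fundamental + 2 harmonics, relative amplitudes
1.0/0.5/0.2) following a piecewise-linear HR profile; accelerometer
axes carrying a common gait tone at per-axis amplitudes (1.0, 0.6,
0.3) g with distinct phases plus white sensor noise; an artifact formed
by per-axis 3-tap FIR mixing of the accelerometer into the PPG; and
white measurement noise. An optional tanh soft-clip on the artifact
exists (off by default) to probe model mismatch.

Amplitude scales are physical: PPG in volts with pulse amplitude
0.05 V, accelerometer in g. The scale matters because the sign-sign
filter's output is built from unit-amplitude sign vectors — its weights
encode the artifact amplitude *in PPG units*, and the weight slew rate
is fixed at μ/c per tap per sample. At the default μ = 1e-4 an artifact
of ~0.1 V cancels within tens of seconds; a PPG expressed in raw ADC
counts (thousands) would need proportionally longer. The volts-scale
default keeps the published step size in its working regime and mirrors
an analog front-end's output swing.

The heavy-artifact fixture (78 BPM pulse vs 2.0 Hz gait, artifact ≈ 2×
the pulse RMS) starts with a 30 s rest before gait onset (5 s ramp-on),
emulating a treadmill protocol in which subjects begin at rest. This is
also the operating condition the closed loop requires: the tracker must
acquire the true lock before the artifact appears, after which the
re-centered band-pass attenuates the gait line and the canceller
removes it. With an artifact that dominates from the very first sample
the loop can lock onto the gait frequency or the pulse's second
harmonic and, with the fixed published parameters, not recover —
a genuine failure mode of single-tone closed-loop trackers, not an
implementation artifact.

What passing on this generator does *not* show: robustness to real PPG
morphology (dicrotic notch, amplitude modulation), non-stationary or
nonlinear accel→artifact coupling, sensor saturation, or cadence equal
to heart rate (a known hard case for accelerometer-referenced
cancellation). Those require real recordings; the SPC 2015 script
exists for that purpose.

## Numerical and degenerate-input behavior

All stage steps are pure with respect to a serialized state snapshot
(JSON round-trip restores bit-identical behavior). Non-finite inputs
raise at every stage boundary. Upsampling is rejected in preprocessing;
band edges must satisfy 0 < low < high < f_s/2; windows require
window_s ≥ step_s > 0 and at least one full window of signal. On a
ramping heart rate the tracker carries a constant lag of ≈ 0.67 BPM/s
× ≈ 4.5 s ≈ 3 BPM set by μ_a and the resonator's group delay; on
steady rates the bias is below 0.3 BPM.

## Problem sizes

Test and acceptance runs use 60–240 s recordings at 25 Hz (1.5k–6k
samples), 20-seed Monte-Carlo for the noise-robustness comparison, and
10⁵-step runs for the weight-boundedness checks — sizes at which every
reported quantity is stable to well within its asserted tolerance.
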