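# pulsetrack

Noise-robust, low-complexity heart-rate estimation from wrist
photoplethysmography (PPG) during motion.

Wrist-worn optical heart-rate sensors fail exactly when people care most
about them: during exercise, when arm movement injects a motion artifact
into the PPG that is often stronger than the pulse itself. `pulsetrack`
implements a three-stage streaming estimator designed for cheap wearable
hardware — every stage is a constant-memory, sample-by-sample recursion
with a handful of multiplications per sample:

1. **Preprocessing** — decimation of the raw 125 Hz channels to 25 Hz
   with FIR anti-aliasing, and a zero-phase 0.4–4 Hz band-pass of the
   PPG (24–240 BPM).
2. **Motion-artifact cancellation** — a three-axis *sign-sign* adaptive
   filter with the accelerometer as reference. With per-axis delay lines
   u_x, u_y, u_z of length M and the shared residual e(n) = d(n) − y(n),

       y(n)  = sign(u_x)ᵀŵ_x + sign(u_y)ᵀŵ_y + sign(u_z)ᵀŵ_z
       ŵ_a  ← ŵ_a + μ · sign(u_a) / (sign(u_a)ᵀsign(u_a)) · sign(e(n))

   Because only signs of the reference and the error are used, the
   update and the output need additions only (at most M true
   multiplications per sample, vs 3M + 1 for the NLMS baseline, which is
   also provided).
3. **Frequency tracking** — an oscillator-based adaptive notch filter
   (OSC-ANF) whose parameter α̂ = cos ω follows the strongest tone of
   the residual; heart rate is HR = ω·f_s/(2π)·60. The noise-robust
   variant (NR-OSC-ANF) anchors each update at the mean ᾱ of the last
   L estimates, and a second-order IIR band-pass re-centered on α̂
   pre-filters the PPG before cancellation, closing the loop.

Defaults are M = 21, μ = 1e-4, L = 5, β = 0.95, μ_a = 0.025,
β_hr = 0.8. Per-sample heart rate is aggregated over 8 s windows
advanced by 2 s. A synthetic-data module generates PPG + accelerometer
recordings with known ground truth (harmonic pulse train, gait-like
accelerometer content, linear FIR accel→artifact mixing, white noise)
so the whole pipeline is testable offline; a configurable reader for
IEEE Signal Processing Cup 2015 MATLAB recordings is included for real
data.

## Worked example

```python
from pulsetrack import run_pipeline, make_windowed_hr, standard_fixtures

frame, truth = standard_fixtures()["heavy_artifact"]   # 78 BPM + 2 Hz gait
est = run_pipeline(frame)
ref = make_windowed_hr(truth.per_sample, frame.fs)
```

Running `python examples/estimate_during_motion.py` prints:

```
window end (s)   full pipeline (BPM)   no-cancellation (BPM)   truth
          68               78.3                120.2         78.0
         128               78.2                120.2         78.0
         218               78.2                120.2         78.0

full pipeline:  Error1 = 0.32 BPM, Error2 = 0.42 %
no cancellation: MAE = 36.2 BPM
```

The observed PPG's spectrum is dominated by the 2.0 Hz (120 BPM) gait
line; without cancellation the tracker locks onto it, while the full
pipeline stays on the true 78 BPM to within a fraction of a beat.
Error1 is the mean absolute error in BPM and Error2 the mean absolute
percentage error; `compute_errors` additionally reports Bland–Altman
limits of agreement and the estimate-vs-reference regression line.

The other scripts in `examples/` demonstrate tone tracking
(`track_a_tone.py`), agreement statistics on a 70→150 BPM treadmill
ramp (`evaluate_agreement.py`) and the run-time multiply counts of the
two cancellers (`complexity_comparison.py`). The same functionality is
available from the shell:

```sh
pulsetrack simulate --fixture heavy_artifact --out rec.csv --truth truth.csv
pulsetrack estimate --input rec.csv --config cfg.yaml --output hr.csv
pulsetrack evaluate --est hr.csv --ref ref.csv --report report.json
```

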