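"""Estimate heart rate from a motion-corrupted wrist PPG recording.

Generates the heavy-artifact fixture — a steady 78 BPM pulse whose
observed PPG is dominated by a 2 Hz gait artifact from 30 s on — runs
the full three-stage pipeline, and contrasts it with an ablation that
skips artifact cancellation.
"""

import numpy as np

from pulsetrack import (PipelineConfig, compute_errors, make_windowed_hr,
                        run_pipeline, standard_fixtures)

frame, truth = standard_fixtures()["heavy_artifact"]
ref = make_windowed_hr(truth.per_sample, frame.fs)

est = run_pipeline(frame)
ablation = run_pipeline(frame, PipelineConfig.from_dict(
    {"ma": {"algorithm": "none"}, "anf": {"feedback": False}}))

print("window end (s)   full pipeline (BPM)   no-cancellation (BPM)   truth")
for i in range(0, est.n, 15):
    print(f"{est.t[i]:12.0f} {est.hr_bpm[i]:18.1f} {ablation.hr_bpm[i]:20.1f}"
          f" {ref.hr_bpm[i]:12.1f}")

keep = ~est.warmup
rep = compute_errors(est, ref, exclude_warmup=True)
mae_ab = np.mean(np.abs(ablation.hr_bpm[keep] - ref.hr_bpm[keep]))
print(f"\nfull pipeline:  Error1 = {rep.error1:.2f} BPM, Error2 = {rep.error2:.2f} %")
print(f"no cancellation: MAE = {mae_ab:.1f} BPM")
print("The canceller keeps the tracker on the true 78 BPM line; without it")
print("the tracker follows the 2 Hz (120 BPM) gait artifact instead.")
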