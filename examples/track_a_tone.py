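"""Track the frequency of a clean tone with the adaptive notch filter.

A 1.2 Hz sinusoid at the 25 Hz working rate corresponds to 72 BPM; the
tracker starts from its 90 BPM initialization and converges within a
few seconds.
"""

import numpy as np

from pulsetrack import NrOscAnfTracker

fs = 25.0
t = np.arange(0, 60, 1 / fs)
tracker = NrOscAnfTracker(fs=fs)
hr = tracker.run(np.sin(2 * np.pi * 1.2 * t))

for sec in (1, 2, 5, 10, 30, 60):
    print(f"t = {sec:3d} s   HR estimate = {hr[int(sec * fs) - 1]:6.2f} BPM")
print(f"\nconverged mean over the last 30 s: {np.mean(hr[int(30 * fs):]):.2f} BPM"
      " (true rate 72.00 BPM)")
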