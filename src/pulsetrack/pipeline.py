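"""Sample-by-sample orchestration of the three estimation stages.

Per sample n:

1. the feedback band-pass re-filters the preprocessed PPG around the
   tracker's most recent frequency estimate (skipped when disabled),
2. the motion-artifact canceller consumes the (filtered) PPG and the
   accelerometer triplet and emits the residual e(n),
3. the adaptive notch tracker consumes e(n) and emits the per-sample HR.

The per-sample trajectory is then aggregated into overlapping windows
(8 s advanced by 2 s by default) to form the reported HR series.
"""

from __future__ import annotations

import logging

import numpy as np

from .config import PipelineConfig
from .containers import HRSeries, SensorFrame
from .ma_reduction import SignSignFilter, ThreeAxisNLMS
from .tracking import FeedbackBandpass, NrOscAnfTracker, OscAnfTracker

__all__ = ["Pipeline", "run_pipeline", "make_windowed_hr"]

logger = logging.getLogger(__name__)


class Pipeline:
    """Streaming HR estimator holding the three stage states.

    The stages are exposed as attributes (``feedback``, ``ma``,
    ``tracker``) for inspection; each counts the samples it has consumed.
    """

    def __init__(self, fs: float, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        self.fs = float(fs)
        anf = self.config.anf
        ma = self.config.ma
        if anf.variant == "nr_osc":
            self.tracker = NrOscAnfTracker(fs=self.fs, beta=anf.beta,
                                           mu_a=anf.mu_a,
                                           f_init_bpm=anf.f_init_bpm, L=anf.L)
        else:
            self.tracker = OscAnfTracker(fs=self.fs, beta=anf.beta,
                                         mu_a=anf.mu_a,
                                         f_init_bpm=anf.f_init_bpm)
        self.feedback = FeedbackBandpass(beta_hr=anf.beta_hr) if anf.feedback else None
        if ma.algorithm == "sign_sign":
            self.ma = SignSignFilter(taps=ma.taps, mu=ma.mu)
        elif ma.algorithm == "nlms":
            self.ma = ThreeAxisNLMS(taps=ma.taps, mu=ma.mu, eps=ma.eps)
        else:
            self.ma = None
        self.n_steps = 0
        self.last_residual = 0.0

    def process_sample(self, ppg: float, ax: float, ay: float, az: float) -> float:
        """Advance all stages by one sample; return the per-sample HR."""
        if self.feedback is not None:
            # α̂ here is the tracker's output from the previous sample
            d = self.feedback.step(ppg, self.tracker.alpha_hat)
        else:
            d = ppg
        if self.ma is not None:
            e, _ = self.ma.step(ax, ay, az, d)
        else:
            e = d
        self.last_residual = e
        hr = self.tracker.step(e)
        self.n_steps += 1
        return hr

    def run(self, frame: SensorFrame) -> HRSeries:
        """Process a whole frame; return the windowed HR series."""
        win = self.config.window
        if frame.n_samples < int(round(win.window_s * frame.fs)):
            raise ValueError(
                f"frame of {frame.n_samples} samples is shorter than one "
                f"{win.window_s} s window at {frame.fs} Hz")
        per_sample = np.empty(frame.n_samples)
        res_sq = 0.0
        log_every = max(1, int(round(win.step_s * frame.fs)))
        for n in range(frame.n_samples):
            per_sample[n] = self.process_sample(
                frame.ppg[n], frame.accel_x[n], frame.accel_y[n],
                frame.accel_z[n])
            res_sq += self.last_residual ** 2
            if logger.isEnabledFor(logging.DEBUG) and (n + 1) % log_every == 0:
                logger.debug(
                    "n=%d alpha_hat=%.6f Px=%.3e residual_power=%.3e",
                    n + 1, self.tracker.alpha_hat, self.tracker.Px,
                    res_sq / (n + 1))
        return make_windowed_hr(per_sample, frame.fs, window_s=win.window_s,
                                step_s=win.step_s, t0=frame.t0, stat=win.stat)


def run_pipeline(frame: SensorFrame, config: PipelineConfig | None = None) -> HRSeries:
    """Run the full three-stage estimator on a preprocessed frame.

    ``frame`` is expected at the working rate (25 Hz by default). The
    output is deterministic given frame and config.
    """
    return Pipeline(frame.fs, config).run(frame)


def make_windowed_hr(per_sample_hr: np.ndarray, fs: float, window_s: float = 8.0,
                     step_s: float = 2.0, t0: float = 0.0,
                     stat: str = "mean") -> HRSeries:
    """Aggregate a per-sample HR trajectory into overlapping windows.

    Each output point is the mean (or median) of the per-sample HR over a
    ``window_s`` window advanced by ``step_s``; timestamps sit at the
    window end. Windows overlapping the first ``window_s`` of signal are
    flagged as warm-up.
    """
    if not window_s >= step_s > 0:
        raise ValueError(
            f"need window_s >= step_s > 0, got window_s={window_s}, step_s={step_s}")
    if stat not in ("mean", "median"):
        raise ValueError(f"stat must be 'mean' or 'median', got {stat!r}")
    x = np.asarray(per_sample_hr, dtype=float)
    wlen = int(round(window_s * fs))
    slen = int(round(step_s * fs))
    if x.size < wlen:
        raise ValueError(
            f"series of {x.size} samples is shorter than one window of {wlen}")
    agg = np.mean if stat == "mean" else np.median
    starts = np.arange(0, x.size - wlen + 1, slen)
    hr = np.array([agg(x[s:s + wlen]) for s in starts])
    t = t0 + (starts + wlen) / fs
    warmup = starts < wlen          # window overlaps the first window_s of signal
    return HRSeries(t=t, hr_bpm=hr, per_sample=x, fs=fs, warmup=warmup)
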