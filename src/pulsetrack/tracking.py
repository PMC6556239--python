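"""Adaptive single-tone frequency tracking of the artifact-reduced PPG.

The oscillator-based adaptive notch filter (OSC-ANF) drives a second-order
IIR resonator with the *sign* of its input and adapts the frequency
parameter α̂ = cos ω by a normalized gradient step until the resonator's
prediction error vanishes, i.e. until ω matches the strongest tone of the
input. Heart rate follows as HR = ω·f_s/(2π)·60.

The noise-robust variant (NR-OSC-ANF) anchors each adaptation step at the
running mean ᾱ of the last L frequency estimates instead of the latest
one, which suppresses estimate jitter at low SNR without changing the
converged value. With L = 1 it degenerates exactly — bit for bit — to the
plain OSC-ANF.

:class:`FeedbackBandpass` is the companion second-order IIR band-pass that
re-centers on the current α̂ and pre-filters the PPG before artifact
cancellation, closing the tracking loop.
"""

from __future__ import annotations

from collections import deque

import numpy as np

__all__ = ["OscAnfTracker", "NrOscAnfTracker", "FeedbackBandpass"]

_ALPHA_CLAMP = 1.0 - 1e-9


def _clamp_alpha(alpha: float) -> float:
    return float(min(_ALPHA_CLAMP, max(-_ALPHA_CLAMP, alpha)))


def hr_from_alpha(alpha: float, fs: float) -> float:
    """Convert the frequency parameter α = cos ω to BPM."""
    return float(np.arccos(alpha) * fs / (2.0 * np.pi) * 60.0)


class OscAnfTracker:
    """Oscillator-based adaptive notch filter (plain variant).

    Per input sample e(n), with s(n) = sign(e(n)):

        x(n)   = α̂(n)(1+β)x(n−1) − βx(n−2) + 0.5(1−β)(s(n) − s(n−2))
        e_α(n) = x(n) − 2α̂(n)x(n−1) + x(n−2)
        P_x(n) = (1−μ_a)P_x(n−1) + μ_a x²(n−1)
        α̂(n+1) = α̂(n) + μ_a x(n−1)/(2P_x(n)) · e_α(n)
        ω(n+1) = arccos α̂(n+1);  HR = ω·f_s/(2π)·60

    β controls the resonator's 3 dB bandwidth, μ_a the adaptation rate.
    α̂ is clamped to (−1, 1) after every update so the arccos is always
    defined, and the normalized gain is capped at unit magnitude for the
    first second to suppress the start-up transient while P_x is still
    dominated by its initialization.
    """

    def __init__(self, fs: float = 25.0, beta: float = 0.95,
                 mu_a: float = 0.025, f_init_bpm: float = 90.0):
        if fs <= 0:
            raise ValueError(f"fs must be positive, got {fs}")
        if not 0.0 < beta < 1.0:
            raise ValueError(f"beta must be in (0, 1), got {beta}")
        if mu_a <= 0:
            raise ValueError(f"mu_a must be positive, got {mu_a}")
        if not 0.0 < f_init_bpm < 60.0 * fs / 2.0:
            raise ValueError(f"f_init_bpm out of range: {f_init_bpm}")
        self.fs = float(fs)
        self.beta = float(beta)
        self.mu_a = float(mu_a)
        self.f_init_bpm = float(f_init_bpm)
        self.alpha_hat = _clamp_alpha(np.cos(2.0 * np.pi * (f_init_bpm / 60.0) / fs))
        self.x1 = 0.0   # x(n−1)
        self.x2 = 0.0   # x(n−2)
        self.e1 = 0.0   # sign(e(n−1))
        self.e2 = 0.0   # sign(e(n−2))
        self.Px = 1e-6
        self.n_steps = 0

    # anchor of the adaptation step; the NR variant overrides this
    def _anchor(self) -> float:
        return self.alpha_hat

    def _record(self, alpha_next: float) -> None:
        pass

    @property
    def hr_bpm(self) -> float:
        """HR corresponding to the current α̂."""
        return hr_from_alpha(self.alpha_hat, self.fs)

    def step(self, e_in: float) -> float:
        """Consume one residual sample; return the updated HR in BPM."""
        if not np.isfinite(e_in):
            raise ValueError(f"non-finite input sample: {e_in!r}")
        s = float(np.sign(e_in))
        a = self.alpha_hat
        x_n = a * (1.0 + self.beta) * self.x1 - self.beta * self.x2 \
            + 0.5 * (1.0 - self.beta) * (s - self.e2)
        anchor = self._anchor()
        e_alpha = x_n - 2.0 * anchor * self.x1 + self.x2
        self.Px = (1.0 - self.mu_a) * self.Px + self.mu_a * self.x1 * self.x1
        gain = self.mu_a * self.x1 / (2.0 * self.Px)
        if self.n_steps < self.fs:
            gain = min(1.0, max(-1.0, gain))
        alpha_next = _clamp_alpha(anchor + gain * e_alpha)
        self.alpha_hat = alpha_next
        self._record(alpha_next)
        self.x2, self.x1 = self.x1, x_n
        self.e2, self.e1 = self.e1, s
        self.n_steps += 1
        return hr_from_alpha(alpha_next, self.fs)

    def run(self, e: np.ndarray) -> np.ndarray:
        """Batch wrapper: per-sample HR trajectory for a residual series."""
        return np.array([self.step(v) for v in np.asarray(e, dtype=float)])

    def to_dict(self) -> dict:
        return {
            "variant": "osc", "fs": self.fs, "beta": self.beta,
            "mu_a": self.mu_a, "f_init_bpm": self.f_init_bpm,
            "alpha_hat": self.alpha_hat, "x1": self.x1, "x2": self.x2,
            "e1": self.e1, "e2": self.e2, "Px": self.Px,
            "n_steps": self.n_steps,
        }

    @classmethod
    def from_dict(cls, state: dict) -> "OscAnfTracker":
        obj = cls(fs=state["fs"], beta=state["beta"], mu_a=state["mu_a"],
                  f_init_bpm=state["f_init_bpm"])
        for key in ("alpha_hat", "x1", "x2", "e1", "e2", "Px"):
            setattr(obj, key, float(state[key]))
        obj.n_steps = int(state["n_steps"])
        return obj


class NrOscAnfTracker(OscAnfTracker):
    """Noise-robust OSC-ANF: adaptation anchored at the mean of recent α̂.

        ᾱ(n)   = (1/L) Σ_{l=0..L−1} α̂(n−l)      (including the current α̂)
        e_α(n) = x(n) − 2ᾱ(n)x(n−1) + x(n−2)
        α̂(n+1) = ᾱ(n) + μ_a x(n−1)/(2P_x(n)) · e_α(n)

    The oscillator recursion itself still uses the instantaneous α̂(n).
    Before L estimates exist the mean runs over those available.
    """

    def __init__(self, fs: float = 25.0, beta: float = 0.95,
                 mu_a: float = 0.025, f_init_bpm: float = 90.0, L: int = 5):
        if L < 1:
            raise ValueError(f"averaging length L must be >= 1, got {L}")
        super().__init__(fs=fs, beta=beta, mu_a=mu_a, f_init_bpm=f_init_bpm)
        self.L = int(L)
        self.alpha_history: deque = deque([self.alpha_hat], maxlen=self.L)

    def _anchor(self) -> float:
        return float(sum(self.alpha_history) / len(self.alpha_history))

    def _record(self, alpha_next: float) -> None:
        self.alpha_history.append(alpha_next)

    def to_dict(self) -> dict:
        state = super().to_dict()
        state["variant"] = "nr_osc"
        state["L"] = self.L
        state["alpha_history"] = list(self.alpha_history)
        return state

    @classmethod
    def from_dict(cls, state: dict) -> "NrOscAnfTracker":
        obj = cls(fs=state["fs"], beta=state["beta"], mu_a=state["mu_a"],
                  f_init_bpm=state["f_init_bpm"], L=state["L"])
        for key in ("alpha_hat", "x1", "x2", "e1", "e2", "Px"):
            setattr(obj, key, float(state[key]))
        obj.n_steps = int(state["n_steps"])
        obj.alpha_history = deque(
            [float(v) for v in state["alpha_history"]], maxlen=obj.L)
        return obj


class FeedbackBandpass:
    """Second-order IIR band-pass re-centered on the tracker's α̂.

        d_hr(n) = α̂(1+β_hr)·d_hr(n−1) − β_hr·d_hr(n−2)
                  + 0.5(1−β_hr)·(d(n) − d(n−2))

    d_hr replaces the raw PPG as the canceller's desired signal once the
    loop is closed; β_hr sets the 3 dB bandwidth. The α̂ supplied at
    sample n is the tracker's estimate from sample n−1, which breaks the
    algebraic loop between the band-pass and the canceller/tracker.
    """

    def __init__(self, beta_hr: float = 0.8):
        if not 0.0 < beta_hr < 1.0:
            raise ValueError(f"beta_hr must be in (0, 1), got {beta_hr}")
        self.beta_hr = float(beta_hr)
        self.d1 = 0.0
        self.d2 = 0.0
        self.dhr1 = 0.0
        self.dhr2 = 0.0
        self.n_steps = 0

    def step(self, d: float, alpha_hat: float) -> float:
        if not (np.isfinite(d) and np.isfinite(alpha_hat)):
            raise ValueError("non-finite input to feedback band-pass")
        if not -1.0 < alpha_hat < 1.0:
            raise ValueError(f"alpha_hat must lie in (-1, 1), got {alpha_hat}")
        b = self.beta_hr
        d_hr = alpha_hat * (1.0 + b) * self.dhr1 - b * self.dhr2 \
            + 0.5 * (1.0 - b) * (d - self.d2)
        self.d2, self.d1 = self.d1, d
        self.dhr2, self.dhr1 = self.dhr1, d_hr
        self.n_steps += 1
        return float(d_hr)

    def to_dict(self) -> dict:
        return {"beta_hr": self.beta_hr, "d1": self.d1, "d2": self.d2,
                "dhr1": self.dhr1, "dhr2": self.dhr2, "n_steps": self.n_steps}

    @classmethod
    def from_dict(cls, state: dict) -> "FeedbackBandpass":
        obj = cls(beta_hr=state["beta_hr"])
        for key in ("d1", "d2", "dhr1", "dhr2"):
            setattr(obj, key, float(state[key]))
        obj.n_steps = int(state["n_steps"])
        return obj
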