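"""Accelerometer-referenced motion-artifact cancellation.

Two adaptive noise cancellers share the same wiring: the corrupted PPG is
the desired signal d(n), the accelerometer axes are the reference inputs,
and the residual e(n) = d(n) − y(n) is the artifact-reduced PPG passed on
to the frequency tracker.

:class:`SignSignFilter` is the low-complexity canceller: three per-axis
weight vectors are driven purely by the *signs* of the reference samples
and of the shared error, normalized by the number of nonzero sign entries.
Every weight increment is therefore an element of {−μ/c, 0, +μ/c}, and the
filter output itself is a sum of ±weights, so a hardware implementation
needs at most M true multiplications per sample against 3M + 1 for an
NLMS canceller of the same total order.

:class:`NLMSFilter` is the conventional normalized-LMS baseline the
sign-sign scheme is compared against.

Both filters expose a per-sample streaming ``step`` and count their actual
multiply operations so the complexity claim is checkable at run time.
"""

from __future__ import annotations

import numpy as np

from .containers import SensorFrame

__all__ = [
    "NLMSFilter",
    "SignSignFilter",
    "ThreeAxisNLMS",
    "count_weight_multiplications",
    "run_sign_sign",
    "run_nlms",
]


def count_weight_multiplications(taps: int) -> tuple[int, int]:
    """Per-sample multiplication counts (sign-sign, NLMS) at filter order M.

    The sign-sign update and output are computable with additions only
    (sign vectors are in {−1, 0, 1}); M is its worst-case bound. NLMS needs
    M for the output inner product, M for the input-power norm, and M + 1
    to scale the update, i.e. 3M + 1.
    """
    if taps < 1:
        raise ValueError(f"taps must be >= 1, got {taps}")
    return taps, 3 * taps + 1


def _check_finite(*values: float) -> None:
    for v in values:
        if not np.isfinite(v):
            raise ValueError(f"non-finite input sample: {v!r}")


class NLMSFilter:
    """Normalized LMS adaptive filter (single reference input).

    Update: w(n) = w(n−1) + μ·u(n)/(uᵀu + eps)·e(n) with
    e(n) = d(n) − uᵀ(n)w(n−1). The regularizer ``eps`` guards the
    normalization against a vanishing input; with ``eps=0`` an all-zero
    delay line raises.
    """

    def __init__(self, taps: int = 21, mu: float = 1e-4, eps: float = 1e-8):
        if taps < 1:
            raise ValueError(f"taps must be >= 1, got {taps}")
        if not 0.0 < mu <= 1.0:
            raise ValueError(f"step size mu must be in (0, 1], got {mu}")
        if eps < 0:
            raise ValueError(f"eps must be >= 0, got {eps}")
        self.taps = int(taps)
        self.mu = float(mu)
        self.eps = float(eps)
        self.w = np.zeros(self.taps)
        self.u = np.zeros(self.taps)
        self.n_steps = 0
        self.multiplications = 0

    def step(self, u_new: float, d: float) -> tuple[float, float]:
        """Consume one reference/desired sample pair; return (e, y)."""
        _check_finite(u_new, d)
        self.u[1:] = self.u[:-1]
        self.u[0] = u_new
        y = float(self.u @ self.w)               # M multiplies
        self.multiplications += self.taps
        e = d - y
        norm = float(self.u @ self.u)            # M multiplies
        self.multiplications += self.taps
        if norm == 0.0 and self.eps == 0.0:
            raise ZeroDivisionError("all-zero delay line with eps=0")
        g = self.mu * e                           # 1 multiply
        self.w = self.w + (g / (norm + self.eps)) * self.u   # M multiplies
        self.multiplications += self.taps + 1
        self.n_steps += 1
        return e, y

    def to_dict(self) -> dict:
        return {"taps": self.taps, "mu": self.mu, "eps": self.eps,
                "w": self.w.tolist(), "u": self.u.tolist(),
                "n_steps": self.n_steps}

    @classmethod
    def from_dict(cls, state: dict) -> "NLMSFilter":
        obj = cls(taps=state["taps"], mu=state["mu"], eps=state["eps"])
        obj.w = np.asarray(state["w"], dtype=float)
        obj.u = np.asarray(state["u"], dtype=float)
        obj.n_steps = int(state["n_steps"])
        return obj


class SignSignFilter:
    """Three-axis sign-sign adaptive canceller.

    Per sample, with sign vectors s_a = sign(u_a) for axis a ∈ {x, y, z}
    (three-valued sign, sign(0) = 0) and c_a = number of nonzero entries
    of s_a:

        y(n) = s_xᵀ w_x + s_yᵀ w_y + s_zᵀ w_z        (previous weights)
        e(n) = d(n) − y(n)
        w_a ← w_a + μ · s_a / c_a · sign(e(n))

    All three axis updates use the pre-update weights and the same scalar
    error, so their order is immaterial. An axis whose delay line is all
    zero (c_a = 0) is skipped for that sample — with no motion reference
    at all the filter is exactly transparent (e ≡ d). Reading only signs
    makes the filter invariant to any positive rescaling of the
    accelerometer channels.
    """

    def __init__(self, taps: int = 21, mu: float = 1e-4):
        if taps < 1:
            raise ValueError(f"taps must be >= 1, got {taps}")
        if not 0.0 < mu <= 1.0:
            raise ValueError(f"step size mu must be in (0, 1], got {mu}")
        self.taps = int(taps)
        self.mu = float(mu)
        self.w_x = np.zeros(self.taps)
        self.w_y = np.zeros(self.taps)
        self.w_z = np.zeros(self.taps)
        self.u_x = np.zeros(self.taps)
        self.u_y = np.zeros(self.taps)
        self.u_z = np.zeros(self.taps)
        self.n_steps = 0
        self.multiplications = 0

    def step(self, ax: float, ay: float, az: float, d: float) -> tuple[float, float]:
        """Consume one accelerometer triplet and desired sample; return (e, y)."""
        _check_finite(ax, ay, az, d)
        for line, new in ((self.u_x, ax), (self.u_y, ay), (self.u_z, az)):
            line[1:] = line[:-1]
            line[0] = new
        s_x = np.sign(self.u_x)
        s_y = np.sign(self.u_y)
        s_z = np.sign(self.u_z)
        # sums of ±w: no true multiplications
        y = float(s_x @ self.w_x + s_y @ self.w_y + s_z @ self.w_z)
        e = d - y
        se = np.sign(e)
        for s, w in ((s_x, self.w_x), (s_y, self.w_y), (s_z, self.w_z)):
            c = int(np.count_nonzero(s))
            if c == 0:
                continue
            inc = (self.mu / c) * se              # 1 multiply per active axis
            self.multiplications += 1
            w += inc * s                          # adds/subtracts of ±inc
        self.n_steps += 1
        return e, y

    def to_dict(self) -> dict:
        return {"taps": self.taps, "mu": self.mu,
                "w_x": self.w_x.tolist(), "w_y": self.w_y.tolist(),
                "w_z": self.w_z.tolist(),
                "u_x": self.u_x.tolist(), "u_y": self.u_y.tolist(),
                "u_z": self.u_z.tolist(), "n_steps": self.n_steps}

    @classmethod
    def from_dict(cls, state: dict) -> "SignSignFilter":
        obj = cls(taps=state["taps"], mu=state["mu"])
        for name in ("w_x", "w_y", "w_z", "u_x", "u_y", "u_z"):
            setattr(obj, name, np.asarray(state[name], dtype=float))
        obj.n_steps = int(state["n_steps"])
        return obj


class ThreeAxisNLMS:
    """NLMS canceller over the concatenated 3-axis reference.

    Multi-reference form of the NLMS baseline: a single NLMS filter whose
    delay line stacks the three per-axis delay lines (3·taps weights in
    total), the textbook wiring for multichannel adaptive noise
    cancellation. Presents the same ``step(ax, ay, az, d)`` surface as
    :class:`SignSignFilter` so the two are interchangeable in the pipeline.
    """

    def __init__(self, taps: int = 21, mu: float = 1e-4, eps: float = 1e-8):
        if taps < 1:
            raise ValueError(f"taps must be >= 1, got {taps}")
        self.taps = int(taps)
        self._nlms = NLMSFilter(taps=3 * self.taps, mu=mu, eps=eps)
        # the stacked delay line is managed here, not by per-sample shifting
        self.u_x = np.zeros(self.taps)
        self.u_y = np.zeros(self.taps)
        self.u_z = np.zeros(self.taps)

    @property
    def n_steps(self) -> int:
        return self._nlms.n_steps

    @property
    def multiplications(self) -> int:
        return self._nlms.multiplications

    @property
    def w(self) -> np.ndarray:
        return self._nlms.w

    def step(self, ax: float, ay: float, az: float, d: float) -> tuple[float, float]:
        _check_finite(ax, ay, az, d)
        for line, new in ((self.u_x, ax), (self.u_y, ay), (self.u_z, az)):
            line[1:] = line[:-1]
            line[0] = new
        self._nlms.u = np.concatenate([self.u_x, self.u_y, self.u_z])
        # delegate with a dummy shift-in equal to the first element already set
        nlms = self._nlms
        y = float(nlms.u @ nlms.w)
        nlms.multiplications += nlms.taps
        e = d - y
        norm = float(nlms.u @ nlms.u)
        nlms.multiplications += nlms.taps
        if norm == 0.0 and nlms.eps == 0.0:
            raise ZeroDivisionError("all-zero delay line with eps=0")
        g = nlms.mu * e
        nlms.w = nlms.w + (g / (norm + nlms.eps)) * nlms.u
        nlms.multiplications += nlms.taps + 1
        nlms.n_steps += 1
        return e, y

    def to_dict(self) -> dict:
        return {"taps": self.taps, "nlms": self._nlms.to_dict(),
                "u_x": self.u_x.tolist(), "u_y": self.u_y.tolist(),
                "u_z": self.u_z.tolist()}

    @classmethod
    def from_dict(cls, state: dict) -> "ThreeAxisNLMS":
        obj = cls(taps=state["taps"])
        obj._nlms = NLMSFilter.from_dict(state["nlms"])
        for name in ("u_x", "u_y", "u_z"):
            setattr(obj, name, np.asarray(state[name], dtype=float))
        return obj


def run_sign_sign(frame: SensorFrame, taps: int = 21, mu: float = 1e-4
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Batch wrapper: map a whole frame to (residual e, artifact estimate y)."""
    filt = SignSignFilter(taps=taps, mu=mu)
    e = np.empty(frame.n_samples)
    y = np.empty(frame.n_samples)
    for n in range(frame.n_samples):
        e[n], y[n] = filt.step(frame.accel_x[n], frame.accel_y[n],
                               frame.accel_z[n], frame.ppg[n])
    return e, y


def run_nlms(frame: SensorFrame, taps: int = 21, mu: float = 1e-4,
             eps: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Batch wrapper for the three-axis NLMS baseline."""
    filt = ThreeAxisNLMS(taps=taps, mu=mu, eps=eps)
    e = np.empty(frame.n_samples)
    y = np.empty(frame.n_samples)
    for n in range(frame.n_samples):
        e[n], y[n] = filt.step(frame.accel_x[n], frame.accel_y[n],
                               frame.accel_z[n], frame.ppg[n])
    return e, y
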