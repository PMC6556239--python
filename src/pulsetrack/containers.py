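"""Core data containers shared across the pipeline stages.

A :class:`SensorFrame` holds one synchronized multichannel record — a PPG
channel plus the three accelerometer axes — at a single sampling rate.
:class:`HRSeries` is a heart-rate trajectory (windowed and/or per-sample),
and :class:`ErrorReport` summarizes agreement between an estimated and a
reference trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SensorFrame", "HRSeries", "ErrorReport"]


def _as_finite_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size < 1:
        raise ValueError(f"{name} must have at least one sample")
    if not np.all(np.isfinite(arr)):
        idx = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"non-finite value in {name} at index {idx}")
    return arr


@dataclass
class SensorFrame:
    """Synchronized PPG + 3-axis accelerometer record.

    Parameters
    ----------
    ppg : array_like
        PPG channel, arbitrary (analog) units.
    accel_x, accel_y, accel_z : array_like
        Accelerometer axes, arbitrary units (typically g).
    fs : float
        Sampling rate in Hz (> 0).
    t0 : float
        Start time in seconds.
    """

    ppg: np.ndarray
    accel_x: np.ndarray
    accel_y: np.ndarray
    accel_z: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.ppg = _as_finite_1d(self.ppg, "ppg")
        self.accel_x = _as_finite_1d(self.accel_x, "accel_x")
        self.accel_y = _as_finite_1d(self.accel_y, "accel_y")
        self.accel_z = _as_finite_1d(self.accel_z, "accel_z")
        n = self.ppg.size
        for name in ("accel_x", "accel_y", "accel_z"):
            if getattr(self, name).size != n:
                raise ValueError(
                    f"channel length mismatch: ppg has {n} samples, "
                    f"{name} has {getattr(self, name).size}"
                )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        self.fs = float(self.fs)
        self.t0 = float(self.t0)

    @property
    def n_samples(self) -> int:
        return int(self.ppg.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def t(self) -> np.ndarray:
        """Sample timestamps in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def replace(self, **kwargs) -> "SensorFrame":
        """Copy of the frame with some fields replaced."""
        fields = dict(
            ppg=self.ppg, accel_x=self.accel_x, accel_y=self.accel_y,
            accel_z=self.accel_z, fs=self.fs, t0=self.t0,
        )
        fields.update(kwargs)
        return SensorFrame(**fields)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.t,
                "ppg": self.ppg,
                "ax": self.accel_x,
                "ay": self.accel_y,
                "az": self.accel_z,
            }
        )


@dataclass
class HRSeries:
    """Heart-rate trajectory in BPM.

    ``t``/``hr_bpm`` hold the (typically windowed) trajectory; ``per_sample``
    optionally carries the full-rate trajectory at ``fs``. ``warmup`` flags
    windows that overlap the pipeline's start-up transient.
    """

    t: np.ndarray
    hr_bpm: np.ndarray
    per_sample: np.ndarray | None = None
    fs: float | None = None
    warmup: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.hr_bpm = np.asarray(self.hr_bpm, dtype=float)
        if self.t.shape != self.hr_bpm.shape:
            raise ValueError("t and hr_bpm must have the same shape")
        if self.t.size >= 2 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not np.all(np.isfinite(self.hr_bpm)) or np.any(self.hr_bpm <= 0):
            raise ValueError("hr_bpm must be finite and positive")
        if self.per_sample is not None:
            self.per_sample = np.asarray(self.per_sample, dtype=float)
        if self.warmup is not None:
            self.warmup = np.asarray(self.warmup, dtype=bool)
            if self.warmup.shape != self.t.shape:
                raise ValueError("warmup flags must match t in shape")

    @property
    def n(self) -> int:
        return int(self.t.size)

    def to_dataframe(self) -> pd.DataFrame:
        out = pd.DataFrame({"t": self.t, "hr_bpm": self.hr_bpm})
        if self.warmup is not None:
            out["warmup"] = self.warmup.astype(int)
        return out

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, t_col: str = "t", hr_col: str = "hr_bpm") -> "HRSeries":
        df = pd.read_csv(path)
        for col in (t_col, hr_col):
            if col not in df.columns:
                raise ValueError(f"missing column {col!r} in {path}")
        warmup = df["warmup"].to_numpy(bool) if "warmup" in df.columns else None
        return cls(t=df[t_col].to_numpy(float), hr_bpm=df[hr_col].to_numpy(float),
                   warmup=warmup)


@dataclass
class ErrorReport:
    """Agreement summary between an estimated and a reference HR series.

    ``error1`` is the mean absolute error in BPM; ``error2`` the mean
    absolute percentage error in percent. ``bland_altman`` is
    (mean difference, lower limit of agreement, upper limit) in BPM with
    limits at mean ± 1.96·SD of the paired differences; ``fit`` is the
    (slope, intercept) of the least-squares line of estimate on reference.
    """

    error1: float
    error2: float
    n: int
    bland_altman: tuple = field(default=(np.nan, np.nan, np.nan))
    fit: tuple = field(default=(np.nan, np.nan))

    def to_dict(self) -> dict:
        md, lo, hi = self.bland_altman
        slope, intercept = self.fit
        return {
            "schema_version": 1,
            "error1_bpm": float(self.error1),
            "error2_pct": float(self.error2),
            "n": int(self.n),
            "bland_altman": {
                "mean_diff_bpm": float(md),
                "loa_lower_bpm": float(lo),
                "loa_upper_bpm": float(hi),
            },
            "fit": {"slope": float(slope), "intercept": float(intercept)},
        }
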