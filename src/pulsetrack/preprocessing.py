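"""Ingest, resampling and band-limiting of raw sensor data.

Raw recordings (nominally 125 Hz) are decimated to the working rate of
25 Hz with an FIR anti-aliasing low-pass, and the PPG channel is
band-passed to the physiological heart-rate band (0.4–4 Hz by default,
i.e. 24–240 BPM). Accelerometer channels are resampled but never
band-passed: the motion-artifact canceller reads only their signs and
expects the raw motion reference.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import loadmat

from .containers import SensorFrame

__all__ = [
    "read_csv_frame",
    "write_csv_frame",
    "read_mat_frame",
    "resample_frame",
    "bandpass_prefilter",
    "preprocess",
]

DEFAULT_COLUMN_MAP = {"ppg": "ppg", "ax": "ax", "ay": "ay", "az": "az"}


def read_csv_frame(path, column_map: dict | None = None, fs: float = 125.0,
                   ppg_combine: str = "mean") -> SensorFrame:
    """Read a multichannel CSV recording into a :class:`SensorFrame`.

    Parameters
    ----------
    path : path-like
        CSV file with a header row and '.' decimal separator.
    column_map : dict, optional
        Maps roles (``ppg``, optional ``ppg2``, ``ax``, ``ay``, ``az``,
        optional ``time``) to column names. Defaults to identical names.
    fs : float
        Sampling rate of the file in Hz.
    ppg_combine : {"mean", "first"}
        How two mapped PPG columns are combined into the single channel.

    Raises
    ------
    ValueError
        If a mapped column is missing (naming the column) or a sample is
        non-finite (citing the row index).
    """
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    if ppg_combine not in ("mean", "first"):
        raise ValueError(f"ppg_combine must be 'mean' or 'first', got {ppg_combine!r}")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path)
    for role in ("ppg", "ax", "ay", "az"):
        if cmap[role] not in df.columns:
            raise ValueError(f"missing column {cmap[role]!r} (role {role!r}) in {path}")

    def _col(role):
        col = df[cmap[role]].to_numpy(dtype=float)
        bad = ~np.isfinite(col)
        if bad.any():
            raise ValueError(
                f"non-finite value in column {cmap[role]!r} at row {int(np.flatnonzero(bad)[0])}"
            )
        return col

    ppg = _col("ppg")
    if "ppg2" in cmap and cmap["ppg2"] is not None and cmap["ppg2"] in df.columns:
        if ppg_combine == "mean":
            ppg = 0.5 * (ppg + _col("ppg2"))
    t0 = 0.0
    if "time" in cmap and cmap.get("time") in df.columns:
        t0 = float(df[cmap["time"]].iloc[0])
    return SensorFrame(ppg=ppg, accel_x=_col("ax"), accel_y=_col("ay"),
                       accel_z=_col("az"), fs=fs, t0=t0)


def write_csv_frame(frame: SensorFrame, path) -> None:
    """Write a frame as CSV with columns time, ppg, ax, ay, az."""
    frame.to_dataframe().to_csv(path, index=False)


def read_mat_frame(path, layout: dict) -> SensorFrame:
    """Read a MATLAB-container recording (e.g. IEEE SPC 2015 sets).

    The channel layout is supplied via ``layout`` rather than hard-coded::

        layout = {"var": "sig", "ppg_rows": [1, 2],
                  "accel_rows": [3, 4, 5], "fs": 125,
                  "ppg_combine": "mean"}

    ``ppg_rows``/``accel_rows`` are 0-based row indices into the 2-D array
    stored under ``var``. Two PPG rows are combined per ``ppg_combine``.
    """
    required = ("var", "ppg_rows", "accel_rows", "fs")
    for key in required:
        if key not in layout:
            raise ValueError(f"layout is missing required key {key!r}")
    mat = loadmat(path)
    var = layout["var"]
    if var not in mat:
        raise ValueError(f"variable {var!r} not found in {path}")
    sig = np.asarray(mat[var], dtype=float)
    if sig.ndim != 2:
        raise ValueError(f"variable {var!r} must be 2-D, got shape {sig.shape}")
    ppg_rows = list(layout["ppg_rows"])
    accel_rows = list(layout["accel_rows"])
    if len(accel_rows) != 3:
        raise ValueError("accel_rows must list exactly three row indices")
    combine = layout.get("ppg_combine", "mean")
    if combine == "first" or len(ppg_rows) == 1:
        ppg = sig[ppg_rows[0]]
    elif combine == "mean":
        ppg = sig[ppg_rows].mean(axis=0)
    else:
        raise ValueError(f"ppg_combine must be 'mean' or 'first', got {combine!r}")
    ax, ay, az = (sig[r] for r in accel_rows)
    return SensorFrame(ppg=ppg, accel_x=ax, accel_y=ay, accel_z=az,
                       fs=float(layout["fs"]))


def resample_frame(frame: SensorFrame, target_fs: float) -> SensorFrame:
    """Resample all channels to ``target_fs`` with anti-aliasing.

    Integer decimation (e.g. 125 → 25 Hz, factor 5) uses a zero-phase FIR
    anti-aliasing low-pass followed by take-every-q-th, so no group-delay
    correction is needed and the first output sample is aligned with the
    first input sample; the output length is ``ceil(n / q)``. Rationally
    related rates fall back to polyphase resampling. Upsampling is out of
    contract.
    """
    if target_fs >= frame.fs:
        raise ValueError(
            f"target_fs ({target_fs}) must be below the frame rate ({frame.fs}); "
            "upsampling is not supported"
        )
    ratio = Fraction(target_fs / frame.fs).limit_denominator(1000)
    channels = (frame.ppg, frame.accel_x, frame.accel_y, frame.accel_z)
    if ratio.numerator == 1:
        q = ratio.denominator
        out = [signal.decimate(c, q, ftype="fir", zero_phase=True) for c in channels]
    else:
        out = [signal.resample_poly(c, ratio.numerator, ratio.denominator)
               for c in channels]
    return SensorFrame(ppg=out[0], accel_x=out[1], accel_y=out[2], accel_z=out[3],
                       fs=float(target_fs), t0=frame.t0)


def bandpass_prefilter(frame: SensorFrame, low_hz: float = 0.4,
                       high_hz: float = 4.0, order: int = 4) -> SensorFrame:
    """Zero-phase Butterworth band-pass applied to the PPG channel only.

    The default 0.4–4 Hz band covers 24–240 BPM while rejecting baseline
    wander and high-frequency noise. The accelerometer channels pass
    through untouched so the artifact canceller sees the raw motion
    reference.
    """
    nyq = frame.fs / 2.0
    if not (0.0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2; "
            f"got low={low_hz}, high={high_hz}, fs/2={nyq}"
        )
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=frame.fs,
                        output="sos")
    return frame.replace(ppg=signal.sosfiltfilt(sos, frame.ppg))


def preprocess(frame: SensorFrame, fs_target: float = 25.0,
               band_low_hz: float = 0.4, band_high_hz: float = 4.0) -> SensorFrame:
    """Resample to the working rate and band-limit the PPG channel."""
    if frame.fs != fs_target:
        frame = resample_frame(frame, fs_target)
    return bandpass_prefilter(frame, band_low_hz, band_high_hz)
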