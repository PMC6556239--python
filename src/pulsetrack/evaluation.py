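"""Error metrics and agreement statistics against a reference HR series.

Error1 is the mean absolute difference in BPM, Error2 the mean absolute
percentage error (reported in percent). Bland–Altman limits of agreement
use the conventional mean difference ± 1.96·SD of the paired differences
(sample SD, n−1 denominator).
"""

from __future__ import annotations

import numpy as np

from .containers import ErrorReport, HRSeries

__all__ = ["align_series", "compute_errors", "plot_bland_altman", "plot_scatter"]


def align_series(est: HRSeries, ref: HRSeries, tol: float | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Inner-join two series on timestamps within ``tol`` seconds.

    ``tol`` defaults to half the median reference step. Returns the
    matched (est, ref) value arrays.
    """
    if tol is None:
        steps = np.diff(ref.t)
        tol = 0.5 * float(np.median(steps)) if steps.size else 0.5
    idx = np.searchsorted(ref.t, est.t)
    est_vals, ref_vals = [], []
    for i, (t, v) in enumerate(zip(est.t, est.hr_bpm)):
        j = idx[i]
        best, dist = None, tol
        for k in (j - 1, j):
            if 0 <= k < ref.t.size and abs(ref.t[k] - t) <= dist:
                best, dist = k, abs(ref.t[k] - t)
        if best is not None:
            est_vals.append(v)
            ref_vals.append(ref.hr_bpm[best])
    if not est_vals:
        raise ValueError("no overlapping timestamps between series")
    return np.asarray(est_vals), np.asarray(ref_vals)


def compute_errors(est: HRSeries, ref: HRSeries, tol: float | None = None,
                   exclude_warmup: bool = False) -> ErrorReport:
    """Compare an estimated HR series against a reference.

    Parameters
    ----------
    est, ref : HRSeries
        Series to compare; aligned by inner join on timestamps.
    tol : float, optional
        Alignment tolerance in seconds (default half the reference step).
    exclude_warmup : bool
        Drop estimate windows flagged as warm-up before comparing.
    """
    if exclude_warmup and est.warmup is not None:
        keep = ~est.warmup
        est = HRSeries(t=est.t[keep], hr_bpm=est.hr_bpm[keep])
    e, r = align_series(est, ref, tol=tol)
    diff = e - r
    error1 = float(np.mean(np.abs(diff)))
    error2 = float(np.mean(np.abs(diff) / r) * 100.0)
    md = float(np.mean(diff))
    if diff.size >= 2:
        sd = float(np.std(diff, ddof=1))
        loa = (md - 1.96 * sd, md + 1.96 * sd)
    else:
        loa = (np.nan, np.nan)
    slope, intercept = np.polyfit(r, e, 1) if np.ptp(r) > 0 else (np.nan, np.nan)
    if np.ptp(r) == 0:
        # degenerate reference: slope undefined, report identity offset
        slope, intercept = np.nan, md
    return ErrorReport(error1=error1, error2=error2, n=int(diff.size),
                       bland_altman=(md, loa[0], loa[1]),
                       fit=(float(slope), float(intercept)))


def plot_bland_altman(est: HRSeries, ref: HRSeries, ax=None):
    """Bland–Altman plot (difference vs mean) with limits of agreement."""
    import matplotlib.pyplot as plt

    e, r = align_series(est, ref)
    diff = e - r
    mean = 0.5 * (e + r)
    md = np.mean(diff)
    sd = np.std(diff, ddof=1)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(mean, diff, s=10, alpha=0.6)
    for y, style in ((md, "-"), (md - 1.96 * sd, "--"), (md + 1.96 * sd, "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of estimate and reference (BPM)")
    ax.set_ylabel("estimate − reference (BPM)")
    return ax


def plot_scatter(est: HRSeries, ref: HRSeries, ax=None):
    """Estimate-vs-reference scatter with the least-squares line."""
    import matplotlib.pyplot as plt

    e, r = align_series(est, ref)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(r, e, s=10, alpha=0.6)
    if np.ptp(r) > 0:
        slope, intercept = np.polyfit(r, e, 1)
        xs = np.array([r.min(), r.max()])
        ax.plot(xs, slope * xs + intercept, "k-", linewidth=1,
                label=f"y = {slope:.4f}x + {intercept:.3f}")
        ax.legend()
    ax.set_xlabel("reference HR (BPM)")
    ax.set_ylabel("estimated HR (BPM)")
    return ax
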