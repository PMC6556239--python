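#!/usr/bin/env python
"""Evaluate the pipeline on IEEE Signal Processing Cup 2015 recordings.

The recordings are not distributed with this package; obtain them
separately and point this script at the directory. Each training set is
a MATLAB container holding a signal matrix (ECG, two PPG channels, three
accelerometer axes at 125 Hz) plus a companion file with the ECG-derived
reference HR per 8 s window advanced by 2 s.

Usage:
    python scripts/reproduce_spc2015.py --data-dir DIR [--layout layout.yaml]

The default layout matches the published channel order; override it via
a YAML file with keys var/ppg_rows/accel_rows/fs if your copy differs.
Prints per-set Error1 (BPM) and Error2 (%) and their mean +/- SD.
"""

import argparse
import glob
import os

import numpy as np
import yaml
from scipy.io import loadmat

from pulsetrack import (HRSeries, compute_errors, preprocess, read_mat_frame,
                        run_pipeline)

DEFAULT_LAYOUT = {"var": "sig", "ppg_rows": [1, 2], "accel_rows": [3, 4, 5],
                  "fs": 125, "ppg_combine": "mean"}


def load_reference_bpm(path):
    mat = loadmat(path)
    for key in ("BPM0", "bpm", "BPM"):
        if key in mat:
            return np.asarray(mat[key], dtype=float).ravel()
    raise ValueError(f"no reference BPM variable found in {path}")


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", required=True)
    parser.add_argument("--layout", help="YAML channel-layout override")
    parser.add_argument("--window-s", type=float, default=8.0)
    parser.add_argument("--step-s", type=float, default=2.0)
    args = parser.parse_args()

    layout = dict(DEFAULT_LAYOUT)
    if args.layout:
        with open(args.layout) as fh:
            layout.update(yaml.safe_load(fh) or {})

    sets = sorted(glob.glob(os.path.join(args.data_dir, "DATA_*.mat")))
    sets = [p for p in sets if "BPMtrace" not in p and "BPM" not in os.path.basename(p)]
    if not sets:
        raise SystemExit(f"no DATA_*.mat recordings found under {args.data_dir}")

    err1s, err2s = [], []
    for path in sets:
        frame = read_mat_frame(path, layout)
        frame = preprocess(frame, fs_target=25.0)
        est = run_pipeline(frame)

        ref_path = path.replace(".mat", "_BPMtrace.mat")
        if not os.path.exists(ref_path):
            print(f"{os.path.basename(path)}: no reference trace, skipped")
            continue
        bpm = load_reference_bpm(ref_path)
        ref = HRSeries(t=args.window_s + args.step_s * np.arange(bpm.size),
                       hr_bpm=bpm)
        rep = compute_errors(est, ref)
        err1s.append(rep.error1)
        err2s.append(rep.error2)
        print(f"{os.path.basename(path)}: Error1 = {rep.error1:.2f} BPM, "
              f"Error2 = {rep.error2:.2f} % (n={rep.n})")

    if err1s:
        print(f"mean Error1 = {np.mean(err1s):.2f} +/- {np.std(err1s, ddof=1):.2f} BPM")
        print(f"mean Error2 = {np.mean(err2s):.2f} +/- {np.std(err2s, ddof=1):.2f} %")


if __name__ == "__main__":
    main()
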