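"""Stride-interval analysis of the PhysioNet neurodegenerative gait database.

Not part of the test suite: requires a user-downloaded copy of the "Gait in
Neurodegenerative Disease Database" (https://doi.org/10.13026/C27G6C),
whose `.ts` files hold two columns (left/right stride times in seconds).

Usage:
    python examples/gait_analysis.py --data-dir /path/to/gaitndd --out gait_result.json

Preprocessing (standard signal routines, outside the package's scope):
clip outliers beyond the 1st/96th percentiles and impute them with a
weighted moving average, resample to 2 Hz by linear interpolation, analyze
3.5 minutes after a 20-second warm-up, detrend, high-pass filter
(Butterworth, 0.01 Hz) and variance-standardize. The fitted series length
is T = 420 (210 s at 2 Hz), estimated with R = 20 sine tapers; band
boundaries are reported in Hz via the 2 Hz sampling rate.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
from scipy.interpolate import interp1d
from scipy.signal import butter, detrend, filtfilt

from fbam.ga import GAConfig, fit_grid
from fbam.io import write_result
from fbam.spectral import TimeSeriesSet, estimate_all

FS = 2.0  # Hz
WARMUP_S = 20.0
DURATION_S = 210.0


def weighted_moving_average(x: np.ndarray, bad: np.ndarray, half: int = 3) -> np.ndarray:
    """Replace flagged samples by a triangular-weighted local average."""
    out = x.copy()
    w = np.r_[np.arange(1, half + 1), half + 1, np.arange(half, 0, -1)].astype(float)
    for i in np.flatnonzero(bad):
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        seg = x[lo:hi]
        ok = ~bad[lo:hi]
        if ok.any():
            ww = w[half - (i - lo) : half + (hi - i)][ok]
            out[i] = np.average(seg[ok], weights=ww)
    return out


def preprocess(times: np.ndarray, intervals: np.ndarray) -> np.ndarray:
    lo, hi = np.percentile(intervals, [1, 96])
    bad = (intervals < lo) | (intervals > hi)
    clean = weighted_moving_average(intervals, bad)
    grid = np.arange(WARMUP_S, WARMUP_S + DURATION_S, 1.0 / FS)
    resampled = interp1d(times, clean, bounds_error=False, fill_value="extrapolate")(grid)
    resampled = detrend(resampled)
    b, a = butter(4, 0.01 / (FS / 2), btype="highpass")
    filtered = filtfilt(b, a, resampled)
    return filtered / filtered.std(ddof=1)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, required=True)
    parser.add_argument("--out", type=Path, default=Path("gait_result.json"))
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    series, ids = [], []
    for path in sorted(args.data_dir.glob("*.ts")):
        raw = np.loadtxt(path)
        times, left = raw[:, 0], raw[:, 1]
        if times[-1] < WARMUP_S + DURATION_S:
            print(f"skipping {path.name}: record too short", file=sys.stderr)
            continue
        series.append(preprocess(times, left))
        ids.append(path.stem)
    if not series:
        sys.exit("no usable .ts records found")

    data = TimeSeriesSet(np.asarray(series), series_ids=ids, sampling_rate=FS)
    spectra = estimate_all(data, R=20)
    result = fit_grid(
        spectra, J_grid=[2, 3, 4, 5], L_grid=[2, 3, 4],
        config=GAConfig(seed=args.seed), mode="joint",
    )
    write_result(result, args.out, spectra)
    print(f"selected J={result.selected[0]}, L={result.selected[1]} -> {args.out}")


if __name__ == "__main__":
    main()
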