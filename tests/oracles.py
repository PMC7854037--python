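"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the implementation's code paths: the window
scan enumerates every window position, the detector oracle scans runs
of supra-threshold samples, and the Pearson oracle is the textbook
two-pass product-moment formula.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_best_window_mean(x: np.ndarray, w: int) -> float:
    """Max mean over all contiguous length-w windows, by enumeration."""
    assert 1 <= w <= len(x)
    return max(float(np.mean(x[i:i + w])) for i in range(len(x) - w + 1))


def brute_force_detect(x: np.ndarray, fs: float, lower: float, upper: float,
                       refractory_s: float) -> list[dict]:
    """Reference hysteresis detector: runs of samples >= lower, merged
    when the below-threshold gap is shorter than the refractory interval.
    Returns dicts with onset/offset sample indices, peak, iEMG
    (trapezoid, last sample held at stream end), reached_upper, truncated.
    """
    n = len(x)
    above = x >= lower
    runs: list[list[int]] = []
    i = 0
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            runs.append([i, j])
            i = j
        else:
            i += 1
    merged: list[list[int]] = []
    for r in runs:
        if merged and (r[0] - merged[-1][1]) < refractory_s * fs:
            merged[-1][1] = r[1]
        else:
            merged.append(list(r))
    dt = 1.0 / fs
    out = []
    for i0, i1 in merged:
        truncated = i1 == n
        hi = min(i1, n - 1)
        iemg = float(np.trapezoid(x[i0:hi + 1], dx=dt))
        if truncated:
            iemg += float(x[-1]) * dt
        peak = float(np.max(x[i0:i1]))
        out.append({
            "onset_i": i0,
            "offset_i": i1,
            "peak": peak,
            "iemg": iemg,
            "reached_upper": peak >= upper,
            "truncated": truncated,
        })
    return out


def two_pass_pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook product-moment correlation, two explicit passes."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)
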