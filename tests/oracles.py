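"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written as plain sample-by-sample scans,
structured differently from the library code it checks: exhaustive
threshold scans for event detection, full ECDF evaluation over every
breakpoint for the KS statistic, and manual sorted-array interpolation
for the quartile fences.
"""

from __future__ import annotations

import numpy as np


def scan_detect(
    v: np.ndarray,
    fs: float,
    t0: float,
    onset_frac: float,
    offset_frac: float,
    min_cycle_s: float,
    min_prominence: float,
) -> list[tuple[float, float, float, float]]:
    """Exhaustive sample-scan inhalation detection on a velocity series.

    Returns (onset_t, offset_t, peak_t, peak_v) tuples under the same
    contract as the fast detector: positive local maxima (first sample of
    a plateau), topographic prominence, tallest-first refractory
    suppression, last-below/first-below threshold crossings.
    """
    n = len(v)

    def prominence(i: int) -> float:
        lo = v[i]
        j = i - 1
        while j >= 0:
            if v[j] > v[i]:
                break
            if v[j] < lo:
                lo = v[j]
            j -= 1
        left = lo
        lo = v[i]
        j = i + 1
        while j < n:
            if v[j] > v[i]:
                break
            if v[j] < lo:
                lo = v[j]
            j += 1
        right = lo
        return v[i] - (left if left > right else right)

    peaks = []
    for i in range(1, n - 1):
        if v[i] > 0 and v[i - 1] < v[i] and v[i + 1] <= v[i]:
            if prominence(i) >= min_prominence:
                peaks.append(i)

    d = int(round(min_cycle_s * fs))
    remaining = sorted(peaks, key=lambda i: (-v[i], i))
    kept: list[int] = []
    for i in remaining:
        ok = True
        for j in kept:
            if abs(i - j) < d:
                ok = False
                break
        if ok:
            kept.append(i)
    kept.sort()

    events = []
    for k, p in enumerate(kept):
        prev = kept[k - 1] if k > 0 else -1
        nxt = kept[k + 1] if k + 1 < len(kept) else n
        onset = prev + 1
        j = p - 1
        while j > prev:
            if v[j] <= onset_frac * v[p]:
                onset = j
                break
            j -= 1
        offset = None
        j = p + 1
        while j < nxt:
            if v[j] <= offset_frac * v[p]:
                offset = j
                break
            j += 1
        if offset is None or onset >= p:
            continue
        events.append((t0 + onset / fs, t0 + offset / fs, t0 + p / fs, float(v[p])))
    return events


def sup_ecdf_distance(a: np.ndarray, b: np.ndarray) -> float:
    """KS statistic by evaluating both ECDFs at every breakpoint."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.count_nonzero(a <= x) / len(a)
        fb = np.count_nonzero(b <= x) / len(b)
        if abs(fa - fb) > best:
            best = abs(fa - fb)
    return best


def _quartile(sorted_x: np.ndarray, q: float) -> float:
    """Linear-interpolation quantile on an already sorted array."""
    pos = (len(sorted_x) - 1) * q
    lo = int(np.floor(pos))
    hi = min(lo + 1, len(sorted_x) - 1)
    frac = pos - lo
    return float(sorted_x[lo] + frac * (sorted_x[hi] - sorted_x[lo]))


def iqr_flags(values: np.ndarray, k: float = 1.5) -> np.ndarray:
    """Boolean outlier mask under the Tukey fence on one variable."""
    x = np.asarray(values, dtype=float)
    s = np.sort(x)
    q1 = _quartile(s, 0.25)
    q3 = _quartile(s, 0.75)
    iqr = q3 - q1
    return (x < q1 - k * iqr) | (x > q3 + k * iqr)
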