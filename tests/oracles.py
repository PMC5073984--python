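"""Independent brute-force oracles used to check the implementation.

Everything here is written with plain Python loops against the textbook
definitions (local maximum, peak prominence, sliding-window morphology,
truncated-window mean) and deliberately shares no code path with the
package, which uses scipy throughout.
"""

from __future__ import annotations

import numpy as np


def brute_local_maxima(values) -> list[int]:
    """Indices i with values[i-1] < values[i] > values[i+1] (strict)."""
    v = list(map(float, values))
    return [i for i in range(1, len(v) - 1) if v[i - 1] < v[i] > v[i + 1]]


def brute_prominence(values, i: int) -> float:
    """Textbook prominence: height above the higher of the two minima
    separating the peak from any strictly higher sample (or the edge)."""
    v = list(map(float, values))
    left_min = v[i]
    j = i - 1
    while j >= 0 and v[j] <= v[i]:
        left_min = min(left_min, v[j])
        j -= 1
    right_min = v[i]
    j = i + 1
    while j < len(v) and v[j] <= v[i]:
        right_min = min(right_min, v[j])
        j += 1
    return v[i] - max(left_min, right_min)


def brute_peak_calls(values, min_prominence: float,
                     min_distance: int) -> list[tuple[int, float]]:
    """Thresholded, distance-thinned peak calls: (index, prominence).

    Thinning repeatedly keeps the highest remaining peak (ties -> smaller
    index) and discards peaks closer than ``min_distance``.
    """
    v = list(map(float, values))
    peaks = [(i, brute_prominence(v, i)) for i in brute_local_maxima(v)]
    peaks = [(i, p) for i, p in peaks if p >= min_prominence]
    remaining = sorted(peaks, key=lambda t: (-v[t[0]], t[0]))
    kept: list[tuple[int, float]] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [t for t in remaining
                     if abs(t[0] - best[0]) >= min_distance]
    return sorted(kept)


def brute_opening_column(values, radius: int) -> list[float]:
    """1-D grey opening with a (2*radius+1) line, truncated at borders:
    erosion (windowed min) followed by dilation (windowed max)."""
    v = list(map(float, values))
    n = len(v)

    def windowed(seq, fn):
        out = []
        for i in range(n):
            lo, hi = max(0, i - radius), min(n, i + radius + 1)
            out.append(fn(seq[lo:hi]))
        return out

    return windowed(windowed(v, min), max)


def brute_background_subtract(pixels, radius: int) -> np.ndarray:
    """Per-column opening background removal by exhaustive scan."""
    px = np.asarray(pixels, dtype=float)
    out = np.empty_like(px)
    for c in range(px.shape[1]):
        bg = brute_opening_column(px[:, c], radius)
        out[:, c] = np.clip(px[:, c] - np.asarray(bg), 0.0, None)
    return out


def brute_truncated_mean(values, window: int) -> list[float]:
    """Centered moving average with truncated edge windows."""
    v = list(map(float, values))
    half = window // 2
    out = []
    for i in range(len(v)):
        lo, hi = max(0, i - half), min(len(v), i + half + 1)
        out.append(sum(v[lo:hi]) / (hi - lo))
    return out


def brute_gaussian_blur_1d(values, sigma: float, truncate: float = 4.0
                           ) -> list[float]:
    """Explicit discrete Gaussian convolution with edge replication,
    matching a normalized truncated kernel."""
    v = list(map(float, values))
    radius = int(truncate * sigma + 0.5)
    kernel = [np.exp(-(k * k) / (2.0 * sigma * sigma))
              for k in range(-radius, radius + 1)]
    s = sum(kernel)
    kernel = [k / s for k in kernel]
    n = len(v)
    out = []
    for i in range(n):
        acc = 0.0
        for k in range(-radius, radius + 1):
            j = min(max(i + k, 0), n - 1)  # nearest-edge replication
            acc += kernel[k + radius] * v[j]
        out.append(acc)
    return out
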