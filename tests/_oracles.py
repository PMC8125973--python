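"""Naive reference implementations used as independent oracles in tests.

Everything here is deliberately written with plain Python loops and
closed-form arithmetic, independent of the package's vectorized paths.
"""

import math


def _percentile(values, q):
    """Linear-interpolation percentile on a sorted copy (q in [0, 100])."""
    s = sorted(values)
    n = len(s)
    if n == 1:
        return s[0]
    h = (n - 1) * q / 100.0
    lo = math.floor(h)
    hi = math.ceil(h)
    return s[lo] + (h - lo) * (s[hi] - s[lo])


def naive_series_stats(x):
    """The 16 summary statistics, computed the slow way."""
    n = len(x)
    mean = sum(x) / n
    std = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    mn, mx = min(x), max(x)
    argmax = x.index(mx)
    argmin = x.index(mn)
    rel_argmax = argmax / (n - 1) if n > 1 else 0.0
    rel_argmin = argmin / (n - 1) if n > 1 else 0.0
    rms = math.sqrt(sum(v * v for v in x) / n)
    mad = sum(abs(v - mean) for v in x) / n
    if n > 1:
        area = sum((x[i] + x[i + 1]) / 2 for i in range(n - 1)) / (n - 1)
        tbar = (n - 1) / 2
        sxx = sum((t - tbar) ** 2 for t in range(n))
        slope = sum((t - tbar) * (x[t] - mean) for t in range(n)) / sxx
    else:
        area = x[0]
        slope = 0.0
    n_peaks = sum(
        1 for i in range(1, n - 1) if x[i] > x[i - 1] and x[i] > x[i + 1]
    )
    return [
        mean,
        _percentile(x, 50),
        std,
        mn,
        mx,
        mx - mn,
        _percentile(x, 75) - _percentile(x, 25),
        _percentile(x, 10),
        _percentile(x, 90),
        rel_argmax,
        rel_argmin,
        rms,
        mad,
        area,
        slope,
        float(n_peaks),
    ]


def naive_moving_average(x, window):
    """Centered moving average with edge replication, by direct summation."""
    half = window // 2
    n = len(x)
    out = []
    for i in range(n):
        acc = 0.0
        for j in range(i - half, i + half + 1):
            acc += x[min(max(j, 0), n - 1)]
        out.append(acc / window)
    return out
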