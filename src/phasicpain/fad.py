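"""Facial Activity Descriptor (FAD).

Summarizes each AU-intensity time series with a fixed set of statistics
computed on the (smoothed) series itself and on its first and second
finite-difference derivatives: 16 statistics x 3 levels = 48 values per
series, concatenated over the 17 canonical AUs into an 816-component
feature vector per sample.

The 16-statistic set is frozen (order below) and spans location, scale,
shape and timing of the response; relative-time statistics are expressed
as fractions of the series length so they are frame-rate invariant, while
derivatives are scaled by the frame rate so they read as intensity per
second.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import AU_NAMES, N_AUS
from .preprocess import smooth_series

__all__ = [
    "STAT_NAMES",
    "N_STATS",
    "DESCRIPTOR_LENGTH",
    "feature_names",
    "derivatives",
    "series_stats",
    "fad_descriptor",
    "sample_features",
    "feature_matrix",
    "write_feature_matrix",
    "read_feature_matrix",
]

#: Names of the 16 per-level statistics, in layout order.
STAT_NAMES: tuple[str, ...] = (
    "mean", "median", "std", "min", "max", "range", "iqr", "p10", "p90",
    "rel_argmax", "rel_argmin", "rms", "mad", "area", "slope", "n_peaks",
)

N_STATS = len(STAT_NAMES)
N_LEVELS = 3
DESCRIPTOR_LENGTH = N_STATS * N_LEVELS  # 48 per time series
FEATURE_LENGTH = N_AUS * DESCRIPTOR_LENGTH  # 816 per sample


def feature_names() -> list[str]:
    """Column names of the per-sample feature vector (AU-major layout)."""
    return [
        f"{au}_L{level}_{stat}"
        for au in AU_NAMES
        for level in range(N_LEVELS)
        for stat in STAT_NAMES
    ]


def derivatives(series: np.ndarray, fps: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """First and second forward-difference derivatives, scaled by ``fps``.

    A series of T samples yields derivatives of length T-1 and T-2; at
    least 3 samples are required.
    """
    series = np.asarray(series, dtype=float).ravel()
    if series.size < 3:
        raise ValueError(f"need at least 3 samples for derivatives, got {series.size}")
    d1 = np.diff(series) * fps
    d2 = np.diff(d1) * fps
    return d1, d2


def series_stats(series: np.ndarray) -> np.ndarray:
    """The 16 summary statistics of one series, in :data:`STAT_NAMES` order.

    Time-position statistics (relative argmax/argmin, slope) are 0 for a
    single-sample series; the normalized area of a single sample is the
    sample itself.
    """
    x = np.asarray(series, dtype=float).ravel()
    n = x.size
    if n == 0:
        raise ValueError("series must be non-empty")
    mean = x.mean()
    p25, p75 = np.percentile(x, [25, 75])
    if n > 1:
        rel_argmax = np.argmax(x) / (n - 1)
        rel_argmin = np.argmin(x) / (n - 1)
        area = np.trapezoid(x) / (n - 1)
        t = np.arange(n)
        slope = np.polyfit(t, x, 1)[0]
    else:
        rel_argmax = rel_argmin = slope = 0.0
        area = x[0]
    if n > 2:
        interior = x[1:-1]
        n_peaks = int(np.sum((interior > x[:-2]) & (interior > x[2:])))
    else:
        n_peaks = 0
    return np.array([
        mean,
        np.median(x),
        x.std(),
        x.min(),
        x.max(),
        x.max() - x.min(),
        p75 - p25,
        np.percentile(x, 10),
        np.percentile(x, 90),
        rel_argmax,
        rel_argmin,
        np.sqrt(np.mean(x**2)),
        np.mean(np.abs(x - mean)),
        area,
        slope,
        float(n_peaks),
    ])


def fad_descriptor(series: np.ndarray, fps: float = 1.0,
                   smoothing_window: int = 5) -> np.ndarray:
    """48-component descriptor of one AU time series.

    The series is smoothed once (centered moving average), statistics are
    computed on the smoothed series and on its first and second
    derivatives, and the three 16-blocks are concatenated.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 3:
        raise ValueError(f"need at least 3 samples, got {x.size}")
    xs = smooth_series(x, smoothing_window)
    d1, d2 = derivatives(xs, fps=fps)
    return np.concatenate([series_stats(xs), series_stats(d1), series_stats(d2)])


def sample_features(sample, smoothing_window: int = 5) -> np.ndarray:
    """816-component FAD vector of a sample: 17 AU descriptors concatenated
    in canonical AU order."""
    series = np.asarray(sample.series, dtype=float)
    if series.ndim != 2 or series.shape[0] != N_AUS:
        raise ValueError(f"expected ({N_AUS}, T) series, got {series.shape}")
    return np.concatenate([
        fad_descriptor(series[i], fps=sample.fps, smoothing_window=smoothing_window)
        for i in range(N_AUS)
    ])


def feature_matrix(samples, smoothing_window: int = 5) -> pd.DataFrame:
    """FAD features for an iterable of samples, indexed by ``sample_id``."""
    rows = {s.sample_id: sample_features(s, smoothing_window) for s in samples}
    return pd.DataFrame.from_dict(rows, orient="index", columns=feature_names())


def write_feature_matrix(features: pd.DataFrame, path) -> None:
    features.rename_axis("sample_id").to_csv(path)


def read_feature_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    expected = feature_names()
    if list(df.columns) != expected:
        raise ValueError(f"{path}: feature columns do not match the canonical layout")
    return df
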