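"""Network-input construction.

Builds the two inputs of the image pipeline:

* the spatio-temporal image — grayscale frames from seconds 1, 3 and 4 of a
  sample stacked as the R, G and B channels of one image, so that temporal
  change appears as colour;
* the constant-valued prediction image encoding a forest's predicted class
  index 0-6, fed to the second network branch;

plus the moving-average smoothing applied to AU time series before feature
extraction.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2gray
from skimage.transform import resize

__all__ = [
    "select_frames",
    "encode_spatiotemporal",
    "encode_prediction",
    "decode_prediction",
    "smooth_series",
    "spatiotemporal_from_sample",
    "KEY_SECONDS",
]

#: The seconds of a 7-s sample from which frames are taken.  Facial pain
#: activity starts roughly 2 s after the thermal plateau (reached at second
#: 1), so seconds 1, 3 and 4 bracket rest, onset and peak of the response.
KEY_SECONDS: tuple[int, ...] = (1, 3, 4)

ST_SIZE = 96
PREDICTION_IMAGE_SIZE = 28
N_PREDICTION_CLASSES = 7


def select_frames(frames: list[np.ndarray], fps: float,
                  seconds: tuple[int, ...] = KEY_SECONDS) -> list[np.ndarray]:
    """Pick one frame per requested second: the midpoint frame of that second.

    The midpoint rule ``floor((s + 0.5) * fps)`` is robust to off-by-one
    placement of second boundaries; the video must span every requested
    second in full.
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    need = (max(seconds) + 1) * fps
    if len(frames) < need:
        raise ValueError(
            f"video has {len(frames)} frames ({len(frames) / fps:.2f} s) but "
            f"seconds {tuple(seconds)} require at least {need:.0f} frames"
        )
    return [frames[int(np.floor((s + 0.5) * fps))] for s in seconds]


def _to_gray(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        if image.shape[2] == 1:
            image = image[:, :, 0]
        else:
            return rgb2gray(image)
    if image.max() > 1.0:
        image = image / 255.0
    return image


def encode_spatiotemporal(frames3: list[np.ndarray], size: int = ST_SIZE) -> np.ndarray:
    """Merge three frames into one spatio-temporal image.

    Each frame is converted to grayscale (luma weights), resized to
    ``size`` x ``size`` (bilinear) and stacked in temporal order: earliest
    frame as the red channel, middle as green, latest as blue.  Values are
    in [0, 1].  Already-grayscale, already-sized inputs pass through
    unchanged, so the encoding is idempotent.
    """
    if len(frames3) != 3:
        raise ValueError(f"expected exactly 3 frames, got {len(frames3)}")
    channels = []
    for frame in frames3:
        g = _to_gray(frame)
        if g.shape != (size, size):
            g = resize(g, (size, size), order=1, anti_aliasing=False)
        channels.append(np.clip(g, 0.0, 1.0))
    return np.stack(channels, axis=-1)


def encode_prediction(class_index: int,
                      size: int = PREDICTION_IMAGE_SIZE) -> np.ndarray:
    """Encode a predicted class index 0-6 as a constant single-channel image.

    The index is normalized to [0, 1] by the largest index, so the encoding
    is exactly invertible by :func:`decode_prediction`.
    """
    if not (isinstance(class_index, (int, np.integer))
            and 0 <= class_index <= N_PREDICTION_CLASSES - 1):
        raise ValueError(f"class index must be an integer in 0..6, got {class_index!r}")
    value = class_index / (N_PREDICTION_CLASSES - 1)
    return np.full((size, size, 1), value, dtype=float)


def decode_prediction(image: np.ndarray) -> int:
    """Recover the class index from a prediction image."""
    value = float(np.mean(image))
    return int(round(value * (N_PREDICTION_CLASSES - 1)))


def smooth_series(series: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average with edge replication.

    ``window`` must be odd; window 1 is the identity.  Works on a 1-D series
    or row-wise on a 2-D (channels, T) array.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 1:
        raise ValueError("series must be non-empty")
    if window == 1:
        return series.copy()
    half = window // 2
    padded = np.concatenate(
        [np.repeat(series[..., :1], half, axis=-1),
         series,
         np.repeat(series[..., -1:], half, axis=-1)],
        axis=-1,
    )
    csum = np.cumsum(padded, axis=-1)
    csum = np.concatenate([np.zeros_like(csum[..., :1]), csum], axis=-1)
    return (csum[..., window:] - csum[..., :-window]) / window


def spatiotemporal_from_sample(sample, size: int = ST_SIZE,
                               render_size: int | None = None,
                               seconds: tuple[int, ...] = KEY_SECONDS) -> np.ndarray:
    """Spatio-temporal image straight from a synthetic sample.

    Renders only the three key frames (midpoints of the requested seconds),
    then encodes them; ``render_size`` lets the schematic renderer work at a
    different resolution than the final image.
    """
    from .synthetic import render_frames

    need = (max(seconds) + 1) * sample.fps
    if sample.n_frames < need:
        raise ValueError("sample too short for the requested seconds")
    idx = [int(np.floor((s + 0.5) * sample.fps)) for s in seconds]
    frames = render_frames(sample, size=max(render_size or size, 32), indices=idx)
    return encode_spatiotemporal(frames, size=size)
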