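"""Raw EMG -> 4x8 activation frames.

The pipeline is band-pass filtering, a causal mean-absolute-value (MAV)
envelope, and row-major mapping of the 32 channels onto the electrode
grid.  Streaming mode is strictly causal; the zero-phase band-pass variant
exists only for offline training data.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal as sps

from .synthetic import GRID_SHAPE, N_CHANNELS, EmgStream

DEFAULT_LOW_HZ = 20.0
DEFAULT_HIGH_HZ = 450.0
DEFAULT_MAV_WINDOW = 15


def _as_array(x):
    if isinstance(x, EmgStream):
        return x.samples, x
    return np.asarray(x, dtype=float), None


def bandpass(
    stream,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    order: int = 4,
    zero_phase: bool = False,
    sample_rate: float = None,
):
    """Per-channel Butterworth band-pass (DC rejecting).

    Accepts an :class:`EmgStream` (returns a filtered copy) or a plain
    ``(T, C)``/``(T,)`` array.  ``zero_phase`` applies forward-backward
    filtering and is reserved for offline use.
    """
    x, src = _as_array(stream)
    fs = sample_rate or (src.sample_rate if src is not None else 1000.0)
    if not (0.0 < low_hz < high_hz < fs / 2.0):
        raise ValueError(
            f"band must satisfy 0 < low < high < fs/2; got ({low_hz}, {high_hz}) at fs={fs}"
        )
    sos = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt if zero_phase else sps.sosfilt
    y = filt(sos, x, axis=0)
    if src is not None:
        return dataclasses.replace(src, samples=y)
    return y


def mav_filter(stream, window: int = DEFAULT_MAV_WINDOW):
    """Causal sliding-window mean of the rectified signal.

    ``out[n] = mean(|x[n-window+1 .. n]|)``.  During warm-up (the first
    ``window - 1`` samples) the partial-window mean is used; see
    :func:`warmup_mask` to exclude those outputs from training labels.
    """
    x, src = _as_array(stream)
    if window < 1:
        raise ValueError("window must be >= 1")
    ax = np.abs(x)
    csum = np.cumsum(ax, axis=0)
    out = np.empty_like(ax, dtype=float)
    w = min(window, ax.shape[0])
    out[:w] = csum[:w] / np.arange(1, w + 1).reshape((-1,) + (1,) * (ax.ndim - 1))
    if ax.shape[0] > window:
        out[window:] = (csum[window:] - csum[:-window]) / window
    if src is not None:
        return dataclasses.replace(src, samples=out)
    return out


def warmup_mask(n_samples: int, window: int = DEFAULT_MAV_WINDOW) -> np.ndarray:
    """Boolean mask, True where the MAV window is only partially filled."""
    mask = np.zeros(n_samples, dtype=bool)
    mask[: window - 1] = True
    return mask


def to_frame(sample_vector) -> np.ndarray:
    """Map a 32-channel sample onto the 4x8 grid (row-major).

    Channel ``k`` lands at ``(row, col) = (k // 8, k % 8)``.  The placement
    is bijective: :func:`frame_to_vector` inverts it exactly.
    """
    v = np.asarray(sample_vector, dtype=float).ravel()
    if v.size != N_CHANNELS:
        raise ValueError(f"expected exactly {N_CHANNELS} channel values, got {v.size}")
    return v.reshape(GRID_SHAPE)


def frame_to_vector(frame) -> np.ndarray:
    """Inverse of :func:`to_frame`."""
    f = np.asarray(frame, dtype=float)
    if f.shape != GRID_SHAPE:
        raise ValueError(f"expected a {GRID_SHAPE} frame, got {f.shape}")
    return f.reshape(N_CHANNELS)


def frames_from_samples(samples) -> np.ndarray:
    """(T, 32) -> (T, 4, 8) row-major grid mapping of every sample."""
    x = np.asarray(samples, dtype=float)
    if x.ndim != 2 or x.shape[1] != N_CHANNELS:
        raise ValueError(f"expected (T, {N_CHANNELS}) samples, got {x.shape}")
    return x.reshape(-1, *GRID_SHAPE)


def stream_to_frames(
    stream,
    low_hz: float = DEFAULT_LOW_HZ,
    high_hz: float = DEFAULT_HIGH_HZ,
    window: int = DEFAULT_MAV_WINDOW,
    zero_phase: bool = False,
) -> np.ndarray:
    """Full front-end: band-pass, MAV, grid mapping.  Returns (T, 4, 8)."""
    y = bandpass(stream, low_hz, high_hz, zero_phase=zero_phase)
    y = mav_filter(y, window=window)
    x = y.samples if isinstance(y, EmgStream) else y
    return frames_from_samples(x)
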