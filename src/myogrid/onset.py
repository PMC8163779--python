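"""Motion-onset detection via the Teager-Kaiser Energy operator.

The discrete TKE operator psi[n] = x[n]^2 - x[n-1] * x[n+1] tracks the
instantaneous energy of the signal; a voluntary contraction makes the
channel-mean TKE jump far above its stationary noise floor.  The detection
threshold is calibrated as mean + k * SD (k = 2.5) of the channel-mean TKE
over a pre-onset baseline window.  A short moving-mean smoothing and a
debounce (the energy must stay above threshold for a minimum duration)
suppress isolated spikes; both are light compared with the contraction
time scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import mav_filter
from .synthetic import NEUTRAL_LABEL, EmgStream


@dataclass(frozen=True)
class OnsetConfig:
    """Calibration and detection settings (times in ms at 1 kHz)."""

    noise_window_ms: float = 500.0
    k: float = 2.5
    smooth_window: int = 15
    debounce_ms: float = 10.0

    def __post_init__(self) -> None:
        if self.noise_window_ms <= 0 or self.k <= 0:
            raise ValueError("noise_window_ms and k must be > 0")
        if self.smooth_window < 1 or self.debounce_ms < 1:
            raise ValueError("smooth_window and debounce_ms must be >= 1")


def _samples(x) -> np.ndarray:
    if isinstance(x, EmgStream):
        return x.samples
    return np.asarray(x, dtype=float)


def tke(signal) -> np.ndarray:
    """Discrete Teager-Kaiser Energy, per channel.

    psi[n] = x[n]^2 - x[n-1] * x[n+1] for interior samples; the two
    boundary samples are set to 0.  Requires at least 3 samples.
    """
    x = _samples(signal)
    if x.shape[0] < 3:
        raise ValueError("TKE requires at least 3 samples")
    psi = np.zeros_like(x, dtype=float)
    psi[1:-1] = x[1:-1] ** 2 - x[:-2] * x[2:]
    return psi


def mean_tke(signal, smooth_window: int = 15) -> np.ndarray:
    """Channel-averaged TKE with causal moving-mean smoothing."""
    psi = tke(signal)
    series = psi.mean(axis=1) if psi.ndim == 2 else psi
    if smooth_window > 1:
        series = mav_filter(series, window=smooth_window)
    return series


def calibrate_threshold(signal, config: OnsetConfig = OnsetConfig()) -> float:
    """Threshold = mean + k * SD of the baseline channel-mean TKE.

    The baseline is the first ``noise_window_ms`` of the stream.  The
    statistics are taken on the *unsmoothed* channel-mean TKE — its SD is
    substantially larger than that of the smoothed series that
    :func:`detect_onset` monitors, so under stationary noise the smoothed
    energy practically never reaches the threshold, while a voluntary
    contraction exceeds it within a few samples.  When an annotated
    :class:`EmgStream` is given, the calibration refuses a baseline window
    overlapping any scripted contraction.
    """
    if isinstance(signal, EmgStream):
        fs = signal.sample_rate
        for seg in signal.segments:
            if seg.label != NEUTRAL_LABEL and seg.start_ms < config.noise_window_ms:
                raise ValueError(
                    "baseline window overlaps a scripted contraction "
                    f"(label {seg.label} starts at {seg.start_ms} ms)"
                )
    else:
        fs = 1000.0
    n = int(round(config.noise_window_ms * fs / 1000.0))
    series = mean_tke(signal, smooth_window=1)[:n]
    return float(series.mean() + config.k * series.std())


def detect_onset(signal, threshold: float, config: OnsetConfig = OnsetConfig()):
    """First instant (ms) the smoothed channel-mean TKE exceeds threshold
    and stays above it for the debounce window; ``None`` if never."""
    fs = signal.sample_rate if isinstance(signal, EmgStream) else 1000.0
    series = mean_tke(signal, smooth_window=config.smooth_window)
    above = series > threshold
    debounce = max(1, int(round(config.debounce_ms * fs / 1000.0)))
    if debounce > 1:
        # sustained-run detection via a moving sum of the boolean series
        runsum = np.convolve(above.astype(int), np.ones(debounce, dtype=int), "valid")
        starts = np.flatnonzero(runsum == debounce)
    else:
        starts = np.flatnonzero(above)
    if starts.size == 0:
        return None
    return float(starts[0]) * 1000.0 / fs
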