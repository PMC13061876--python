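"""Instantaneous-frequency extraction.

For each channel the band-limited signal x_i(t) is taken to its analytic
form a_i(t) = x_i(t) + i H[x_i](t) via the Hilbert transform.  The wrapped
phase phi_i(t) = arg a_i(t) is unwrapped (adding 2*pi*k(t) to remove branch
cuts) and differentiated,

    IF_i(t) = (1 / 2*pi) d/dt unwrap[phi_i(t)]   [Hz],

using central differences at interior samples and one-sided differences at
the ends.  Noise-driven phase slips produce brief spurious IF spikes; the
only mitigation applied is a running median filter (100 ms by default),
length-preserving with truncated windows at the edges.  Out-of-band or
negative IF values that survive the median are retained, not clipped.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .io import EEGRecording

__all__ = [
    "IFSeries",
    "InstantaneousFrequency",
    "analytic",
    "wrapped_phase",
    "unwrap_phase",
    "phase_to_frequency",
    "median_smooth",
    "median_window_samples",
    "extract_if",
]


@dataclasses.dataclass
class IFSeries:
    """Per-channel instantaneous-frequency time series (Hz)."""

    if_hz: np.ndarray  # channels x samples
    fs_hz: float
    channel_labels: tuple[str, ...]
    participant_id: str = ""
    group: str = ""

    @property
    def n_channels(self) -> int:
        return self.if_hz.shape[0]

    @property
    def n_samples(self) -> int:
        return self.if_hz.shape[1]


def analytic(x: np.ndarray) -> np.ndarray:
    """Analytic signal along the last axis (real part == input)."""
    x = np.asarray(x, dtype=float)
    return signal.hilbert(x, axis=-1)


def wrapped_phase(a: np.ndarray) -> np.ndarray:
    """Elementwise argument of the analytic signal, in [-pi, pi].

    Raises if any channel is identically zero (phase undefined there).
    """
    a = np.asarray(a)
    flat = np.atleast_2d(a)
    dead = np.flatnonzero(~np.any(flat != 0, axis=-1))
    if dead.size:
        raise ValueError(f"all-zero channel(s) at index {dead.tolist()}: "
                         "phase is undefined")
    return np.angle(a)


def unwrap_phase(phi: np.ndarray) -> np.ndarray:
    """Remove 2-pi branch cuts along the last axis (numpy unwrap)."""
    return np.unwrap(np.asarray(phi, dtype=float), axis=-1)


def phase_to_frequency(phi_unwrapped: np.ndarray, fs_hz: float) -> np.ndarray:
    """Differentiate unwrapped phase to raw IF in Hz.

    Central differences at interior samples, one-sided at both ends
    (``np.gradient``).  Needs at least 3 samples.
    """
    phi = np.asarray(phi_unwrapped, dtype=float)
    if phi.shape[-1] < 3:
        raise ValueError("need at least 3 samples to differentiate phase")
    return np.gradient(phi, axis=-1) * fs_hz / (2.0 * np.pi)


def median_window_samples(window_ms: float, fs_hz: float) -> int:
    """Median window length in samples: round(ms*fs/1000), forced odd (up)."""
    w = int(round(window_ms * fs_hz / 1000.0))
    w = max(w, 1)
    if w % 2 == 0:
        w += 1
    return w


def median_smooth(if_raw: np.ndarray, fs_hz: float,
                  window_ms: float = 100.0) -> np.ndarray:
    """Centered running median along the last axis, length preserving.

    At the edges the median is taken over the samples that fall inside the
    signal (truncated window), so no padding value is invented.
    """
    w = median_window_samples(window_ms, fs_hz)
    if w == 1:
        return np.asarray(if_raw, dtype=float).copy()
    x = np.atleast_2d(np.asarray(if_raw, dtype=float))
    out = (
        pd.DataFrame(x.T)
        .rolling(w, center=True, min_periods=1)
        .median()
        .to_numpy()
        .T
    )
    return out.reshape(np.shape(if_raw))


class InstantaneousFrequency(BaseEstimator, TransformerMixin):
    """Hilbert-transform IF extractor (samples x channels in and out).

    Parameters
    ----------
    fs_hz : float
        Sampling rate of the (already band-limited) input.
    median_ms : float, default 100
        Running-median smoothing window; set to 0 to disable.
    """

    def __init__(self, fs_hz: float = 200.0, median_ms: float = 100.0):
        self.fs_hz = fs_hz
        self.median_ms = median_ms

    def fit(self, X=None, y=None):
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float).T  # -> channels x samples
        a = analytic(X)
        phi = unwrap_phase(wrapped_phase(a))
        raw = phase_to_frequency(phi, self.fs_hz)
        if self.median_ms > 0:
            raw = median_smooth(raw, self.fs_hz, self.median_ms)
        return raw.T


def extract_if(rec: EEGRecording, median_ms: float = 100.0) -> IFSeries:
    """Smoothed per-channel instantaneous frequency of a recording."""
    est = InstantaneousFrequency(fs_hz=rec.fs_hz, median_ms=median_ms)
    return IFSeries(
        if_hz=est.transform(rec.data.T).T,
        fs_hz=rec.fs_hz,
        channel_labels=rec.channel_labels,
        participant_id=rec.participant_id,
        group=rec.group,
    )
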