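"""Band-pass filtering and edge trimming.

Resting-state segments are band-limited to the theta-alpha range
(4-13 Hz by default; 8-13 Hz for an alpha-only variant) with a zero-phase
Butterworth filter, and the filter-transient edges are cut off before any
phase-based quantity is computed.  Zero-phase filtering matters here: a
causal filter's group delay would bias the instantaneous phase and hence
every downstream frequency estimate.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .io import EEGRecording

__all__ = ["BandSpec", "BandpassFilter", "bandpass", "trim_edges"]


@dataclasses.dataclass(frozen=True)
class BandSpec:
    """Analysis band edges in Hz (0 < low < high < Nyquist)."""

    low_hz: float = 4.0
    high_hz: float = 13.0

    def validate(self, fs_hz: float) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(f"invalid band {self.low_hz}-{self.high_hz} Hz")
        if self.high_hz >= fs_hz / 2:
            raise ValueError(
                f"band edge {self.high_hz} Hz is at or above Nyquist "
                f"({fs_hz / 2} Hz)"
            )


class BandpassFilter(BaseEstimator, TransformerMixin):
    """Zero-phase Butterworth band-pass transformer.

    Operates on samples x channels arrays (scikit-learn orientation).  The
    filter is applied forward and backward (``sosfiltfilt``), so the
    effective magnitude order is twice ``order`` and the phase response is
    identically zero.

    Parameters
    ----------
    low_hz, high_hz : float
        Band edges in Hz.
    fs_hz : float
        Sampling rate of the input.
    order : int, default 4
        Butterworth design order of the one-pass filter.
    """

    def __init__(self, low_hz: float = 4.0, high_hz: float = 13.0,
                 fs_hz: float = 200.0, order: int = 4):
        self.low_hz = low_hz
        self.high_hz = high_hz
        self.fs_hz = fs_hz
        self.order = order

    def fit(self, X=None, y=None):
        BandSpec(self.low_hz, self.high_hz).validate(self.fs_hz)
        self.sos_ = signal.butter(
            self.order, [self.low_hz, self.high_hz],
            btype="bandpass", fs=self.fs_hz, output="sos",
        )
        return self

    def transform(self, X):
        if not hasattr(self, "sos_"):
            self.fit()
        X = np.asarray(X, dtype=float)
        return signal.sosfiltfilt(self.sos_, X, axis=0)


def bandpass(rec: EEGRecording, band: BandSpec | None = None,
             order: int = 4) -> EEGRecording:
    """Zero-phase band-pass filter a recording (default 4-13 Hz)."""
    band = band or BandSpec()
    filt = BandpassFilter(band.low_hz, band.high_hz, rec.fs_hz, order).fit()
    return rec.replace(data=filt.transform(rec.data.T).T)


def trim_edges(rec: EEGRecording, trim_s: float) -> EEGRecording:
    """Drop ``trim_s`` seconds from each end of the recording.

    The interior samples are returned unchanged; duration shrinks by
    exactly ``2 * trim_s``.
    """
    if trim_s < 0:
        raise ValueError("trim_s must be non-negative")
    n_trim = int(round(trim_s * rec.fs_hz))
    if 2 * n_trim >= rec.n_samples:
        raise ValueError(
            f"cannot trim {trim_s} s from each end of a "
            f"{rec.duration_s:.3f} s recording"
        )
    if n_trim == 0:
        return rec.replace(data=rec.data.copy())
    return rec.replace(data=rec.data[:, n_trim:-n_trim].copy())
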