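"""Recording container and file I/O.

EEG recordings move through the pipeline as :class:`EEGRecording` objects:
a channels x samples float matrix plus sampling rate, ordered 10-20 channel
labels, a participant id and a group label.

Supported on-disk formats:

* CSV — one header row of channel labels, one row per sample (long axis =
  time), comma-separated.  This is the round-trip format the synthetic
  cohort writer uses.
* EDF — read-only, via :mod:`mne` (imported lazily so the dependency stays
  optional).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_CHANNELS",
    "EEGRecording",
    "read_recording",
    "write_recording_csv",
]

#: The 16-electrode international 10-20 montage used throughout.
DEFAULT_CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "Fz", "F4", "F7", "F8", "C3",
    "C4", "P3", "Pz", "P4", "T5", "T6", "O1", "O2",
)


@dataclasses.dataclass
class EEGRecording:
    """One participant's multichannel EEG segment.

    Parameters
    ----------
    data
        Channels x samples matrix (microvolts or arbitrary units).
    fs_hz
        Sampling rate in Hz.
    channel_labels
        Ordered, unique channel names (10-20 convention).
    participant_id
        Free-form identifier.
    group
        Group label (e.g. ``"younger"`` / ``"middle_aged"``); may be empty.
    """

    data: np.ndarray
    fs_hz: float
    channel_labels: tuple[str, ...]
    participant_id: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        self.channel_labels = tuple(str(c) for c in self.channel_labels)
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if len(self.channel_labels) < 2:
            raise ValueError("a recording needs at least 2 channels")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not self.fs_hz > 0:
            raise ValueError("fs_hz must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def replace(self, **kwargs) -> "EEGRecording":
        """Return a copy with some fields replaced."""
        return dataclasses.replace(self, **kwargs)


def write_recording_csv(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as CSV: header of channel labels, rows = samples."""
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
    df.to_csv(path, index=False)


def _read_csv(path: Path, fs_hz: float | None) -> EEGRecording:
    if fs_hz is None:
        raise ValueError("fs_hz is required when reading CSV (no header field)")
    with open(path) as fh:
        labels = tuple(name.strip() for name in fh.readline().split(","))
    if len(set(labels)) != len(labels):
        raise ValueError(f"{path}: duplicate channel labels in CSV header")
    df = pd.read_csv(path, header=0, names=labels)
    return EEGRecording(
        data=df.to_numpy(dtype=float).T,
        fs_hz=fs_hz,
        channel_labels=labels,
        participant_id=path.stem,
    )


def _read_edf(path: Path) -> EEGRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "reading EDF requires the optional dependency 'mne' "
            "(pip install ifmicrostate[edf])"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data(),
        fs_hz=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
        participant_id=path.stem,
    )


def read_recording(
    path: str | Path,
    format: str | None = None,
    fs_hz: float | None = None,
) -> EEGRecording:
    """Read a recording from disk.

    Parameters
    ----------
    path
        File to read.
    format
        ``"edf"`` or ``"csv"``; inferred from the suffix when ``None``.
    fs_hz
        Sampling rate — required for CSV (the dialect carries no rate);
        ignored for EDF (taken from the header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "csv":
        return _read_csv(path, fs_hz)
    if fmt == "edf":
        return _read_edf(path)
    raise ValueError(f"unsupported recording format: {fmt!r}")
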