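"""Core container for multichannel EEG data.

An :class:`EEGRecording` is a channels x samples matrix of amplitudes (µV)
together with the sampling rate, 10-20-system channel labels and a start
timestamp in seconds.  All pipeline stages consume and return this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EEGRecording"]


@dataclass
class EEGRecording:
    """Multichannel EEG signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Amplitudes in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        Unique channel names (10-20 system, e.g. ``"Fz"``, ``"Cz"``).
    start_time : float
        Recording start, seconds since an arbitrary origin.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy_with(self, data: np.ndarray, channel_labels: list[str] | None = None) -> "EEGRecording":
        """Return a new recording sharing fs/start_time with replaced data."""
        return EEGRecording(
            data=data,
            fs=self.fs,
            channel_labels=list(channel_labels if channel_labels is not None else self.channel_labels),
            start_time=self.start_time,
        )
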