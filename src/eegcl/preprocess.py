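"""Pipeline front end: band-pass filtering, channel selection, segmentation.

The recording is band-pass filtered 0.5-45 Hz with a third-order Butterworth
filter (no artifact rejection), then cut into 3-s windows sliding 1 s at a
time.  Filtering is zero-phase by default (forward-backward application) so
that feature timestamps stay aligned with the behavioural scoring; a causal
single-pass mode is available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import EEGRecording

__all__ = ["SegmentSeries", "bandpass_filter", "select_channels", "segment"]


@dataclass
class SegmentSeries:
    """Ordered fixed-length analysis windows over a recording.

    ``windows`` holds half-open 0-based sample ranges ``[start, end)``;
    ``start_times`` are the corresponding absolute offsets in seconds.
    """

    windows: np.ndarray          # (n_windows, 2) int sample indices
    start_times: np.ndarray      # (n_windows,) seconds
    window_s: float
    hop_s: float
    fs: float

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def bandpass_filter(
    rec: EEGRecording,
    low: float = 0.5,
    high: float = 45.0,
    order: int = 3,
    zero_phase: bool = True,
) -> EEGRecording:
    """Butterworth band-pass filter applied per channel.

    Parameters
    ----------
    low, high : float
        Pass-band edges in Hz.  ``high`` must be below Nyquist.
    order : int
        Filter order (3 by default).
    zero_phase : bool
        If True (default) the filter is applied forward and backward
        (``sosfiltfilt``), doubling the effective order but cancelling the
        phase delay.  If False a causal single pass is used.
    """
    nyq = rec.fs / 2.0
    if not 0 < low < high:
        raise ValueError(f"require 0 < low < high, got low={low}, high={high}")
    if high >= nyq:
        raise ValueError(f"high cut-off {high} Hz must be below Nyquist {nyq} Hz")
    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    # sosfiltfilt needs enough samples for its edge padding
    min_len = 3 * (2 * sos.shape[0] + 1)
    if rec.n_samples <= min_len:
        raise ValueError(
            f"signal too short to filter: {rec.n_samples} samples, need > {min_len}"
        )
    if zero_phase:
        out = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        out = signal.sosfilt(sos, rec.data, axis=1)
    return rec.copy_with(out)


def select_channels(rec: EEGRecording, wanted: list[str]) -> EEGRecording:
    """Restrict a recording to ``wanted`` channels, in ``wanted``'s order.

    The study analysed only the montage channels common to all recording
    sites; this is the generic restriction operation behind that step.
    """
    missing = [w for w in wanted if w not in rec.channel_labels]
    if missing:
        raise KeyError(f"channels not in recording: {missing}")
    idx = [rec.channel_labels.index(w) for w in wanted]
    return rec.copy_with(rec.data[idx], channel_labels=list(wanted))


def segment(rec: EEGRecording, window_s: float = 3.0, hop_s: float = 1.0) -> SegmentSeries:
    """Cut a recording into sliding windows (3 s long, 1 s hop by default).

    Trailing samples that do not fill a whole window are dropped: every
    feature downstream is defined on fixed-length segments.
    """
    if window_s <= 0 or hop_s <= 0:
        raise ValueError("window_s and hop_s must be positive")
    win = int(round(window_s * rec.fs))
    hop = int(round(hop_s * rec.fs))
    if rec.n_samples < win:
        raise ValueError(
            f"recording of {rec.n_samples} samples shorter than one "
            f"{window_s}-s window ({win} samples)"
        )
    n_windows = (rec.n_samples - win) // hop + 1
    starts = np.arange(n_windows) * hop
    windows = np.stack([starts, starts + win], axis=1)
    start_times = rec.start_time + starts / rec.fs
    return SegmentSeries(
        windows=windows,
        start_times=start_times,
        window_s=window_s,
        hop_s=hop_s,
        fs=rec.fs,
    )
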