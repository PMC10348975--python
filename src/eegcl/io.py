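"""File input/output: recordings (CSV, EDF), label tracks and trace tables.

The plain-text CSV dialect stores samples as rows and channels as columns,
with the channel labels as header — small, diff-able and sufficient for the
synthetic data.  Clinical EDF files are read through MNE when it is
installed (``pip install eegcl[edf]``).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .estimate import ConsciousnessTrace
from .recording import EEGRecording

__all__ = [
    "write_recording_csv",
    "read_recording_csv",
    "read_edf",
    "write_labels_csv",
    "read_labels_csv",
    "write_trace_csv",
    "read_trace_csv",
]


def write_recording_csv(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording as CSV: rows = samples, columns = channels."""
    df = pd.DataFrame(rec.data.T, columns=rec.channel_labels)
    df.to_csv(path, index=False)


def read_recording_csv(
    path: str | Path, fs: float, start_time: float = 0.0
) -> EEGRecording:
    """Read the CSV dialect written by :func:`write_recording_csv`.

    The sampling rate is not stored in the file and must be supplied.
    """
    df = pd.read_csv(path)
    return EEGRecording(
        data=df.to_numpy(float).T,
        fs=fs,
        channel_labels=[str(c) for c in df.columns],
        start_time=start_time,
    )


def read_edf(path: str | Path) -> EEGRecording:
    """Read an EDF recording (requires the optional ``mne`` dependency)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - depends on extras
        raise ImportError(
            "reading EDF requires MNE; install with `pip install eegcl[edf]`"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return EEGRecording(
        data=raw.get_data() * 1e6,  # MNE loads volts; recordings carry µV
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        start_time=0.0,
    )


def write_labels_csv(labels: np.ndarray, fs: float, path: str | Path) -> None:
    """Write per-sample true-state labels (1 = conscious) with timestamps."""
    df = pd.DataFrame({
        "time_s": np.arange(labels.size) / fs,
        "state": labels.astype(int),
    })
    df.to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(float), df["state"].to_numpy(int)


def write_trace_csv(
    path: str | Path,
    ensemble: ConsciousnessTrace,
    p_fcm: ConsciousnessTrace | None = None,
    p_gmm: ConsciousnessTrace | None = None,
) -> None:
    """Write the consciousness trace(s) as CSV (timestamp_s, p_fcm, p_gmm, p_avg)."""
    cols = {"timestamp_s": ensemble.timestamps}
    if p_fcm is not None:
        cols["p_fcm"] = p_fcm.p_conscious
    if p_gmm is not None:
        cols["p_gmm"] = p_gmm.p_conscious
    cols["p_avg"] = ensemble.p_conscious
    pd.DataFrame(cols).to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> ConsciousnessTrace:
    df = pd.read_csv(path)
    return ConsciousnessTrace(
        p_conscious=df["p_avg"].to_numpy(float),
        timestamps=df["timestamp_s"].to_numpy(float),
    )
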