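"""Per-window feature extraction and the FeatureMatrix container.

Seven features are computed per 3-s window: θ and β relative power, SEF95,
Poincaré ERR and Lempel-Ziv complexity (each computed per channel, then
averaged across channels), plus θ-band imaginary coherency and wSMI (each
computed per unordered channel pair, then averaged across pairs).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import complexity, connectivity, spectral
from .preprocess import SegmentSeries
from .recording import EEGRecording

__all__ = ["FEATURE_NAMES", "FeatureMatrix", "extract_features"]

FEATURE_NAMES = (
    "theta_rp",
    "beta_rp",
    "sef95",
    "err",
    "lzc",
    "icoh_theta",
    "wsmi_theta",
)


@dataclass
class FeatureMatrix:
    """N_samples x N_features table with per-window timestamps.

    Rows with any non-finite value are tracked via :meth:`finite_mask` and
    excluded from clustering downstream.
    """

    values: np.ndarray                   # (n_windows, n_features)
    timestamps: np.ndarray               # window start, seconds
    feature_names: tuple[str, ...] = field(default=FEATURE_NAMES)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.values.shape[0] != self.timestamps.size:
            raise ValueError("one timestamp per feature row required")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError(
                f"{self.values.shape[1]} columns for {len(self.feature_names)} names"
            )

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def finite_mask(self) -> np.ndarray:
        """True for rows where every feature is finite."""
        return np.isfinite(self.values).all(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.feature_names))
        df.insert(0, "segment_start_s", self.timestamps)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        names = tuple(c for c in df.columns if c != "segment_start_s")
        return cls(
            values=df[list(names)].to_numpy(float),
            timestamps=df["segment_start_s"].to_numpy(float),
            feature_names=names,
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        return cls.from_frame(pd.read_csv(path))


def _icoh_all_pairs(seg, fs, freqs, psd, pairs):
    """θ-band |Im coherency| for all pairs in one broadcast csd call.

    Matches :func:`eegcl.connectivity.icoh_pair` (same Welch scheme; the
    auto-spectra are reused from the already-computed per-channel PSD).
    """
    from scipy import signal as _sig

    n = seg.shape[1]
    nperseg = n // 8
    ii = np.array([p[0] for p in pairs])
    jj = np.array([p[1] for p in pairs])
    _, sxy = _sig.csd(
        seg[ii], seg[jj], fs=fs, window="hamming",
        nperseg=nperseg, noverlap=nperseg // 2, detrend=False, axis=-1,
    )
    band = spectral.THETA
    mask = (freqs >= band.f1) & (freqs <= band.f2)
    denom = np.sqrt(psd[ii][:, mask] * psd[jj][:, mask])
    out = np.full(len(pairs), np.nan)
    ok = ~np.any(denom == 0, axis=1)
    if mask.any():
        out[ok] = np.mean(
            np.abs(np.imag(sxy[np.ix_(ok, mask)] / denom[ok])), axis=1
        )
    return out


def extract_features(
    rec: EEGRecording,
    segments: SegmentSeries,
    lzc_scheme: str = "lz76",
) -> FeatureMatrix:
    """Compute the seven-feature vector for every window of ``segments``.

    Per-channel features are averaged across channels; pair features across
    all unordered channel pairs.  Degenerate windows (zero power, constant
    signal) yield NaN in the affected feature.
    """
    tau = connectivity.tau_samples_for(rec.fs)
    pairs = list(itertools.combinations(range(rec.n_channels), 2))
    rows = np.empty((len(segments), len(FEATURE_NAMES)))

    for w, (start, end) in enumerate(segments.windows):
        seg = rec.data[:, start:end]

        freqs, psd = spectral.welch_psd(seg, rec.fs)
        theta_rp = np.array(
            [spectral.relative_power(freqs, p, spectral.THETA) for p in psd]
        )
        beta_rp = np.array(
            [spectral.relative_power(freqs, p, spectral.BETA) for p in psd]
        )
        sef95 = np.array([spectral.sef(freqs, p, r=0.95) for p in psd])

        err = np.array([complexity.poincare_err(ch) for ch in seg])
        lz = np.array(
            [complexity.lzc(complexity.hilbert_binarize(ch), scheme=lzc_scheme)
             for ch in seg]
        )

        if pairs:
            symbols = [connectivity.symbolize(ch, k=3, tau_samples=tau) for ch in seg]
            icoh = _icoh_all_pairs(seg, rec.fs, freqs, psd, pairs)
            wsmi = [
                connectivity.wsmi_pair(symbols[i], symbols[j]) for i, j in pairs
            ]
            icoh_mean = connectivity.aggregate_pairs(icoh)
            wsmi_mean = connectivity.aggregate_pairs(wsmi)
        else:
            icoh_mean = wsmi_mean = float("nan")

        rows[w] = (
            np.mean(theta_rp),
            np.mean(beta_rp),
            np.mean(sef95),
            np.mean(err),
            np.mean(lz),
            icoh_mean,
            wsmi_mean,
        )

    return FeatureMatrix(values=rows, timestamps=segments.start_times.copy())
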