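"""Spectral features: Welch PSD, relative band power and spectral edge frequency.

Relative power of a band [f1, f2] is the ratio of the PSD sum over the band
to the PSD sum over 0-45 Hz (the upper limit of the acquisition filter).
The spectral edge frequency SEF_r is the smallest frequency below which a
fraction r of the total (0 to fs/2) power lies; it is reported normalised by
45 Hz.  The PSD is a Welch estimate with Hamming sub-windows of 1/8 the
segment length and 50% overlap.

All quantities use discrete grid sums, matching the defining equations; a
frequency bin belongs to a band when its centre lies in [f1, f2] inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "BandDefinition",
    "THETA",
    "BETA",
    "welch_psd",
    "relative_power",
    "sef",
]

SEF_NORM_HZ = 45.0  # upper cut-off of the acquisition band-pass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [f1, f2] in Hz."""

    name: str
    f1: float
    f2: float

    def __post_init__(self) -> None:
        if not 0 <= self.f1 < self.f2:
            raise ValueError(f"invalid band limits [{self.f1}, {self.f2}]")


THETA = BandDefinition("theta", 4.0, 8.0)
BETA = BandDefinition("beta", 12.0, 30.0)


def welch_psd(x: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD with Hamming sub-windows of 1/8 segment length, 50% overlap.

    Parameters
    ----------
    x : ndarray
        Signal(s); the estimate is taken along the last axis, so a
        (n_channels, n_samples) array yields one PSD per channel.
    fs : float
        Sampling rate in Hz.

    Returns
    -------
    freqs : ndarray
        One-sided frequency grid, 0 to fs/2.
    power : ndarray
        Power spectral density, same leading shape as ``x``; >= 0.
    """
    n = np.shape(x)[-1]
    if n < 8:
        raise ValueError(f"segment of {n} samples too short for Welch (need >= 8)")
    nperseg = n // 8
    freqs, power = signal.welch(
        x,
        fs=fs,
        window="hamming",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        axis=-1,
    )
    return freqs, power


def relative_power(
    freqs: np.ndarray,
    power: np.ndarray,
    band: BandDefinition,
    f_l: float = 0.0,
    f_h: float = 45.0,
) -> float:
    """Band power as a fraction of total power over [f_l, f_h].

    Returns NaN when the total power over the denominator range is zero
    (degenerate flat segment); callers flag such windows.
    """
    if not (f_l <= band.f1 and band.f2 <= f_h):
        raise ValueError(f"band {band} outside denominator range [{f_l}, {f_h}]")
    freqs = np.asarray(freqs)
    power = np.asarray(power, dtype=float)
    total_mask = (freqs >= f_l) & (freqs <= f_h)
    band_mask = (freqs >= band.f1) & (freqs <= band.f2)
    total = power[total_mask].sum()
    if total <= 0:
        return float("nan")
    return float(power[band_mask].sum() / total)


def sef(freqs: np.ndarray, power: np.ndarray, r: float = 0.95,
        norm_hz: float = SEF_NORM_HZ) -> float:
    """Normalised spectral edge frequency.

    The smallest grid frequency whose cumulative power reaches ``r`` times
    the total power (summed over the whole 0 to fs/2 grid), divided by
    ``norm_hz``.  First-bin-crossing convention, no interpolation.
    """
    if not 0 < r < 1:
        raise ValueError(f"r must be in (0, 1), got {r}")
    freqs = np.asarray(freqs)
    power = np.asarray(power, dtype=float)
    total = power.sum()
    if total <= 0:
        return float("nan")
    cum = np.cumsum(power)
    idx = int(np.searchsorted(cum, r * total))
    idx = min(idx, len(freqs) - 1)
    return float(freqs[idx] / norm_hz)
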