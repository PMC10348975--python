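"""Complexity features: Poincaré ellipsoid radius ratio and Lempel-Ziv complexity.

The Poincaré plot maps x(t) against x(t+τ) (τ = 1 sample); SD1 and SD2 are
the dispersions across and along the identity line,

    SD1 = (√2 / 2) · SD(x(t) − x(t+τ)),
    SD2 = sqrt( 2 · SD(x)² − SD1² ).

Their ratio ERR = SD1/SD2 is ≈ 1 for exchangeable (random) signals and → 0
for linearly predictable ones.

Lempel-Ziv complexity counts the new sub-strings encountered while streaming
a binary sequence left to right.  The signal is binarised through its
Hilbert transform x_h: bit 1 where |x_h(t)| exceeds the segment mean of
|x_h|, 0 otherwise.  The default parsing is the LZ76 exhaustive scheme
(the EEG-literature standard); an LZ78 dictionary parse is available behind
a flag.  The normalised complexity is c(n)·log2(n)/n, which tends to 1 for
i.i.d. fair-coin sequences.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = ["poincare_err", "hilbert_binarize", "lzc"]


def poincare_err(x: np.ndarray, tau: int = 1) -> float:
    """Ellipsoid radius ratio SD1/SD2 of the Poincaré plot.

    Returns NaN when SD2 is zero (constant signal) or the SD2 radicand is
    non-positive (pathological two-point signals).
    """
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise ValueError(f"tau must be >= 1 sample, got {tau}")
    if x.size < tau + 2:
        raise ValueError(f"window of {x.size} samples too short for tau={tau}")
    d = x[:-tau] - x[tau:]
    sd_d = np.std(d, ddof=1)
    sd_x = np.std(x, ddof=1)
    sd1 = (np.sqrt(2.0) / 2.0) * sd_d
    radicand = 2.0 * sd_x**2 - 0.5 * sd_d**2
    if radicand <= 0:
        return float("nan")
    sd2 = np.sqrt(radicand)
    if sd2 == 0:
        return float("nan")
    return float(sd1 / sd2)


def hilbert_binarize(x: np.ndarray) -> np.ndarray:
    """Binarise a window through the magnitude of its Hilbert transform.

    Bit t is 1 iff |x_h(t)| > mean_t |x_h(t)| where x_h is the Hilbert
    transform (the imaginary part of the analytic signal).  Ties — including
    the all-zero signal — map to 0.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError(f"window of {x.size} samples too short to binarise")
    xh = np.abs(np.imag(signal.hilbert(x)))
    return (xh > xh.mean()).astype(np.uint8)


def _lz76(bits: np.ndarray) -> int:
    """Exhaustive LZ76 parsing complexity.

    Each phrase is the shortest prefix of the remaining stream that cannot
    be copied from the sequence seen so far (overlap with the phrase's own
    start allowed).  Implemented with C-level substring search on the byte
    string for speed.
    """
    s = bits.tobytes()
    n = len(s)
    c = 0
    p = 0
    while p < n:
        length = 1
        # grow the phrase while it is reproducible from the history
        while p + length <= n and s[p : p + length] in s[: p + length - 1]:
            length += 1
        c += 1
        p += length
    return c


def _lz78(bits: np.ndarray) -> int:
    """LZ78 incremental-dictionary phrase count (alternative scheme)."""
    phrases: set[bytes] = set()
    w = bytearray()
    for b in bits:
        w.append(b)
        key = bytes(w)
        if key not in phrases:
            phrases.add(key)
            w.clear()
    # a trailing unfinished word counts as one more phrase
    return len(phrases) + (1 if w else 0)


def lzc(bits: np.ndarray, normalize: bool = True, scheme: str = "lz76") -> float:
    """Lempel-Ziv complexity of a binary sequence.

    Parameters
    ----------
    bits : array-like of {0, 1}
    normalize : bool
        If True, return c(n) · log2(n) / n; otherwise the raw phrase count.
    scheme : {"lz76", "lz78"}
        Parsing scheme; exhaustive LZ76 is the default.
    """
    bits = np.asarray(bits)
    if bits.size == 0:
        raise ValueError("empty bit sequence")
    if not np.isin(bits, (0, 1)).all():
        raise ValueError("sequence must be binary")
    bits = bits.astype(np.uint8)
    if scheme == "lz76":
        c = _lz76(bits)
    elif scheme == "lz78":
        c = _lz78(bits)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    if not normalize:
        return float(c)
    n = bits.size
    if n < 2:
        return float(c)
    return float(c * np.log2(n) / n)
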