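"""Connectivity features: θ-band imaginary coherency and weighted symbolic MI.

Coherency between channels x and y at frequency f is
S_xy(f) / sqrt(S_xx(f)·S_yy(f)); only its imaginary part is retained, which
suppresses zero-lag (volume-conducted) coupling.  The per-pair feature is
the mean of |Im(coherency)| over the θ-band (4-8 Hz) bins, spectra being
estimated with the same Welch scheme as the spectral features.

wSMI maps each signal to a sequence of ordinal patterns — the rank order of
k = 3 samples spaced τ apart (τ = 16 ms, i.e. 8 samples at 500 Hz, tuning
the patterns to θ-range dynamics) — and computes the mutual information
between the two symbol streams, normalised by log(k!).  Pattern pairs that
are identical or sign-opposite get weight 0, discounting common-source
artefacts; all other pairs get weight 1.  Because the zero-weight cells are
excluded, the raw weighted sum can dip a hair below 0 through estimation
noise on independent signals; estimates are floored at 0 to respect the
measure's [0, 1] range.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .spectral import THETA, BandDefinition

__all__ = [
    "SymbolSequence",
    "symbolize",
    "wsmi_pair",
    "icoh_pair",
    "aggregate_pairs",
    "tau_samples_for",
]

WSMI_TAU_MS = 16.0  # ordinal-pattern element spacing


def tau_samples_for(fs: float, tau_ms: float = WSMI_TAU_MS) -> int:
    """Round the symbolic time lag to whole samples; warn on coarse grids."""
    exact = tau_ms * fs / 1000.0
    tau = max(1, int(round(exact)))
    if exact > 0 and abs(tau - exact) / exact > 0.10:
        warnings.warn(
            f"tau = {tau_ms} ms is {exact:.2f} samples at fs = {fs} Hz; "
            f"rounded to {tau} (> 10% rounding error)",
            stacklevel=2,
        )
    return tau


@dataclass
class SymbolSequence:
    """Ordinal-pattern symbol stream derived from one channel window."""

    symbols: np.ndarray  # int codes in [0, k!)
    k: int
    tau_samples: int

    def __len__(self) -> int:
        return len(self.symbols)

    @property
    def n_symbols(self) -> int:
        return math.factorial(self.k)


def _pattern_codes(k: int) -> dict[tuple[int, ...], int]:
    return {perm: i for i, perm in enumerate(itertools.permutations(range(k)))}


def _opposite_code_map(k: int) -> np.ndarray:
    """Code of the rank-reversed (sign-flipped) pattern, per code."""
    codes = _pattern_codes(k)
    opp = np.empty(len(codes), dtype=np.int64)
    for perm, code in codes.items():
        reversed_perm = tuple((k - 1) - r for r in perm)
        opp[code] = codes[reversed_perm]
    return opp


def symbolize(x: np.ndarray, k: int = 3, tau_samples: int = 8) -> SymbolSequence:
    """Encode a window as ordinal patterns of k samples spaced tau apart.

    The symbol at t is the rank pattern of (x[t], x[t+τ], ..., x[t+(k-1)τ]);
    ties are broken by temporal order (the earlier sample ranks lower), so a
    constant signal maps to a single repeated pattern.
    """
    x = np.asarray(x, dtype=float)
    span = (k - 1) * tau_samples
    if x.size <= span:
        raise ValueError(
            f"window of {x.size} samples too short for k={k}, tau={tau_samples}"
        )
    n = x.size - span
    # (n, k) lagged embedding
    emb = np.stack([x[i * tau_samples : i * tau_samples + n] for i in range(k)], axis=1)
    # stable double argsort gives ranks with earlier-sample-wins tie-breaking
    order = np.argsort(emb, axis=1, kind="stable")
    ranks = np.empty_like(order)
    rows = np.arange(n)[:, None]
    ranks[rows, order] = np.arange(k)[None, :]
    # encode the rank tuple in factorial-free positional form (base k)
    weights = (k ** np.arange(k - 1, -1, -1)).astype(np.int64)
    raw = ranks @ weights
    # remap raw positional codes to dense 0..k!-1 codes
    codes = _pattern_codes(k)
    lut = np.full(k ** k, -1, dtype=np.int64)
    for perm, code in codes.items():
        lut[int(np.dot(perm, weights))] = code
    return SymbolSequence(symbols=lut[raw], k=k, tau_samples=tau_samples)


def wsmi_pair(sx: SymbolSequence, sy: SymbolSequence) -> float:
    """Weighted symbolic mutual information between two symbol streams.

    Joint and marginal pattern probabilities are empirical frequencies; the
    weighted MI is normalised by log(k!) and floored at 0.
    """
    if sx.k != sy.k or sx.tau_samples != sy.tau_samples:
        raise ValueError("symbol sequences must share k and tau")
    if len(sx) != len(sy):
        raise ValueError(f"length mismatch: {len(sx)} vs {len(sy)}")
    k = sx.k
    n_sym = math.factorial(k)
    n = len(sx)
    if n < n_sym:
        warnings.warn(
            f"only {n} symbols for a {n_sym}-letter alphabet; wSMI estimate unstable",
            stacklevel=2,
        )
    joint = np.bincount(
        sx.symbols * n_sym + sy.symbols, minlength=n_sym * n_sym
    ).reshape(n_sym, n_sym).astype(float) / n
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)

    w = np.ones((n_sym, n_sym))
    idx = np.arange(n_sym)
    w[idx, idx] = 0.0                      # identical patterns
    w[idx, _opposite_code_map(k)] = 0.0    # sign-opposite patterns

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = joint / (px[:, None] * py[None, :])
        terms = np.where(joint > 0, w * joint * np.log(ratio), 0.0)
    value = terms.sum() / math.log(n_sym)
    return float(max(value, 0.0))


def icoh_pair(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    band: BandDefinition = THETA,
) -> float:
    """Mean |imaginary coherency| over the band's frequency bins.

    Cross- and auto-spectra use the same Welch scheme as the spectral
    features (Hamming, 1/8-length sub-windows, 50% overlap).  Returns NaN
    when either channel has zero power in the band.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("channel windows must have the same length")
    if band.f2 >= fs / 2:
        raise ValueError(f"band {band} reaches Nyquist at fs={fs}")
    n = x.size
    if n < 8:
        raise ValueError("window too short for spectral estimation")
    nperseg = n // 8
    kw = dict(fs=fs, window="hamming", nperseg=nperseg,
              noverlap=nperseg // 2, detrend=False)
    freqs, sxy = signal.csd(x, y, **kw)
    _, sxx = signal.welch(x, **kw)
    _, syy = signal.welch(y, **kw)
    mask = (freqs >= band.f1) & (freqs <= band.f2)
    denom = np.sqrt(sxx[mask] * syy[mask])
    if not mask.any() or np.any(denom == 0):
        return float("nan")
    coherency = sxy[mask] / denom
    return float(np.mean(np.abs(np.imag(coherency))))


def aggregate_pairs(values: np.ndarray | list[float]) -> float:
    """Mean over channel pairs, ignoring NaN pairs; NaN if all pairs are NaN."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("no channel pairs to aggregate")
    if np.isnan(values).all():
        warnings.warn("all channel pairs NaN", stacklevel=2)
        return float("nan")
    return float(np.nanmean(values))
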