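"""Synthetic multichannel EEG with a known conscious/unconscious schedule.

The original clinical recordings are restricted, so this module generates
surrogate data that reproduce the statistical contrasts the estimation
method relies on.  Each channel is a sum of band-limited filtered-noise
components (δ 0.5-4, θ 4-8, α 8-12, β 12-30 Hz) plus a white broadband
component; the mixing weights switch instantaneously with the scheduled
state.  Conscious epochs have, by construction:

* higher θ and β relative power,
* a spectral edge frequency above the α band (via the broadband component),
* higher signal randomness (larger broadband fraction → higher LZC and
  ERR closer to 1),
* stronger θ-band inter-channel coupling, realised by a shared θ-band
  source injected into every channel with channel-specific sample delays
  (1-10 samples) so the shared component carries non-zero imaginary
  coherency rather than a zero-lag, volume-conduction-like copy.

Alongside the recording the module emits the per-sample true state labels
and an eyes-scoring sequence (one O/C/O-C/NA label per 5-min epoch), the
behavioural proxy the evaluation stage compares against.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .recording import EEGRecording

__all__ = [
    "StateSchedule",
    "StateParams",
    "SynthConfig",
    "generate_recording",
    "generate_eyes_scoring",
    "DEFAULT_CONSCIOUS",
    "DEFAULT_UNCONSCIOUS",
]

BANDS_HZ = {"delta": (0.5, 4.0), "theta": (4.0, 8.0),
            "alpha": (8.0, 12.0), "beta": (12.0, 30.0)}

CONSCIOUS = "conscious"
UNCONSCIOUS = "unconscious"


@dataclass
class StateSchedule:
    """Ordered (duration_s, state) blocks defining the ground-truth sequence."""

    entries: list[tuple[float, str]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("schedule must contain at least one entry")
        for dur, state in self.entries:
            if dur <= 0:
                raise ValueError(f"entry duration must be positive, got {dur}")
            if state not in (CONSCIOUS, UNCONSCIOUS):
                raise ValueError(f"unknown state {state!r}")

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.entries))

    def sample_labels(self, fs: float) -> np.ndarray:
        """Per-sample labels: 1 = conscious, 0 = unconscious."""
        pieces = [
            np.full(int(round(d * fs)), 1 if s == CONSCIOUS else 0, dtype=np.uint8)
            for d, s in self.entries
        ]
        return np.concatenate(pieces)

    @classmethod
    def alternating(cls, block_s: float, n_blocks: int,
                    first: str = CONSCIOUS) -> "StateSchedule":
        other = UNCONSCIOUS if first == CONSCIOUS else CONSCIOUS
        return cls([(block_s, first if i % 2 == 0 else other)
                    for i in range(n_blocks)])


@dataclass
class StateParams:
    """Per-state generative parameters.

    ``band_weights`` are amplitude weights of unit-variance band-limited
    components; ``broadband_frac`` is the fraction of signal variance
    contributed by the white broadband component; ``theta_coupling`` is the
    fraction of θ variance drawn from the cross-channel shared source.
    """

    band_weights: dict[str, float]
    broadband_frac: float
    theta_coupling: float

    def __post_init__(self) -> None:
        for name, w in self.band_weights.items():
            if name not in BANDS_HZ:
                raise ValueError(f"unknown band {name!r}")
            if w < 0:
                raise ValueError(f"band weight must be >= 0, got {name}={w}")
        if not 0 <= self.broadband_frac <= 1:
            raise ValueError(f"broadband_frac must be in [0,1], got {self.broadband_frac}")
        if not 0 <= self.theta_coupling <= 1:
            raise ValueError(f"theta_coupling must be in [0,1], got {self.theta_coupling}")


# Defaults chosen to realise the hypothesised conscious/unconscious contrast
# with a comfortable margin: awake-like broadband, θ/β-rich activity versus
# δ-dominated, narrowband, weakly coupled activity.
DEFAULT_CONSCIOUS = StateParams(
    band_weights={"delta": 0.5, "theta": 1.0, "alpha": 0.6, "beta": 0.8},
    broadband_frac=0.5,
    theta_coupling=0.7,
)
DEFAULT_UNCONSCIOUS = StateParams(
    band_weights={"delta": 1.5, "theta": 0.4, "alpha": 0.8, "beta": 0.2},
    broadband_frac=0.15,
    theta_coupling=0.1,
)


@dataclass
class SynthConfig:
    n_channels: int = 6
    fs: float = 500.0
    seed: int = 0
    conscious_params: StateParams = field(
        default_factory=lambda: replace(DEFAULT_CONSCIOUS)
    )
    unconscious_params: StateParams = field(
        default_factory=lambda: replace(DEFAULT_UNCONSCIOUS)
    )
    eyes_epoch_s: float = 300.0
    eyes_noise_rate: float = 0.0
    amplitude_uv: float = 20.0   # overall RMS scale of the output, µV

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("need at least one channel")
        if self.fs <= 2 * 45.0:
            raise ValueError(
                f"fs = {self.fs} Hz too low for 45 Hz content (need > 90 Hz)"
            )
        if not 0 <= self.eyes_noise_rate <= 1:
            raise ValueError("eyes_noise_rate must be in [0,1]")


def _band_noise(rng: np.random.Generator, n: int, fs: float,
                lo: float, hi: float) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    x = rng.standard_normal(n)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = signal.sosfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def _params_for(config: SynthConfig, state: int) -> StateParams:
    return config.conscious_params if state == 1 else config.unconscious_params


def generate_recording(
    schedule: StateSchedule, config: SynthConfig
) -> tuple[EEGRecording, np.ndarray]:
    """Generate a recording following ``schedule`` plus per-sample labels.

    Deterministic for a fixed ``config.seed``.
    """
    fs = config.fs
    labels = schedule.sample_labels(fs)
    n = labels.size
    if n == 0:
        raise ValueError("schedule has zero total duration")
    rng = np.random.default_rng(config.seed)

    # per-sample state-dependent weight envelopes
    per_state = {s: _params_for(config, s) for s in (0, 1)}
    band_env = {
        b: np.where(labels == 1,
                    per_state[1].band_weights.get(b, 0.0),
                    per_state[0].band_weights.get(b, 0.0))
        for b in BANDS_HZ
    }
    band_norm = np.sqrt(sum(env**2 for env in band_env.values()))
    band_norm[band_norm == 0] = 1.0
    broad_env = np.where(labels == 1,
                         per_state[1].broadband_frac,
                         per_state[0].broadband_frac)
    coup_env = np.where(labels == 1,
                        per_state[1].theta_coupling,
                        per_state[0].theta_coupling)

    # shared θ source: common waveform, channel-specific delays (1-10 samples)
    shared_theta = _band_noise(rng, n + 16, fs, *BANDS_HZ["theta"])
    max_delay = 10
    if config.n_channels <= max_delay:
        delays = rng.choice(np.arange(1, max_delay + 1),
                            size=config.n_channels, replace=False)
    else:
        delays = rng.integers(1, max_delay + 1, size=config.n_channels)

    data = np.empty((config.n_channels, n))
    for c in range(config.n_channels):
        band_part = np.zeros(n)
        for b, (lo, hi) in BANDS_HZ.items():
            comp = _band_noise(rng, n, fs, lo, hi)
            if b == "theta":
                shared = shared_theta[delays[c] : delays[c] + n]
                comp = (np.sqrt(1.0 - coup_env) * comp
                        + np.sqrt(coup_env) * shared)
            band_part += band_env[b] * comp
        band_part /= band_norm
        white = rng.standard_normal(n)
        x = (np.sqrt(1.0 - broad_env) * band_part
             + np.sqrt(broad_env) * white)
        data[c] = config.amplitude_uv * x

    rec = EEGRecording(
        data=data,
        fs=fs,
        channel_labels=[f"ch{i}" for i in range(config.n_channels)],
        start_time=0.0,
    )
    return rec, labels


def generate_eyes_scoring(
    schedule: StateSchedule, config: SynthConfig
) -> "EyesScoring":
    """Eyes-scoring labels aligned with the schedule, one per 5-min epoch.

    An epoch is O if majority-conscious, C if majority-unconscious, O/C on
    an exact tie; a seeded fraction ``eyes_noise_rate`` of the labels is
    replaced by NA (scoring unavailable).  Epochs tile the recording; a
    trailing partial epoch is kept.
    """
    from .evaluate import EyesScoring

    fs = config.fs
    labels = schedule.sample_labels(fs)
    n = labels.size
    epoch = int(round(config.eyes_epoch_s * fs))
    starts = np.arange(0, n, epoch)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xE7E5]))
    rows = []
    for s in starts:
        e = min(s + epoch, n)
        frac = labels[s:e].mean()
        if frac > 0.5:
            lab = "O"
        elif frac < 0.5:
            lab = "C"
        else:
            lab = "O/C"
        if rng.random() < config.eyes_noise_rate:
            lab = "NA"
        rows.append((s / fs, e / fs, lab))
    return EyesScoring(epochs=rows, epoch_length_s=config.eyes_epoch_s)
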