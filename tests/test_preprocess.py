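import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from eegcl import EEGRecording, bandpass_filter, segment, select_channels


def _designed_gain(freq_hz, fs=500.0, low=0.5, high=45.0, order=3, zero_phase=True):
    """Magnitude response of the designed Butterworth at one frequency."""
    sos = sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=[freq_hz], fs=fs)
    gain = np.abs(h[0])
    return gain**2 if zero_phase else gain


class TestBandpassFilter:
    def test_passband_preserves_10hz_sine(self):
        fs = 500.0
        t = np.arange(int(20 * fs)) / fs
        rec = EEGRecording(np.sin(2 * np.pi * 10 * t)[None, :], fs)
        out = bandpass_filter(rec)
        # designed transfer function predicts near-unity gain at 10 Hz
        assert _designed_gain(10.0) > 0.98
        mid = slice(1000, -1000)  # avoid edge transients
        amp_ratio = np.abs(out.data[0, mid]).max() / np.abs(rec.data[0, mid]).max()
        assert amp_ratio == pytest.approx(1.0, abs=0.05)

    def test_stopband_rejects_slow_drift(self):
        fs = 500.0
        t = np.arange(int(60 * fs)) / fs
        rec = EEGRecording(np.sin(2 * np.pi * 0.05 * t)[None, :], fs)
        out = bandpass_filter(rec)
        assert _designed_gain(0.05) ** 2 < 1e-4  # power gain of one pass
        power_ratio = np.mean(out.data**2) / np.mean(rec.data**2)
        assert power_ratio < 0.01

    def test_zero_signal_maps_to_zero(self):
        rec = EEGRecording(np.zeros((2, 5000)), fs=500.0)
        out = bandpass_filter(rec)
        assert np.allclose(out.data, 0.0)

    def test_high_cut_at_nyquist_rejected(self):
        rec = EEGRecording(np.random.default_rng(0).standard_normal((1, 5000)), fs=80.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filter(rec, high=45.0)

    def test_too_short_signal_rejected(self):
        rec = EEGRecording(np.zeros((1, 10)), fs=500.0)
        with pytest.raises(ValueError, match="too short"):
            bandpass_filter(rec)

    def test_passband_idempotent_and_commutes_with_selection(self, rng):
        # pass-band content: a second filter pass changes almost nothing
        fs = 500.0
        t = np.arange(10000) / fs
        x = sum(np.sin(2 * np.pi * f * t + p)
                for f, p in [(5, 0.0), (10, 1.0), (20, 2.0)])
        rec = EEGRecording(np.tile(x, (3, 1)), fs=fs,
                           channel_labels=["a", "b", "c"])
        once = bandpass_filter(rec)
        twice = bandpass_filter(once)
        mid = slice(1000, -1000)
        rel_err = (np.linalg.norm(twice.data[0, mid] - once.data[0, mid])
                   / np.linalg.norm(once.data[0, mid]))
        assert rel_err < 0.05  # pass-band gain is ~1, not exactly 1
        noisy = EEGRecording(rng.standard_normal((3, 10000)), fs=fs,
                             channel_labels=["a", "b", "c"])
        sel_then_filt = bandpass_filter(select_channels(noisy, ["c", "a"]))
        filt_then_sel = select_channels(bandpass_filter(noisy), ["c", "a"])
        assert np.allclose(sel_then_filt.data, filt_then_sel.data)


class TestSelectChannels:
    def test_subset_of_montage(self, rng):
        labels = [f"e{i}" for i in range(18)]
        rec = EEGRecording(rng.standard_normal((18, 100)), 500.0, labels)
        wanted = labels[:12]
        out = select_channels(rec, wanted)
        assert out.channel_labels == wanted
        assert out.data.shape == (12, 100)

    def test_all_channels_is_identity(self, rng):
        rec = EEGRecording(rng.standard_normal((3, 50)), 500.0, ["a", "b", "c"])
        out = select_channels(rec, ["a", "b", "c"])
        assert np.array_equal(out.data, rec.data)

    def test_unknown_label_raises_naming_it(self, rng):
        rec = EEGRecording(rng.standard_normal((2, 50)), 500.0, ["a", "b"])
        with pytest.raises(KeyError, match="XX"):
            select_channels(rec, ["a", "XX"])


class TestSegment:
    @pytest.mark.parametrize(
        "duration_s, expected",
        [(10.0, 8), (3.0, 1), (3.5, 1)],
    )
    def test_window_counts(self, duration_s, expected):
        fs = 500.0
        rec = EEGRecording(np.zeros((1, int(duration_s * fs))), fs)
        segs = segment(rec)
        assert len(segs) == expected
        assert all(end - start == 1500 for start, end in segs.windows)

    def test_too_short_recording_raises(self):
        rec = EEGRecording(np.zeros((1, 100)), fs=500.0)
        with pytest.raises(ValueError, match="shorter"):
            segment(rec)

    @given(
        n_samples=st.integers(min_value=400, max_value=20000),
        window=st.integers(min_value=2, max_value=8),
        hop=st.integers(min_value=1, max_value=10),
    )
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_window_count_formula(self, n_samples, window, hop):
        fs = 100.0
        if n_samples < window * fs:
            return
        rec = EEGRecording(np.zeros((1, n_samples)), fs)
        segs = segment(rec, window_s=window, hop_s=hop)
        duration = n_samples / fs
        assert len(segs) == int((duration - window) // hop) + 1
        # consecutive starts differ by hop, windows stay in bounds
        starts = segs.windows[:, 0]
        assert np.all(np.diff(starts) == hop * fs)
        assert segs.windows[-1, 1] <= n_samples
        # with overlapping or abutting windows every sample of the first
        # duration - window seconds is covered (gaps are expected otherwise)
        if hop <= window:
            covered = np.zeros(n_samples, dtype=bool)
            for s, e in segs.windows:
                covered[s:e] = True
            assert covered[: n_samples - int(window * fs)].all()
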