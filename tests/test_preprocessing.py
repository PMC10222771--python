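"""Filtering, loading and windowing contracts."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from momofuse.errors import FormatError, ParameterError
from momofuse.preprocessing import (
    FilterConfig,
    butterworth_lowpass,
    load_recording,
    segment_windows,
    subtract_background,
    wavelet_quaternion_filter,
)


def _write_stream(path, n, fs, channels, jitter=None, duplicates=0, seed=0):
    rng = np.random.default_rng(seed)
    t = np.arange(n) / fs
    if jitter:
        t = np.sort(t + rng.uniform(-jitter, jitter, n))
    df = pd.DataFrame(rng.normal(size=(n, channels)),
                      columns=[f"ch{i}" for i in range(channels)])
    df.insert(0, "timestamp", t)
    if duplicates:
        df = pd.concat([df, df.iloc[:duplicates]], ignore_index=True)
    df.to_csv(path, index=False)
    return df


class TestLoadRecording:
    def test_identity_load(self, tmp_path):
        _write_stream(tmp_path / "amb.csv", 100, 10.0, 3)
        rec = load_recording(str(tmp_path / "amb.csv"), None, None, None)
        assert rec.ambient.shape == (100, 3)
        assert not rec.has_inertial and not rec.has_frames

    def test_absent_frames_dir_gives_empty_track(self, tmp_path):
        _write_stream(tmp_path / "amb.csv", 10, 10.0, 1)
        rec = load_recording(str(tmp_path / "amb.csv"), None,
                             str(tmp_path / "missing"), None)
        assert rec.frames == [] and len(rec.frame_labels) == 0

    def test_duplicate_timestamps_deduplicated(self, tmp_path):
        _write_stream(tmp_path / "amb.csv", 50, 10.0, 2, duplicates=7)
        rec = load_recording(str(tmp_path / "amb.csv"), None, None, None)
        assert rec.ambient.shape == (50, 2)

    def test_missing_file_raises_named_error(self, tmp_path):
        with pytest.raises(Exception, match="nope.csv"):
            load_recording(str(tmp_path / "nope.csv"), None, None, None)

    def test_irregular_timestamps_resampled(self, tmp_path):
        _write_stream(tmp_path / "amb.csv", 80, 10.0, 2, jitter=0.02)
        rec = load_recording(str(tmp_path / "amb.csv"), None, None, None)
        assert rec.ambient.shape[1] == 2
        assert abs(len(rec.ambient) - 80) <= 2


class TestButterworth:
    def test_dc_passthrough(self):
        x = np.full(200, 2.0)
        assert np.allclose(butterworth_lowpass(x, 25.0, 5.0, 3), 2.0, atol=1e-6)

    def test_zero_in_zero_out(self):
        assert np.all(butterworth_lowpass(np.zeros(100), 25.0) == 0)

    def test_amplitude_ratio_at_cutoff_is_half(self):
        # forward-backward application squares the single-pass -3 dB gain
        fs, fc = 100.0, 5.0
        t = np.arange(4000) / fs
        y = butterworth_lowpass(np.sin(2 * np.pi * fc * t), fs, fc, order=3)
        mid = y[1000:3000]
        assert np.ptp(mid) / 2 == pytest.approx(0.5, abs=0.05)

    def test_zero_phase_no_lag(self):
        fs = 50.0
        t = np.arange(1000) / fs
        x = np.sin(2 * np.pi * 1.0 * t)
        y = butterworth_lowpass(x, fs, 5.0)
        lags = sps.correlation_lags(len(x), len(y))
        assert lags[np.argmax(sps.correlate(x, y))] == 0

    @pytest.mark.parametrize("bad_cutoff", [12.5, 20.0])
    def test_cutoff_at_or_above_nyquist_rejected(self, bad_cutoff):
        with pytest.raises(ParameterError):
            butterworth_lowpass(np.ones(100), 25.0, bad_cutoff)

    def test_too_short_signal_rejected(self):
        with pytest.raises(ParameterError):
            butterworth_lowpass(np.ones(10), 25.0, 5.0, order=3)


class TestWaveletQuaternionFilter:
    def test_clean_sinusoid_preserved(self):
        t = np.arange(512) / 25.0
        x = np.sin(2 * np.pi * 1.5 * t)
        y, _ = wavelet_quaternion_filter(x)
        rel = np.sqrt(np.mean((y - x) ** 2)) / np.sqrt(np.mean(x**2))
        assert rel <= 1e-3

    def test_denoising_reduces_rms_error(self, rng):
        t = np.arange(1024) / 25.0
        clean = np.sin(2 * np.pi * 1.0 * t)
        noisy = clean + rng.normal(0, 0.5, len(t))
        y, _ = wavelet_quaternion_filter(noisy)
        assert np.sqrt(np.mean((y - clean) ** 2)) < np.sqrt(np.mean((noisy - clean) ** 2))

    def test_idempotent_on_smooth_signal(self):
        t = np.arange(512) / 25.0
        x = np.sin(2 * np.pi * 0.8 * t)
        once, _ = wavelet_quaternion_filter(x)
        twice, _ = wavelet_quaternion_filter(once)
        assert np.allclose(once, twice, atol=1e-6)

    def test_quaternion_renormalised(self):
        q = np.array([[2.0, 0.0, 0.0, 0.0], [0.0, 3.0, 0.0, 0.0]])
        _, qn = wavelet_quaternion_filter(np.ones((64, 1)) + np.sin(np.arange(64))[:, None], q)
        assert np.allclose(qn[0], [1, 0, 0, 0])
        assert np.allclose(np.linalg.norm(qn, axis=1), 1.0)

    def test_degenerate_quaternion_row_named(self):
        q = np.array([[1.0, 0, 0, 0], [1e-12, 0, 0, 0]])
        with pytest.raises(ParameterError, match="row 1"):
            wavelet_quaternion_filter(np.random.default_rng(0).normal(size=(64, 1)), q)


class TestSubtractBackground:
    def test_identical_frames_give_zero_masks(self, rng):
        frame = rng.integers(0, 255, size=(40, 30)).astype(np.uint8)
        masks = subtract_background([frame] * 5)
        assert all(not m.any() for m in masks)

    def test_moving_rectangle_area_recovered(self):
        h, w, side = 60, 80, 14
        frames = []
        for i in range(10):
            f = np.full((h, w), 30, dtype=np.uint8)
            x0 = 5 + 6 * i
            f[20:20 + side, x0:x0 + side] = 220
            frames.append(f)
        masks = subtract_background(frames, FilterConfig(morph_radius=1))
        for m in masks:
            assert m.sum() == pytest.approx(side * side, rel=0.10)

    def test_two_frames_rejected(self):
        with pytest.raises(ParameterError):
            subtract_background([np.zeros((4, 4), dtype=np.uint8)] * 2)

    def test_inconsistent_sizes_rejected(self):
        with pytest.raises(FormatError):
            subtract_background(
                [np.zeros((4, 4), np.uint8), np.zeros((5, 4), np.uint8),
                 np.zeros((4, 4), np.uint8)]
            )


class TestSegmentWindows:
    def test_floor_arithmetic(self):
        wins = segment_windows(np.zeros((1000, 2)), 25.0, np.zeros(1000))
        assert len(wins) == 10 and all(len(w.data) == 100 for w in wins)

    def test_half_overlap_count(self):
        wins = segment_windows(np.zeros((1000, 1)), 25.0, np.zeros(1000), overlap=0.5)
        assert len(wins) == 19  # floor((1000-100)/50)+1

    def test_short_signal_yields_empty(self):
        assert segment_windows(np.zeros((99, 1)), 25.0, np.zeros(99)) == []

    def test_majority_label_with_tie_to_smaller_id(self):
        labels = np.array([3] * 50 + [1] * 50 + [2] * 100)
        wins = segment_windows(np.zeros((200, 1)), 25.0, labels)
        assert wins[0].label == 1  # 50/50 tie between 3 and 1 -> smaller id
        assert wins[1].label == 2

    def test_sample_conservation(self):
        for n in (100, 137, 731):
            wins = segment_windows(np.zeros((n, 1)), 10.0, np.zeros(n), window_s=4)
            w, step = 40, 40
            assert len(wins) * step + w <= n + step
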