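"""Resampling, cycle extraction, length normalisation, screening, splitting."""

import numpy as np
import pytest

from lungsound.icbhi_io import CycleAnnotation
from lungsound.labels import Label
from lungsound.preprocess import (
    CycleClip,
    DatasetMatrix,
    PreprocessConfig,
    extract_cycles,
    fix_length,
    resample,
    segment_events,
    spectrogram,
    split_train_test,
    validity_screen,
)
from lungsound.synth import SynthConfig, synth_cycle


def _sine(freq, rate, dur=1.0):
    t = np.arange(int(rate * dur)) / rate
    return np.sin(2 * np.pi * freq * t)


class TestResample:
    def test_identity_when_rates_match(self):
        x = np.random.default_rng(0).normal(size=1000)
        np.testing.assert_array_equal(resample(x, 4000, 4000), x)

    def test_output_length_arithmetic(self):
        assert len(resample(np.zeros(44100), 44100, 4000)) == 4000
        assert len(resample(np.zeros(8013), 8000, 4000)) == round(8013 / 2)

    def test_downsampled_sine_matches_direct_synthesis(self):
        x = resample(_sine(500, 44100), 44100, 4000)
        ref = _sine(500, 4000)
        r = np.corrcoef(x[50:-50], ref[50:-50])[0, 1]
        assert r > 0.99

    def test_round_trip_preserves_bandlimited_content(self):
        x = _sine(300, 4000) + 0.5 * _sine(800, 4000)
        back = resample(resample(x, 4000, 8000), 8000, 4000)
        r = np.corrcoef(x[50:-50], back[50:-50])[0, 1]
        assert r > 0.99

    def test_empty_input(self):
        assert len(resample(np.array([]), 8000, 4000)) == 0


class TestExtractCycles:
    def test_index_arithmetic(self):
        wav = np.arange(40000, dtype=float)  # 10 s at 4 kHz
        anns = [CycleAnnotation(2.0, 4.5, False, False)]
        (clip,) = extract_cycles(wav, 4000, anns)
        assert len(clip.samples) == 10000
        assert clip.samples[0] == 8000  # round(2.0 * 4000)

    def test_no_annotations(self):
        assert extract_cycles(np.zeros(100), 4000, []) == []

    def test_out_of_range_annotation_skipped_and_overlap_clamped(self):
        wav = np.zeros(4000)  # 1 s
        anns = [
            CycleAnnotation(0.5, 1.2, False, False),  # clamped
            CycleAnnotation(2.0, 3.0, True, False),  # skipped
        ]
        clips = extract_cycles(wav, 4000, anns)
        assert len(clips) == 1
        assert len(clips[0].samples) == 4000 - 2000

    def test_labels_preserved_from_annotations(self):
        wav = np.zeros(8000)
        anns = [CycleAnnotation(0.0, 1.0, True, True), CycleAnnotation(1.0, 2.0, False, True)]
        labels = [c.label for c in extract_cycles(wav, 4000, anns)]
        assert labels == [Label.BOTH, Label.WHEEZE]


class TestFixLength:
    cfg = PreprocessConfig()

    def _clip(self, n):
        return CycleClip(np.arange(n, dtype=float), 4000, Label.NORMAL)

    def test_long_clip_keeps_initial_samples(self):
        out = fix_length(self._clip(64000), self.cfg)  # 16 s
        assert len(out.samples) == 8000
        np.testing.assert_array_equal(out.samples, np.arange(8000.0))

    def test_exact_length_unchanged(self):
        out = fix_length(self._clip(8000), self.cfg)
        np.testing.assert_array_equal(out.samples, np.arange(8000.0))

    def test_zero_padding(self):
        out = fix_length(self._clip(5000), self.cfg)
        assert len(out.samples) == 8000
        assert np.all(out.samples[5000:] == 0)

    def test_wrap_padding(self):
        cfg = PreprocessConfig(pad_mode="wrap")
        out = fix_length(self._clip(5000), cfg)
        np.testing.assert_array_equal(out.samples[5000:], np.arange(3000.0))

    def test_truncation_precedes_crop(self):
        # 2.7 s at 4 kHz = 10800 samples survive truncation, then crop to 8000
        out = fix_length(self._clip(20000), self.cfg)
        assert out.samples[-1] == 7999


class TestSegmentEvents:
    def test_window_counts(self):
        cfg = PreprocessConfig()
        clip = CycleClip(np.zeros(8000), 4000, Label.NORMAL)
        assert segment_events(clip, cfg, window_ms=25).shape == (80, 100)
        assert segment_events(clip, cfg, window_ms=20).shape == (100, 80)

    def test_window_longer_than_clip_clamped(self):
        cfg = PreprocessConfig()
        clip = CycleClip(np.zeros(50), 4000, Label.NORMAL)
        assert segment_events(clip, cfg).shape == (1, 50)

    def test_crackle_windows_spikier_than_normal(self):
        cfg = SynthConfig(seed=2)
        from scipy.stats import kurtosis

        crackle = synth_cycle(Label.CRACKLE, cfg, np.random.default_rng(2))
        normal = synth_cycle(Label.NORMAL, cfg, np.random.default_rng(2))
        pcfg = PreprocessConfig()
        kc = kurtosis(segment_events(CycleClip(crackle.samples, 4000, Label.CRACKLE), pcfg), axis=1).max()
        kn = kurtosis(segment_events(CycleClip(normal.samples, 4000, Label.NORMAL), pcfg), axis=1).max()
        assert kc > kn


class TestSpectrogram:
    def test_pure_tone_concentrates_in_one_bin(self):
        clip = CycleClip(_sine(500, 4000), 4000, Label.NORMAL)
        f, t, mag = spectrogram(clip)
        assert f[0] == 0 and f[-1] == 2000
        peak_bin = mag.mean(axis=1).argmax()
        assert abs(f[peak_bin] - 500) <= f[1] - f[0]

    def test_zero_clip_zero_matrix(self):
        _, _, mag = spectrogram(CycleClip(np.zeros(1024), 4000, Label.NORMAL))
        assert np.all(mag == 0)

    def test_too_short_clip_raises(self):
        with pytest.raises(ValueError):
            spectrogram(CycleClip(np.zeros(10), 4000, Label.NORMAL))

    def test_wheeze_ridge_persists_across_frames(self):
        cfg = SynthConfig(seed=3)
        clip = synth_cycle(Label.WHEEZE, cfg, np.random.default_rng(3))
        f, t, mag = spectrogram(CycleClip(clip.samples, clip.rate, Label.WHEEZE))
        ridge_bin = np.argmax(mag.sum(axis=1) * (f > 100))
        frame_peaks = mag.argmax(axis=0)
        frac = np.mean(np.abs(frame_peaks - ridge_bin) <= 2)
        assert frac >= 0.3


class TestValidityScreen:
    cfg = PreprocessConfig(screening_enabled=True, screening_threshold=1.0)

    def _synth(self, label, seed=4):
        c = synth_cycle(label, SynthConfig(seed=seed), np.random.default_rng(seed))
        return CycleClip(c.samples, c.rate, label)

    def test_wheeze_clip_passes(self):
        ok, _ = validity_screen(self._synth(Label.WHEEZE), self.cfg)
        assert ok

    def test_normal_clip_fails_when_labelled_wheeze(self):
        c = self._synth(Label.NORMAL)
        forced = CycleClip(c.samples, c.rate, Label.WHEEZE)
        ok, _ = validity_screen(forced, self.cfg)
        assert not ok

    def test_zero_threshold_admits_everything(self):
        cfg = PreprocessConfig(screening_enabled=True, screening_threshold=0.0)
        c = self._synth(Label.NORMAL)
        for lbl in Label:
            ok, _ = validity_screen(CycleClip(c.samples, c.rate, lbl), cfg)
            assert ok

    def test_screening_monotone_in_threshold(self):
        clip = self._synth(Label.BOTH)
        admitted = [
            validity_screen(clip, PreprocessConfig(screening_threshold=th))[0]
            for th in (0.0, 0.5, 1.0, 2.0, 5.0)
        ]
        # once rejected at some threshold, never admitted at a higher one
        assert admitted == sorted(admitted, reverse=True)


class TestSplit:
    def test_per_class_70_percent(self):
        rng = np.random.default_rng(0)
        counts = [40, 30, 20, 10]
        X = rng.normal(size=(100, 5))
        y = np.repeat([0, 1, 2, 3], counts)
        tr, te = split_train_test(DatasetMatrix(X, y), PreprocessConfig(seed=0))
        got = [int((tr.y == c).sum()) for c in range(4)]
        assert got == [28, 21, 14, 7]

    def test_disjoint_partition(self, small_matrix, preprocess_cfg):
        tr, te = split_train_test(small_matrix, preprocess_cfg)
        assert len(tr) + len(te) == len(small_matrix)
        assert set(tr.provenance).isdisjoint(te.provenance)

    def test_same_seed_identical(self, small_matrix, preprocess_cfg):
        a = split_train_test(small_matrix, preprocess_cfg)
        b = split_train_test(small_matrix, preprocess_cfg)
        np.testing.assert_array_equal(a[0].X, b[0].X)
        np.testing.assert_array_equal(a[1].y, b[1].y)

    def test_singleton_class_rejected(self):
        X = np.zeros((3, 4))
        y = np.array([0, 0, 1])
        with pytest.raises(ValueError, match="crackle"):
            split_train_test(DatasetMatrix(X, y), PreprocessConfig())


def test_pipeline_rows_fixed_length_and_labels_preserved(small_matrix, small_clips):
    assert small_matrix.X.shape == (20, 8000)
    assert [Label(v) for v in small_matrix.y] == [c.label for c in small_clips]
    assert np.abs(small_matrix.X).max() <= 1.0
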