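"""Raw recordings -> fixed-length, labelled, model-ready cycle clips.

Pipeline: resample every recording to a common rate (default 4 kHz — the
adventitious-sound band sits below 2 kHz, so Nyquist is respected), cut the
annotated respiratory cycles out of the waveform, normalise each cycle to a
fixed length (truncate long cycles at 2.7 s, then crop or pad to the model's
8000-sample input), optionally screen adventitious clips for spectrogram
evidence of their labelled event, and split into stratified train/test
partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from lungsound.icbhi_io import CycleAnnotation, paired_recordings, read_annotation, read_wav
from lungsound.labels import CLASS_NAMES, Label
from lungsound.synth import tonality_score, transient_score

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    target_rate: int = 4000
    cycle_truncation_s: float = 2.7
    model_input_samples: int = 8000
    pad_mode: str = "zero"  # or "wrap"
    event_window_ms: tuple[float, float] = (20.0, 25.0)
    screening_enabled: bool = False
    screening_threshold: float = 1.0
    split_fraction: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_rate <= 0:
            raise ValueError("target_rate must be positive")
        if self.model_input_samples > int(np.ceil(self.cycle_truncation_s * self.target_rate)):
            raise ValueError("model_input_samples exceeds the truncated cycle length")
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.pad_mode not in ("zero", "wrap"):
            raise ValueError("pad_mode must be 'zero' or 'wrap'")


@dataclass
class CycleClip:
    """One respiratory-cycle waveform with its label and provenance."""

    samples: np.ndarray
    rate: int
    label: Label
    source: str = "unknown"
    cycle_index: int = 0


@dataclass
class DatasetMatrix:
    """Fixed-length clips stacked into a model-ready matrix.

    ``X`` is (N, L); ``y`` holds integer labels per :class:`Label`;
    ``provenance`` tracks each row's origin (and marks oversampled rows).
    """

    X: np.ndarray
    y: np.ndarray
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2 or len(self.y) != self.X.shape[0]:
            raise ValueError("X must be (N, L) with one label per row")
        if not self.provenance:
            self.provenance = ["unknown"] * len(self.y)
        if len(self.provenance) != len(self.y):
            raise ValueError("provenance must have one entry per row")

    def __len__(self) -> int:
        return len(self.y)

    def class_counts(self) -> dict[str, int]:
        return {name: int((self.y == lbl).sum()) for name, lbl in zip(CLASS_NAMES, Label)}

    def subset(self, idx: np.ndarray) -> "DatasetMatrix":
        return DatasetMatrix(
            self.X[idx].copy(), self.y[idx].copy(), [self.provenance[i] for i in idx]
        )


def resample(waveform: np.ndarray, src_rate: int, dst_rate: int) -> np.ndarray:
    """Polyphase resampling with anti-alias filtering on downsampling.

    Output length is ``round(n * dst / src)``; a no-op when rates match.
    """
    if src_rate <= 0 or dst_rate <= 0:
        raise ValueError("sample rates must be positive")
    waveform = np.asarray(waveform, dtype=np.float64)
    if len(waveform) == 0:
        logger.warning("resample called on empty waveform")
        return waveform
    if src_rate == dst_rate:
        return waveform
    from math import gcd

    g = gcd(src_rate, dst_rate)
    up, down = dst_rate // g, src_rate // g
    out = signal.resample_poly(waveform, up, down)
    target = int(round(len(waveform) * dst_rate / src_rate))
    if len(out) > target:
        out = out[:target]
    elif len(out) < target:
        out = np.pad(out, (0, target - len(out)))
    return out


def extract_cycles(
    waveform: np.ndarray,
    rate: int,
    annotations: list[CycleAnnotation],
    source: str = "unknown",
) -> list[CycleClip]:
    """Cut annotated cycles out of a recording.

    Sample indices are ``round(t * rate)`` with half-open [start, end) spans
    so adjacent cycles never share a boundary sample.  Annotations that run
    marginally past the recording are clamped; ones fully outside are skipped
    with a warning.
    """
    n = len(waveform)
    clips: list[CycleClip] = []
    for i, ann in enumerate(annotations):
        lo = int(round(ann.start_s * rate))
        hi = int(round(ann.end_s * rate))
        if lo >= n:
            logger.warning("%s cycle %d (%.2f-%.2fs) outside audio; skipped", source, i, ann.start_s, ann.end_s)
            continue
        if hi > n:
            logger.warning("%s cycle %d clamped to recording end", source, i)
            hi = n
        clips.append(CycleClip(waveform[lo:hi].copy(), rate, ann.label, source, i))
    return clips


def fix_length(clip: CycleClip, cfg: PreprocessConfig) -> CycleClip:
    """Normalise a clip to exactly ``model_input_samples`` samples.

    Long cycles are first truncated at ``cycle_truncation_s`` (keeping the
    initial span), then cropped or padded to the model input length; padding
    is zeros by default, periodic wrap on request.
    """
    x = clip.samples
    trunc = int(round(cfg.cycle_truncation_s * clip.rate))
    if len(x) > trunc:
        x = x[:trunc]
    L = cfg.model_input_samples
    if len(x) > L:
        x = x[:L]
    elif len(x) < L:
        if cfg.pad_mode == "wrap":
            reps = int(np.ceil(L / max(len(x), 1)))
            x = np.tile(x, reps)[:L]
        else:
            x = np.pad(x, (0, L - len(x)))
    return replace_samples(clip, x)


def replace_samples(clip: CycleClip, samples: np.ndarray) -> CycleClip:
    return CycleClip(samples, clip.rate, clip.label, clip.source, clip.cycle_index)


def peak_normalize(x: np.ndarray) -> np.ndarray:
    """Scale to unit peak amplitude; silent clips pass through unchanged."""
    peak = np.abs(x).max()
    return x / peak if peak > 0 else x


def segment_events(clip: CycleClip, cfg: PreprocessConfig, window_ms: float | None = None) -> np.ndarray:
    """Non-overlapping short windows (default 25 ms) for event statistics/QC.

    Returns an (n_windows, width) array.  These windows feed quality control
    (e.g. per-window kurtosis for crackle evidence), not the model input; the
    classifier consumes the full fixed-length cycle.
    """
    ms = window_ms if window_ms is not None else cfg.event_window_ms[1]
    width = int(round(ms * clip.rate / 1000.0))
    if width <= 0:
        raise ValueError("event window must be positive")
    if width > len(clip.samples):
        logger.warning("event window longer than clip; clamped to clip length")
        return clip.samples[None, :]
    n_win = len(clip.samples) // width
    return clip.samples[: n_win * width].reshape(n_win, width)


def spectrogram(
    clip: CycleClip, nperseg: int = 256, noverlap: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Short-time Fourier magnitude (Hann window, 50% overlap by default).

    Returns (frequencies, frame times, |STFT|) with frequency rows spanning
    [0, rate/2].
    """
    if len(clip.samples) == 0:
        raise ValueError("cannot compute a spectrogram of an empty clip")
    if len(clip.samples) < nperseg:
        raise ValueError("clip shorter than one STFT window")
    if noverlap is None:
        noverlap = nperseg // 2
    f, t, z = signal.stft(
        clip.samples, fs=clip.rate, window="hann", nperseg=nperseg, noverlap=noverlap
    )
    return f, t, np.abs(z)


def validity_screen(clip: CycleClip, cfg: PreprocessConfig) -> tuple[bool, dict[str, float]]:
    """Automated stand-in for manual spectrogram review of adventitious clips.

    A labelled crackle/wheeze/both clip passes iff the matching evidence
    score — narrowband tonality for wheeze, short-window transient kurtosis
    for crackle — reaches ``screening_threshold`` (both must for ``both``).
    Scores are normalised by the QC thresholds so 1.0 is the natural operating
    point; a threshold of 0 admits everything.  Normal clips bypass screening.
    """
    from lungsound.synth import TONALITY_THRESHOLD, TRANSIENT_THRESHOLD

    scores = {
        "tonality": tonality_score(clip.samples, clip.rate) / TONALITY_THRESHOLD,
        "transient": transient_score(clip.samples, clip.rate) / TRANSIENT_THRESHOLD,
    }
    if clip.label == Label.NORMAL:
        return True, scores
    needed = []
    if clip.label in (Label.WHEEZE, Label.BOTH):
        needed.append(scores["tonality"])
    if clip.label in (Label.CRACKLE, Label.BOTH):
        needed.append(scores["transient"])
    return all(s >= cfg.screening_threshold for s in needed), scores


def clips_to_matrix(clips: list[CycleClip], cfg: PreprocessConfig) -> DatasetMatrix:
    """fix_length + per-clip peak normalisation + stacking."""
    fixed = [fix_length(c, cfg) for c in clips]
    X = np.stack([peak_normalize(c.samples) for c in fixed]).astype(np.float32)
    y = np.array([int(c.label) for c in fixed], dtype=np.int64)
    prov = [f"{i}:{c.source}#{c.cycle_index}" for i, c in enumerate(fixed)]
    return DatasetMatrix(X, y, prov)


def load_directory(root: str | Path, cfg: PreprocessConfig) -> DatasetMatrix:
    """Run the full ingestion pipeline over an ICBHI-layout directory."""
    clips: list[CycleClip] = []
    dropped = 0
    for wav_path, txt_path in paired_recordings(root):
        x, rate = read_wav(wav_path)
        x = resample(x, rate, cfg.target_rate)
        anns = read_annotation(txt_path)
        for clip in extract_cycles(x, cfg.target_rate, anns, source=wav_path.stem):
            if cfg.screening_enabled and clip.label != Label.NORMAL:
                ok, scores = validity_screen(clip, cfg)
                if not ok:
                    dropped += 1
                    logger.info(
                        "discarded %s#%d (%s): evidence scores %s below threshold",
                        clip.source, clip.cycle_index, clip.label.name.lower(), scores,
                    )
                    continue
            clips.append(clip)
    if dropped:
        logger.info("validity screening discarded %d clips", dropped)
    return clips_to_matrix(clips, cfg)


def split_train_test(
    data: DatasetMatrix, cfg: PreprocessConfig
) -> tuple[DatasetMatrix, DatasetMatrix]:
    """Seeded stratified split into train (``split_fraction``) and test.

    Per class, ``round(fraction * n_c)`` shuffled rows go to train; the split
    is a disjoint partition and preserves class proportions within one sample.
    """
    rng = np.random.default_rng(cfg.seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lbl in Label:
        idx = np.flatnonzero(data.y == int(lbl))
        if len(idx) == 0:
            continue
        if len(idx) < 2:
            raise ValueError(f"class {lbl.name.lower()} has < 2 samples; cannot split")
        perm = rng.permutation(idx)
        n_train = int(round(cfg.split_fraction * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)  # both sides non-empty
        train_idx.extend(perm[:n_train])
        test_idx.extend(perm[n_train:])
    return data.subset(np.array(sorted(train_idx))), data.subset(np.array(sorted(test_idx)))
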