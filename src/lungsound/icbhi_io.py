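"""Readers for ICBHI-layout respiratory-sound directories.

A dataset root holds per-recording WAV files plus a same-stem annotation TXT
with one row per respiratory cycle: ``start_s  end_s  crackle  wheeze``.
Recording stems follow the five-field convention
``patientID_recordingIndex_chestLocation_acquisitionMode_equipment``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from lungsound.labels import CLASS_NAMES, Label, label_of

logger = logging.getLogger(__name__)


class AnnotationError(ValueError):
    """Malformed annotation file or filename."""


@dataclass(frozen=True)
class RecordingMeta:
    """Metadata parsed from an ICBHI recording filename."""

    patient_id: str
    recording_index: str
    chest_location: str
    acquisition_mode: str
    equipment: str
    source_path: Path | None = None
    sample_rate: int | None = None

    @property
    def stem(self) -> str:
        return "_".join(
            (
                self.patient_id,
                self.recording_index,
                self.chest_location,
                self.acquisition_mode,
                self.equipment,
            )
        )


@dataclass(frozen=True)
class CycleAnnotation:
    """One annotated respiratory cycle: time span and adventitious-sound flags."""

    start_s: float
    end_s: float
    crackle: bool
    wheeze: bool

    def __post_init__(self) -> None:
        if not 0 <= self.start_s < self.end_s:
            raise AnnotationError(
                f"cycle must satisfy 0 <= start < end, got ({self.start_s}, {self.end_s})"
            )

    @property
    def label(self) -> Label:
        return label_of(self.crackle, self.wheeze)


@dataclass(frozen=True)
class Census:
    """Dataset composition summary: recording/cycle counts and durations."""

    n_recordings: int
    n_cycles: int
    per_class: dict[str, int]
    duration_min_s: float
    duration_mean_s: float
    duration_max_s: float

    def __post_init__(self) -> None:
        assert sum(self.per_class.values()) == self.n_cycles

    def as_dict(self) -> dict:
        return {
            "n_recordings": self.n_recordings,
            "n_cycles": self.n_cycles,
            **{f"n_{k}": v for k, v in self.per_class.items()},
            "duration_min_s": self.duration_min_s,
            "duration_mean_s": self.duration_mean_s,
            "duration_max_s": self.duration_max_s,
        }


def parse_filename(name: str | Path) -> RecordingMeta:
    """Parse a five-field ICBHI stem like ``101_1b1_Al_sc_Meditron``.

    ``format(meta.stem)`` is the exact inverse for any valid stem.
    """
    path = Path(name)
    stem = path.stem if path.suffix else path.name
    fields = stem.split("_")
    if len(fields) != 5:
        raise AnnotationError(
            f"cannot parse {stem!r}: expected 5 underscore-separated fields, got {len(fields)}"
        )
    return RecordingMeta(*fields, source_path=path if path.suffix else None)


def read_annotation(path: str | Path) -> list[CycleAnnotation]:
    """Read a whitespace-delimited annotation TXT, one cycle per row."""
    out: list[CycleAnnotation] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) != 4:
            raise AnnotationError(f"{path}:{lineno}: expected 4 columns, got {len(parts)}")
        try:
            start, end = float(parts[0]), float(parts[1])
            crackle, wheeze = int(parts[2]), int(parts[3])
        except ValueError as exc:
            raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
        if crackle not in (0, 1) or wheeze not in (0, 1):
            raise AnnotationError(f"{path}:{lineno}: flags must be 0/1")
        try:
            out.append(CycleAnnotation(start, end, bool(crackle), bool(wheeze)))
        except AnnotationError as exc:
            raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
    return out


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a PCM WAV as a mono float waveform in [-1, 1] plus its rate.

    Integer encodings are scaled by their full-scale value; multi-channel
    audio is averaged to mono.
    """
    try:
        rate, data = wavfile.read(path)
    except Exception as exc:
        raise AnnotationError(f"cannot read WAV {path}: {exc}") from exc
    if data.dtype == np.int16:
        x = data / 32768.0
    elif data.dtype == np.int32:
        x = data / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(np.float64) - 128.0) / 128.0
    else:
        x = data.astype(np.float64)
    if x.ndim > 1:
        x = x.mean(axis=1)
    return np.clip(x, -1.0, 1.0), int(rate)


def paired_recordings(root: str | Path) -> list[tuple[Path, Path]]:
    """All (wav, txt) same-stem pairs under root; unpaired files are skipped
    with a warning rather than aborting, so partial downloads still load."""
    root = Path(root)
    wavs = {p.stem: p for p in sorted(root.glob("*.wav"))}
    txts = {p.stem: p for p in sorted(root.glob("*.txt"))}
    pairs = []
    for stem in sorted(set(wavs) | set(txts)):
        if stem in wavs and stem in txts:
            pairs.append((wavs[stem], txts[stem]))
        else:
            kind = "annotation" if stem in wavs else "audio"
            logger.warning("skipping %s: missing %s file", stem, kind)
    return pairs


def census(root: str | Path) -> Census:
    """Count recordings, cycles and per-class cycles under an ICBHI root.

    Duration statistics are over annotated cycle lengths (end - start).
    """
    per_class = {name: 0 for name in CLASS_NAMES}
    durations: list[float] = []
    pairs = paired_recordings(root)
    for _wav, txt in pairs:
        for ann in read_annotation(txt):
            per_class[ann.label.name.lower()] += 1
            durations.append(ann.end_s - ann.start_s)
    n_cycles = len(durations)
    return Census(
        n_recordings=len(pairs),
        n_cycles=n_cycles,
        per_class=per_class,
        duration_min_s=min(durations) if durations else 0.0,
        duration_mean_s=float(np.mean(durations)) if durations else 0.0,
        duration_max_s=max(durations) if durations else 0.0,
    )
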