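"""Seedable generator of annotated synthetic respiratory-cycle audio.

Emulates the four classes of lung sound used throughout the package:

* **normal** — band-limited breath noise shaped by a raised-cosine
  inspiration/expiration envelope ("smooth periodic breath noise");
* **crackle** — normal breathing plus brief (5–15 ms) exponentially damped
  sinusoid bursts at random positions, the standard transient model of
  discontinuous adventitious sounds;
* **wheeze** — normal breathing plus a sustained amplitude-modulated tone
  (150–900 Hz, small vibrato, one or two harmonics) occupying at least 30 %
  of the cycle — a narrowband spectrogram ridge;
* **both** — superposition of the crackle and wheeze events.

The generator writes ICBHI-layout fixtures (WAV + same-stem annotation TXT)
so the ingestion, preprocessing, balancing and training stages can all be
exercised without downloading the real database.  Identical configuration and
seed give bit-identical output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

from lungsound.labels import CLASS_NAMES, Label, flags_of

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CrackleParams:
    """Transient-burst model: counts, widths and band of the damped sinusoids."""

    bursts_per_cycle: tuple[int, int] = (5, 14)
    burst_duration_ms: tuple[float, float] = (5.0, 15.0)
    center_freq_hz: tuple[float, float] = (200.0, 1800.0)
    damping: float = 5.0  # e-folds over one burst duration
    amplitude: tuple[float, float] = (1.2, 2.2)  # relative to breath-noise peak


@dataclass(frozen=True)
class WheezeParams:
    """Sustained-tone model: band, minimum duty cycle, harmonics, vibrato."""

    tone_freq_hz: tuple[float, float] = (150.0, 900.0)
    tone_fraction: tuple[float, float] = (0.4, 0.8)  # of the cycle, >= 0.3
    harmonics: int = 2
    fm_depth: float = 0.02  # fractional frequency deviation
    amplitude: tuple[float, float] = (0.5, 0.9)  # relative to breath-noise peak


@dataclass(frozen=True)
class SynthConfig:
    """Class-conditional signal parameters and the master seed.

    All frequency parameters must sit below the Nyquist frequency, and
    crackle centre frequencies below 2 kHz — the band that carries the
    clinically relevant signal and motivates the 4 kHz pipeline rate.
    """

    sample_rate: int = 4000
    cycle_duration_s: tuple[float, float] = (1.0, 4.0)
    n_per_class: int | tuple[int, int, int, int] = 10
    noise_floor_db: float = -40.0  # background level relative to breath peak
    breath_bandwidth_hz: float = 500.0  # low-pass corner of breath noise
    crackle_params: CrackleParams = field(default_factory=CrackleParams)
    wheeze_params: WheezeParams = field(default_factory=WheezeParams)
    breath_envelope: tuple[float, float] = (0.45, 0.55)  # insp/exp fractions
    cycles_per_recording: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        nyq = self.sample_rate / 2
        if self.crackle_params.center_freq_hz[1] >= min(nyq, 2000.0):
            raise ValueError("crackle centre frequencies must stay below 2 kHz and Nyquist")
        if self.wheeze_params.tone_freq_hz[1] * self.wheeze_params.harmonics >= nyq:
            raise ValueError("wheeze harmonics must stay below Nyquist")
        if self.cycle_duration_s[0] <= 0 or self.cycle_duration_s[0] > self.cycle_duration_s[1]:
            raise ValueError("cycle_duration_s must be a positive (min, max) pair")
        if self.wheeze_params.tone_fraction[0] < 0.3:
            raise ValueError("wheeze tone must occupy at least 0.3 of the cycle")
        if abs(sum(self.breath_envelope) - 1.0) > 1e-9:
            raise ValueError("breath envelope fractions must sum to 1")

    @property
    def counts(self) -> tuple[int, int, int, int]:
        if isinstance(self.n_per_class, int):
            return (self.n_per_class,) * 4
        return tuple(self.n_per_class)  # type: ignore[return-value]


@dataclass
class SynthClip:
    """One generated cycle: waveform, class, and the parameters that made it."""

    samples: np.ndarray
    rate: int
    label: Label
    duration_s: float


def _breath_envelope(n: int, insp_frac: float) -> np.ndarray:
    """Raised-cosine inspiration then expiration humps over n samples."""
    n_insp = max(int(round(n * insp_frac)), 1)
    n_exp = max(n - n_insp, 1)
    insp = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_insp) / n_insp))
    exp_ = 0.5 * (1 - np.cos(2 * np.pi * np.arange(n_exp) / n_exp))
    env = np.concatenate([insp, 0.8 * exp_])[:n]
    return 0.1 + 0.9 * env  # keep a little airflow noise between phases


def _breath_noise(n: int, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Low-passed Gaussian noise under the inspiration/expiration envelope."""
    white = rng.standard_normal(n + 256)
    sos = signal.butter(4, cfg.breath_bandwidth_hz, fs=cfg.sample_rate, output="sos")
    breath = signal.sosfilt(sos, white)[256:]  # discard filter transient
    breath /= max(np.abs(breath).max(), 1e-12)
    return breath * _breath_envelope(n, cfg.breath_envelope[0])


def _crackle_events(n: int, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    p = cfg.crackle_params
    out = np.zeros(n)
    n_bursts = int(rng.integers(p.bursts_per_cycle[0], p.bursts_per_cycle[1] + 1))
    fs = cfg.sample_rate
    for _ in range(n_bursts):
        dur = rng.uniform(*p.burst_duration_ms) / 1000.0
        width = max(int(round(dur * fs)), 4)
        f0 = rng.uniform(*p.center_freq_hz)
        amp = rng.uniform(*p.amplitude)
        t = np.arange(width) / fs
        burst = amp * np.exp(-p.damping * t / dur) * np.sin(2 * np.pi * f0 * t)
        start = int(rng.integers(0, max(n - width, 1)))
        out[start : start + width] += burst[: n - start]
    return out


def _wheeze_tone(n: int, cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    p = cfg.wheeze_params
    fs = cfg.sample_rate
    frac = rng.uniform(*p.tone_fraction)
    width = max(int(round(n * frac)), 8)
    start = int(rng.integers(0, n - width + 1))
    f0 = rng.uniform(*p.tone_freq_hz)
    amp = rng.uniform(*p.amplitude)
    t = np.arange(width) / fs
    # slow vibrato around f0; phase = integral of instantaneous frequency
    fm = 1.0 + p.fm_depth * np.sin(2 * np.pi * rng.uniform(2.0, 6.0) * t)
    phase = 2 * np.pi * np.cumsum(f0 * fm) / fs
    tone = np.sin(phase)
    for h in range(2, p.harmonics + 1):
        tone += (0.3 / h) * np.sin(h * phase)
    window = np.hanning(width) ** 0.5  # gentle on/off ramps
    out = np.zeros(n)
    out[start : start + width] = amp * tone * window
    return out


def synth_cycle(label: Label | str, cfg: SynthConfig, rng: np.random.Generator) -> SynthClip:
    """Generate one labelled respiratory-cycle waveform.

    The waveform is mono at ``cfg.sample_rate``, peak-normalized into
    [-1, 1], with duration drawn uniformly from ``cfg.cycle_duration_s``.
    Crackle clips contain at least one damped transient (unless the burst
    count range is forced to zero, in which case the clip degenerates to
    normal-class statistics — the zero-event boundary is allowed and simply
    produces an event-free cycle); wheeze clips contain a sustained tone;
    ``both`` superposes the two; normal clips contain neither.
    """
    if isinstance(label, str):
        try:
            label = Label[label.upper()]
        except KeyError:
            raise ValueError(f"unknown class label {label!r}; expected one of {CLASS_NAMES}")
    label = Label(label)

    duration = rng.uniform(*cfg.cycle_duration_s)
    n = int(round(duration * cfg.sample_rate))
    x = _breath_noise(n, cfg, rng)
    if label in (Label.CRACKLE, Label.BOTH):
        x = x + _crackle_events(n, cfg, rng)
    if label in (Label.WHEEZE, Label.BOTH):
        x = x + _wheeze_tone(n, cfg, rng)
    x = x + 10 ** (cfg.noise_floor_db / 20) * rng.standard_normal(n)
    x = 0.95 * x / max(np.abs(x).max(), 1e-12)
    return SynthClip(samples=x.astype(np.float64), rate=cfg.sample_rate, label=label, duration_s=duration)


def synth_dataset(cfg: SynthConfig) -> list[SynthClip]:
    """Generate ``cfg.counts`` clips per class, deterministically under seed.

    Clips are generated class-by-class in label order from a single seeded
    stream, so the same config always yields byte-identical waveforms.
    """
    counts = cfg.counts
    if min(counts) < 0 or max(counts) < 1:
        raise ValueError("n_per_class must request at least one clip")
    rng = np.random.default_rng(cfg.seed)
    clips: list[SynthClip] = []
    for label, n in zip(Label, counts):
        for _ in range(n):
            clips.append(synth_cycle(label, cfg, rng))
    return clips


def _icbhi_stem(patient: int, rec_index: int) -> str:
    # patientID_recordingIndex_chestLocation_acquisitionMode_equipment
    return f"{patient:03d}_{rec_index}b1_Al_sc_Synth"


def write_icbhi_fixture(
    clips: list[SynthClip],
    out_dir: str | Path,
    cycles_per_recording: int = 1,
) -> pd.DataFrame:
    """Write clips as ICBHI-layout WAV + annotation TXT pairs.

    Each recording concatenates ``cycles_per_recording`` consecutive clips
    (default one) and gets a same-stem TXT whose rows are
    ``start_s  end_s  crackle_flag  wheeze_flag``.  Returns a manifest frame
    with one row per written recording.  Labels and sample counts round-trip
    exactly through :mod:`lungsound.icbhi_io`.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, start in enumerate(range(0, len(clips), cycles_per_recording)):
        group = clips[start : start + cycles_per_recording]
        stem = _icbhi_stem(100 + rec, 1)
        rate = group[0].rate
        wave = np.concatenate([c.samples for c in group])
        pcm = np.clip(wave, -1.0, 1.0)
        wavfile.write(out / f"{stem}.wav", rate, (pcm * 32767.0).astype(np.int16))
        t = 0.0
        ann_lines = []
        for c in group:
            end = t + len(c.samples) / rate
            cr, wh = flags_of(c.label)
            ann_lines.append(f"{t:.4f}\t{end:.4f}\t{cr}\t{wh}")
            t = end
        (out / f"{stem}.txt").write_text("\n".join(ann_lines) + ("\n" if ann_lines else ""))
        rows.append(
            {
                "stem": stem,
                "wav": str(out / f"{stem}.wav"),
                "txt": str(out / f"{stem}.txt"),
                "n_cycles": len(group),
                "labels": ";".join(c.label.name.lower() for c in group),
            }
        )
    manifest = pd.DataFrame(rows, columns=["stem", "wav", "txt", "n_cycles", "labels"])
    logger.info("wrote %d recordings to %s", len(manifest), out)
    return manifest


# --- fixture QC: a deliberately trivial band-energy / transient classifier ---

def tonality_score(samples: np.ndarray, rate: int, band: tuple[float, float] = (120.0, 1000.0)) -> float:
    """Spectral peak-to-median power ratio inside the wheeze band (Welch PSD).

    Sustained narrowband tones produce a sharp ridge, hence a large ratio;
    breath noise and transients spread power and score low.
    """
    nper = min(1024, len(samples))
    f, pxx = signal.welch(samples, fs=rate, nperseg=nper)
    inband = pxx[(f >= band[0]) & (f <= band[1])]
    return float(inband.max() / max(np.median(inband), 1e-20))


def transient_score(
    samples: np.ndarray, rate: int, window_ms: float = 25.0, highpass_hz: float = 1200.0
) -> float:
    """Maximum excess kurtosis over short windows — high for crackle bursts.

    The signal is high-passed first so breath noise and any sustained wheeze
    tone (fundamentals below ~900 Hz) do not dilute the transient statistic;
    crackle bursts are broadband and survive the filter.
    """
    from scipy.stats import kurtosis

    if highpass_hz and highpass_hz < rate / 2:
        sos = signal.butter(4, highpass_hz, btype="high", fs=rate, output="sos")
        samples = signal.sosfilt(sos, samples)
    width = max(int(round(window_ms * rate / 1000.0)), 8)
    n_win = len(samples) // width
    if n_win == 0:
        return float(kurtosis(samples))
    blocks = samples[: n_win * width].reshape(n_win, width)
    return float(kurtosis(blocks, axis=1).max())


# Operating points chosen once on generator output while designing the
# acoustic models; they sit in the wide gap between the class distributions
# (tonality: event-free clips < ~15, wheezes > ~45; transient kurtosis:
# burst-free clips < ~5, crackles > ~13).
TONALITY_THRESHOLD = 30.0
TRANSIENT_THRESHOLD = 8.0


def heuristic_label(samples: np.ndarray, rate: int) -> Label:
    """Threshold classifier used to certify that the fixtures are learnable."""
    wheezy = tonality_score(samples, rate) >= TONALITY_THRESHOLD
    crackly = transient_score(samples, rate) >= TRANSIENT_THRESHOLD
    from lungsound.labels import label_of

    return label_of(crackly, wheezy)
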