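import numpy as np
import pytest

from lungsound.labels import Label
from lungsound.preprocess import CycleClip, DatasetMatrix, PreprocessConfig, clips_to_matrix
from lungsound.synth import SynthConfig, synth_cycle, synth_dataset


@pytest.fixture(scope="session")
def synth_cfg() -> SynthConfig:
    return SynthConfig(n_per_class=5, seed=7)


@pytest.fixture(scope="session")
def small_clips(synth_cfg):
    """20 synthetic cycles, 5 per class, deterministic."""
    return synth_dataset(synth_cfg)


@pytest.fixture(scope="session")
def matched_pair():
    """A normal and a wheeze clip drawn from identically seeded streams."""
    cfg = SynthConfig(seed=1)
    normal = synth_cycle(Label.NORMAL, cfg, np.random.default_rng(1))
    wheeze = synth_cycle(Label.WHEEZE, cfg, np.random.default_rng(1))
    return normal, wheeze


@pytest.fixture(scope="session")
def preprocess_cfg() -> PreprocessConfig:
    return PreprocessConfig(seed=0)


@pytest.fixture(scope="session")
def small_matrix(small_clips, preprocess_cfg) -> DatasetMatrix:
    clips = [CycleClip(c.samples, c.rate, c.label) for c in small_clips]
    return clips_to_matrix(clips, preprocess_cfg)


@pytest.fixture(scope="session")
def imbalanced_matrix() -> DatasetMatrix:
    """Low-dimensional imbalanced training matrix for oversampling tests."""
    rng = np.random.default_rng(3)
    counts = {0: 100, 1: 50, 2: 25, 3: 10}
    X, y = [], []
    for lbl, n in counts.items():
        X.append(rng.normal(loc=lbl * 2.0, size=(n, 12)))
        y.extend([lbl] * n)
    return DatasetMatrix(np.vstack(X), np.array(y))


@pytest.fixture()
def icbhi_dir(tmp_path, small_clips):
    """On-disk ICBHI-layout fixture written from the synthetic clips."""
    from lungsound.synth import write_icbhi_fixture

    manifest = write_icbhi_fixture(small_clips, tmp_path / "icbhi")
    return tmp_path / "icbhi", manifest
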