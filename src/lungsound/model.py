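"""Model/Results interface for the raw-waveform respiratory-sound classifier.

:class:`LungSoundCNN` pairs an architecture description with training data;
``fit()`` runs seeded mini-batch training and returns a :class:`CNNResults`
carrying the fitted weights, per-epoch history, prediction/evaluation methods
and a layer-table ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lungsound import nn
from lungsound.arch import ArchSpec, default_arch, summarize
from lungsound.evaluate import EvalReport, evaluate_predictions
from lungsound.labels import N_CLASSES
from lungsound.preprocess import DatasetMatrix


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings.

    Defaults: Adam at learning rate 1e-3 (the middle of the tuning grid's
    {1e-4, 1e-3, 1e-2}), batch 32, cross-entropy loss.  Focal loss with
    ``focal_gamma`` is available as the alternative imbalance treatment.
    """

    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "categorical_crossentropy"
    focal_gamma: float = 2.0
    lr_decay: float = 1.0  # optional step-decay factor applied at lr_decay_at
    lr_decay_at: tuple[float, ...] = (0.5, 0.8)  # fractions of total epochs
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training configuration")
        if self.loss not in ("categorical_crossentropy", "focal"):
            raise ValueError(f"unknown loss {self.loss!r}")
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def one_hot(y: np.ndarray, n_classes: int = N_CLASSES) -> np.ndarray:
    out = np.zeros((len(y), n_classes), dtype=np.float32)
    out[np.arange(len(y)), y] = 1.0
    return out


def build(arch: ArchSpec, cfg: TrainConfig) -> nn.Network:
    """Instantiate a trainable network from an architecture description.

    The returned network's ``param_count`` (summed sizes of allocated weight
    arrays) equals ``summarize(arch).total_params`` computed arithmetically —
    the two counts are independent and cross-checked in the test suite.
    """
    return nn.Network(arch, np.random.default_rng(cfg.seed))


class LungSoundCNN:
    """A 1D-CNN classifier bound to a training (and optional validation) set.

    Parameters
    ----------
    train : DatasetMatrix
        Fixed-length waveform rows with integer class labels.
    val : DatasetMatrix, optional
        Held-out data scored once per epoch.
    arch : ArchSpec, optional
        Defaults to the reference four-block architecture.
    config : TrainConfig, optional
    """

    def __init__(
        self,
        train: DatasetMatrix,
        val: DatasetMatrix | None = None,
        arch: ArchSpec | None = None,
        config: TrainConfig = TrainConfig(),
    ):
        self.train_data = train
        self.val_data = val
        self.arch = arch if arch is not None else default_arch(input_len=train.X.shape[1])
        if self.arch.input_len != train.X.shape[1]:
            raise ValueError(
                f"architecture expects {self.arch.input_len} samples, data has {train.X.shape[1]}"
            )
        self.config = config
        self.n_classes = self.arch.layers[-1].units

    @classmethod
    def from_dataset(cls, data: DatasetMatrix, **kwargs) -> "LungSoundCNN":
        return cls(data, **kwargs)

    def fit(self, verbose: bool = False) -> "CNNResults":
        """Seeded mini-batch training; returns the fitted results object.

        Records per-epoch training loss/accuracy and, when a validation set is
        bound, validation loss/accuracy.  Aborts with a diagnostic if the loss
        turns non-finite.
        """
        cfg = self.config
        net = build(self.arch, cfg)
        rng = np.random.default_rng(cfg.seed + 1)  # shuffling stream
        if cfg.optimizer == "adam":
            opt: nn.Adam | nn.SGD = nn.Adam(net.trainable_params, cfg.learning_rate)
        else:
            opt = nn.SGD(net.trainable_params, cfg.learning_rate)

        X = self.train_data.X.astype(np.float32)
        Y = one_hot(self.train_data.y, self.n_classes)
        history: dict[str, list[float]] = {
            "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
        }
        gamma = cfg.focal_gamma if cfg.loss == "focal" else 0.0
        loss_fn = (
            (lambda p, t: nn.focal_loss(p, t, cfg.focal_gamma))
            if cfg.loss == "focal"
            else nn.cross_entropy
        )

        decay_epochs = {int(f * cfg.epochs) for f in cfg.lr_decay_at}
        for epoch in range(cfg.epochs):
            if epoch in decay_epochs:
                opt.lr *= cfg.lr_decay
            order = rng.permutation(len(X))
            ep_loss, ep_correct = 0.0, 0
            for start in range(0, len(X), cfg.batch_size):
                sel = order[start : start + cfg.batch_size]
                probs = net.forward(X[sel], train=True)
                batch_loss = loss_fn(probs, Y[sel])
                if not np.isfinite(batch_loss):
                    raise FloatingPointError(
                        f"non-finite loss at epoch {epoch}: lower the learning rate"
                    )
                grads = net.backward(probs, Y[sel], cfg.loss, gamma)
                opt.step(grads)
                ep_loss += batch_loss * len(sel)
                ep_correct += int((probs.argmax(axis=1) == self.train_data.y[sel]).sum())
            history["loss"].append(ep_loss / len(X))
            history["accuracy"].append(ep_correct / len(X))
            if self.val_data is not None:
                vp = _predict_proba(net, self.val_data.X)
                history["val_loss"].append(loss_fn(vp, one_hot(self.val_data.y, self.n_classes)))
                history["val_accuracy"].append(
                    float((vp.argmax(axis=1) == self.val_data.y).mean())
                )
            if verbose:
                msg = f"epoch {epoch + 1}/{cfg.epochs} loss={history['loss'][-1]:.4f} acc={history['accuracy'][-1]:.3f}"
                if self.val_data is not None:
                    msg += f" val_acc={history['val_accuracy'][-1]:.3f}"
                print(msg)
        return CNNResults(self, net, history)


def _predict_proba(
    net: nn.Network,
    X: np.ndarray,
    batch: int = 64,
    mc_samples: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Class probabilities for a waveform batch.

    With ``mc_samples`` > 0, predictions are Monte-Carlo dropout averages:
    the mean softmax over that many stochastic forward passes with dropout
    active, from a seeded stream.  This evaluates the network in the same
    regime it was trained in; a single deterministic dropout-free pass is
    systematically biased through the max-pool/ReLU nonlinearities and
    over-reports transient evidence.  ``mc_samples=0`` gives the plain
    dropout-free pass.
    """
    if mc_samples <= 0:
        out = [net.forward(X[i : i + batch].astype(np.float32)) for i in range(0, len(X), batch)]
        return np.vstack(out)
    net.reseed_dropout(np.random.default_rng(seed))
    acc = np.zeros((len(X), net.forward(X[:1].astype(np.float32)).shape[1]), dtype=np.float64)
    for _ in range(mc_samples):
        for i in range(0, len(X), batch):
            acc[i : i + batch] += net.forward(X[i : i + batch].astype(np.float32), train=True)
    return acc / mc_samples


class CNNResults:
    """Fitted classifier: weights, training history, evaluation, summary."""

    def __init__(self, model: LungSoundCNN, network: nn.Network, history: dict[str, list[float]]):
        self.model = model
        self.network = network
        self.history = history

    @property
    def param_count(self) -> int:
        return self.network.param_count

    #: stochastic forward passes averaged per prediction (MC dropout); the
    #: trained network is evaluated in its training regime.  0 disables.
    mc_samples: int = 10

    def predict_proba(self, X: np.ndarray, mc_samples: int | None = None) -> np.ndarray:
        """(N, L) waveforms -> (N, n_classes) class probabilities.

        Deterministic: the Monte-Carlo dropout averaging draws its masks from
        a stream seeded by the model's training seed.
        """
        mc = self.mc_samples if mc_samples is None else mc_samples
        return _predict_proba(
            self.network, np.asarray(X), mc_samples=mc, seed=self.model.config.seed + 2
        )

    def predict(self, X: np.ndarray, mc_samples: int | None = None) -> np.ndarray:
        return self.predict_proba(X, mc_samples=mc_samples).argmax(axis=1)

    def evaluate(self, test: DatasetMatrix) -> EvalReport:
        """Score on held-out data: confusion matrix plus per-class and macro metrics."""
        return evaluate_predictions(test.y, self.predict(test.X))

    def summary(self) -> str:
        """Layer table (output shapes and parameter counts) plus fit stats."""
        s = summarize(self.model.arch)
        lines = [s.as_text(), ""]
        if self.history["loss"]:
            lines.append(
                f"trained {len(self.history['loss'])} epochs; "
                f"final train acc {self.history['accuracy'][-1]:.3f}"
            )
            if self.history["val_accuracy"]:
                lines.append(f"final validation acc {self.history['val_accuracy'][-1]:.3f}")
        else:
            lines.append("untrained model (0 epochs)")
        return "\n".join(lines)

    def save_weights(self, path) -> None:
        np.savez(path, *self.network.get_weights())

    def load_weights(self, path) -> None:
        with np.load(path) as data:
            self.network.set_weights([data[k] for k in data.files])
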