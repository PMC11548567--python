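"""Grid-search hyperparameter tuning with stratified k-fold cross-validation.

The search exhaustively enumerates the Cartesian product of the grid, scores
every configuration by mean validation accuracy over stratified folds, and is
leakage-safe: class balancing (SMOTE) is re-run inside each fold on that
fold's training split only, and held-out rows are never touched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from lungsound.arch import ArchSpec, scaled_arch, summarize
from lungsound.evaluate import EvalReport
from lungsound.labels import Label
from lungsound.model import LungSoundCNN, TrainConfig
from lungsound.preprocess import DatasetMatrix
from lungsound.smote import SmoteConfig, smote_balance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GridSpec:
    """Hyperparameter grid.

    Defaults are the reference tuning grid: first-layer filter count and
    kernel width, dropout rate, first-dense-layer units, learning rate —
    3^5 = 243 configurations.
    """

    n_filters: tuple[int, ...] = (32, 64, 128)
    kernel_size: tuple[int, ...] = (3, 5, 7)
    dropout_rate: tuple[float, ...] = (0.2, 0.3, 0.4)
    num_units: tuple[int, ...] = (64, 128, 256)
    learning_rate: tuple[float, ...] = (1e-4, 1e-3, 1e-2)

    def __post_init__(self) -> None:
        for name in ("n_filters", "kernel_size", "dropout_rate", "num_units", "learning_rate"):
            if len(getattr(self, name)) == 0:
                raise ValueError(f"{name} must be non-empty")

    def combinations(self) -> list[dict]:
        return [
            {
                "n_filters": f,
                "kernel_size": k,
                "dropout_rate": d,
                "num_units": u,
                "learning_rate": lr,
            }
            for f, k, d, u, lr in product(
                self.n_filters, self.kernel_size, self.dropout_rate, self.num_units, self.learning_rate
            )
        ]


@dataclass
class CvResult:
    """k-fold cross-validation outcome: per-fold reports and aggregates."""

    k: int
    fold_reports: list[EvalReport]
    mean: dict[str, float] = field(default_factory=dict)
    std: dict[str, float] = field(default_factory=dict)

    METRICS = ("accuracy", "sensitivity", "specificity", "precision", "f1")

    def __post_init__(self) -> None:
        if len(self.fold_reports) != self.k:
            raise ValueError("need one report per fold")
        vals = {
            "accuracy": [r.accuracy for r in self.fold_reports],
            "sensitivity": [r.macro_sensitivity for r in self.fold_reports],
            "specificity": [r.macro_specificity for r in self.fold_reports],
            "precision": [r.macro_precision for r in self.fold_reports],
            "f1": [r.macro_f1 for r in self.fold_reports],
        }
        self.mean = {m: float(np.mean(v)) for m, v in vals.items()}
        self.std = {m: float(np.std(v, ddof=1)) if self.k > 1 else 0.0 for m, v in vals.items()}

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"metric": list(self.METRICS),
             "mean": [self.mean[m] for m in self.METRICS],
             "std": [self.std[m] for m in self.METRICS]}
        )


def kfold_split(labels: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """Stratified fold index sets: a seeded disjoint partition of all indices
    with per-class counts differing by at most one across folds."""
    labels = np.asarray(labels)
    for lbl in np.unique(labels):
        if (labels == lbl).sum() < k:
            raise ValueError(
                f"class {Label(int(lbl)).name.lower()} has fewer than k={k} members"
            )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test_idx for _, test_idx in skf.split(np.zeros(len(labels)), labels)]


def crossval(
    data: DatasetMatrix,
    arch: ArchSpec,
    cfg: TrainConfig,
    k: int = 5,
    smote: SmoteConfig | None = SmoteConfig(),
    seed: int = 0,
) -> CvResult:
    """Stratified k-fold cross-validation of one architecture.

    Each fold: balance the training split (SMOTE, if enabled), fit from
    scratch, evaluate on the held-out fold.
    """
    folds = kfold_split(data.y, k, seed)
    reports: list[EvalReport] = []
    all_idx = np.arange(len(data))
    for fi, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(all_idx, test_idx)
        train = data.subset(train_idx)
        if smote is not None:
            train = smote_balance(train, smote)
        model = LungSoundCNN(train, arch=arch, config=cfg)
        result = model.fit()
        reports.append(result.evaluate(data.subset(test_idx)))
        logger.info("fold %d/%d accuracy %.3f", fi + 1, k, reports[-1].accuracy)
    return CvResult(k=k, fold_reports=reports)


def grid_search(
    grid: GridSpec,
    data: DatasetMatrix,
    k: int = 5,
    cfg: TrainConfig = TrainConfig(),
    smote: SmoteConfig | None = SmoteConfig(),
    seed: int = 0,
    input_len: int | None = None,
    n_conv_blocks: int = 4,
) -> tuple[pd.DataFrame, dict]:
    """Exhaustive search over the grid, scored by mean k-fold validation accuracy.

    Returns the ranked trace (one row per configuration with per-fold scores)
    and the best configuration.  Ranking ties break toward fewer parameters,
    then grid order.  Configurations whose architecture collapses (kernel
    longer than the pooled sequence) are skipped and logged, not fatal.
    """
    input_len = input_len if input_len is not None else data.X.shape[1]
    rows = []
    for order, combo in enumerate(grid.combinations()):
        try:
            arch = scaled_arch(
                base_filters=combo["n_filters"],
                base_kernel=combo["kernel_size"],
                dropout_rate=combo["dropout_rate"],
                base_units=combo["num_units"],
                input_len=input_len,
                n_conv_blocks=n_conv_blocks,
            )
            n_params = summarize(arch).total_params
        except ValueError as exc:
            logger.warning("skipping infeasible configuration %s: %s", combo, exc)
            continue
        run_cfg = TrainConfig(
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            learning_rate=combo["learning_rate"],
            optimizer=cfg.optimizer,
            loss=cfg.loss,
            focal_gamma=cfg.focal_gamma,
            seed=cfg.seed,
        )
        try:
            cv = crossval(data, arch, run_cfg, k=k, smote=smote, seed=seed)
        except FloatingPointError as exc:
            logger.warning("configuration %s diverged: %s", combo, exc)
            continue
        rows.append(
            {
                **combo,
                "order": order,
                "n_params": n_params,
                "mean_accuracy": cv.mean["accuracy"],
                "std_accuracy": cv.std["accuracy"],
                "fold_accuracies": [r.accuracy for r in cv.fold_reports],
            }
        )
    if not rows:
        raise ValueError("no feasible configuration in the grid")
    trace = pd.DataFrame(rows).sort_values(
        ["mean_accuracy", "n_params", "order"], ascending=[False, True, True]
    ).reset_index(drop=True)
    best = trace.iloc[0][["n_filters", "kernel_size", "dropout_rate", "num_units", "learning_rate"]].to_dict()
    return trace, best
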