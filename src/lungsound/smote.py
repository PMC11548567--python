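"""From-scratch SMOTE oversampling for the training partition.

Synthetic Minority Over-sampling Technique: for a minority-class sample
``x_i``, pick one of its k nearest same-class neighbours ``x_j`` and emit

    x_new = x_i + r * (x_j - x_i),   r ~ Uniform[0, 1]

repeating until every class reaches its target count (by default the majority
count).  Every synthetic sample is therefore a convex combination of two
same-class originals.  Balancing is applied to training data only — within
cross-validation, to each fold's training split — never to held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from lungsound.labels import Label
from lungsound.preprocess import DatasetMatrix


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 5
    target_counts: dict[int, int] | None = None  # default: raise all to majority
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def knn_minority(X_class: np.ndarray, i: int, k: int) -> np.ndarray:
    """Indices of the k nearest same-class rows to row i (Euclidean).

    Row i is excluded from its own neighbour set; distance ties break toward
    the lower index (stable sort) for determinism.
    """
    X_class = np.asarray(X_class, dtype=np.float64)
    m = X_class.shape[0]
    if m < 2:
        raise ValueError("need at least 2 samples in the class to find neighbours")
    if k > m - 1:
        raise ValueError(f"k={k} exceeds available neighbours ({m - 1})")
    d = np.linalg.norm(X_class - X_class[i], axis=1)
    d[i] = np.inf
    order = np.argsort(d, kind="stable")
    return order[:k]


def smote_sample(xi: np.ndarray, xj: np.ndarray, r: float) -> np.ndarray:
    """Interpolate: xi + r * (xj - xi) with r in [0, 1].

    Each coordinate of the result lies between the corresponding coordinates
    of the two parents (r=0 gives xi, r=1 gives xj).
    """
    xi = np.asarray(xi, dtype=np.float64)
    xj = np.asarray(xj, dtype=np.float64)
    if xi.shape != xj.shape:
        raise ValueError(f"shape mismatch: {xi.shape} vs {xj.shape}")
    if not 0.0 <= r <= 1.0:
        raise ValueError("r must lie in [0, 1]")
    return xi + r * (xj - xi)


def smote_balance(train: DatasetMatrix, cfg: SmoteConfig = SmoteConfig()) -> DatasetMatrix:
    """Oversample minority classes in a training matrix up to target counts.

    Original rows are preserved verbatim and in order; synthetic rows are
    appended with provenance ``"smote:<class>"``.  Already-balanced input is
    returned unchanged (no synthetic rows).  The base sample cycles through
    the minority rows in order; the neighbour is drawn uniformly from the k
    nearest, and r uniformly from [0, 1], from a seeded stream.
    """
    counts = {int(lbl): int((train.y == int(lbl)).sum()) for lbl in Label if (train.y == int(lbl)).any()}
    if cfg.target_counts is None:
        majority = max(counts.values())
        targets = {lbl: majority for lbl in counts}
    else:
        targets = {int(l): int(c) for l, c in cfg.target_counts.items()}
    for lbl, tgt in targets.items():
        if tgt < counts.get(lbl, 0):
            raise ValueError(
                f"target count {tgt} below current count {counts.get(lbl, 0)} "
                f"for class {Label(lbl).name.lower()}"
            )
    if all(targets.get(lbl, counts[lbl]) == counts[lbl] for lbl in counts):
        return train

    rng = np.random.default_rng(cfg.seed)
    new_rows: list[np.ndarray] = []
    new_labels: list[int] = []
    new_prov: list[str] = []
    for lbl in sorted(counts):
        deficit = targets.get(lbl, counts[lbl]) - counts[lbl]
        if deficit == 0:
            continue
        idx = np.flatnonzero(train.y == lbl)
        if len(idx) < 2:
            raise ValueError(
                f"class {Label(lbl).name.lower()} has a single sample; SMOTE needs >= 2 "
                "(lower the target count or merge classes)"
            )
        Xc = train.X[idx].astype(np.float64)
        k = min(cfg.k_neighbors, len(idx) - 1)
        neighbours = {i: knn_minority(Xc, i, k) for i in range(len(idx))}
        for s in range(deficit):
            i = s % len(idx)
            j = int(rng.choice(neighbours[i]))
            r = float(rng.uniform(0.0, 1.0))
            new_rows.append(smote_sample(Xc[i], Xc[j], r))
            new_labels.append(lbl)
            new_prov.append(f"smote:{Label(lbl).name.lower()}")

    X = np.vstack([train.X, np.asarray(new_rows, dtype=train.X.dtype)])
    y = np.concatenate([train.y, np.asarray(new_labels, dtype=train.y.dtype)])
    return DatasetMatrix(X, y, list(train.provenance) + new_prov)
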