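"""Condition classification with a small from-scratch multilayer perceptron.

Feature vectors summarise each (subject, condition) observation by six
numbers: the five relative band powers and the Higuchi fractal dimension,
each averaged over the nine analysis channels — one oscillatory block and
one non-oscillatory complexity measure.

The classifier is a 6-6-2 feedforward network with hyperbolic-tangent
hidden and output units, trained by online backpropagated gradient descent
with momentum (initial learning rate 0.4 annealed exponentially to 0.001,
momentum 0.9) on sum-of-squares error
against ±1 one-hot targets, on a stratified random 70/30 train/test split.
Features are standardised using training-split statistics only.  Evaluation
reports the confusion counts, sensitivity TP/(TP+FN), specificity
TN/(TN+FP), accuracy (TP+TN)/total, and the ROC AUC of the output-unit
activation difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

__all__ = [
    "CONTRASTS",
    "FeatureDataset",
    "MLPConfig",
    "TrainedMLP",
    "ClassifierReport",
    "assemble_features",
    "train_mlp",
    "evaluate",
]

#: contrast name -> (conditions included, positive-class condition)
CONTRASTS: dict[str, tuple[tuple[str, ...], str]] = {
    "3DvsEO": (("3D", "EO"), "3D"),
    "3Dvs2D": (("3D", "2D"), "3D"),
    "2DvsEO": (("2D", "EO"), "2D"),
    "3DvsRest": (("3D", "2D", "EO"), "3D"),
}


@dataclass(frozen=True)
class FeatureDataset:
    """Observations x features with binary labels and provenance ids."""

    X: np.ndarray
    y: np.ndarray
    ids: tuple[tuple[str, str], ...]  # (subject, condition)
    feature_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.size or self.X.shape[0] != len(self.ids):
            raise ValueError("inconsistent dataset shapes")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match feature dimension")


@dataclass(frozen=True)
class MLPConfig:
    layout: tuple[int, int, int] = (6, 6, 2)
    learning_rate: float = 0.4
    lr_min: float = 0.001
    momentum: float = 0.9
    train_fraction: float = 0.70
    epochs: int = 500
    tol: float = 1e-6
    batch: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if any(v < 1 for v in self.layout):
            raise ValueError("layout sizes must be positive")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass
class TrainedMLP:
    """Weights plus the training-split scaler and split bookkeeping."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    train_idx: np.ndarray
    test_idx: np.ndarray
    dataset: FeatureDataset
    n_epochs_run: int

    def _forward(self, x: np.ndarray) -> np.ndarray:
        h = np.tanh(x @ self.w1 + self.b1)
        return np.tanh(h @ self.w2 + self.b2)

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-unit minus negative-unit activation per observation."""
        out = self._forward((X - self.scaler_mean) / self.scaler_sd)
        return out[:, 1] - out[:, 0]

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Argmax of the output units; exact ties go to the negative class."""
        return (self.decision_scores(X) > 0).astype(int)


@dataclass(frozen=True)
class ClassifierReport:
    TP: int
    TN: int
    FP: int
    FN: int
    sensitivity: float
    specificity: float
    accuracy: float
    roc_auc: float

    def as_dict(self) -> dict:
        return {
            "TP": self.TP, "TN": self.TN, "FP": self.FP, "FN": self.FN,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "accuracy": self.accuracy, "roc_auc": self.roc_auc,
        }


def assemble_features(
    power_table: pd.DataFrame, fd_table: pd.DataFrame, contrast: str = "3DvsRest"
) -> FeatureDataset:
    """Build the 6-feature dataset for one binary contrast.

    Band powers and FD are averaged over channels per (subject, condition);
    the label is 1 for the first-named condition of the contrast.  Rows are
    ordered by (subject, condition) for determinism.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; choose from {sorted(CONTRASTS)}")
    conditions, positive = CONTRASTS[contrast]
    bands = list(dict.fromkeys(power_table["band"]))
    power_avg = (
        power_table.groupby(["subject", "condition", "band"], sort=False)["value"]
        .mean()
        .unstack("band")[bands]
    )
    fd_avg = fd_table.groupby(["subject", "condition"], sort=False)["fd"].mean()
    feat = power_avg.join(fd_avg.rename("fd"), how="inner")
    if feat.isna().any().any() or len(feat) < len(power_avg):
        missing = sorted(set(power_avg.index) - set(feat.dropna().index))
        raise ValueError(f"feature tables disagree; missing entries for {missing}")
    feat = feat.loc[[idx for idx in sorted(feat.index) if idx[1] in conditions]]
    X = feat.to_numpy(dtype=float)
    y = np.array([1 if cond == positive else 0 for _, cond in feat.index], dtype=int)
    return FeatureDataset(
        X=X,
        y=y,
        ids=tuple((s, c) for s, c in feat.index),
        feature_names=tuple(bands) + ("fd",),
    )


def _stratified_split(
    y: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        n_train = int(round(train_fraction * idx.size))
        n_train = min(max(n_train, 1), idx.size - 1) if idx.size > 1 else n_train
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def train_mlp(dataset: FeatureDataset, cfg: MLPConfig | None = None) -> TrainedMLP:
    """Train the tanh MLP on a stratified 70/30 split of the dataset.

    Online (per-observation) updates by default, in a per-epoch shuffled
    order; ``cfg.batch=True`` switches to full-batch gradients.  Training
    stops early when the epoch sum-of-squares error changes by less than
    ``cfg.tol``.  Deterministic in (dataset, cfg.seed).
    """
    cfg = cfg or MLPConfig()
    if dataset.X.shape[0] < 10:
        raise ValueError("need at least 10 observations")
    if dataset.X.shape[1] != cfg.layout[0]:
        raise ValueError(
            f"dataset has {dataset.X.shape[1]} features but layout expects {cfg.layout[0]}"
        )
    rng = np.random.default_rng(cfg.seed)
    for _attempt in range(10):
        train_idx, test_idx = _stratified_split(dataset.y, cfg.train_fraction, rng)
        if np.unique(dataset.y[train_idx]).size == 2:
            break
    else:
        raise ValueError("could not draw a training split containing both classes")

    X_tr = dataset.X[train_idx]
    mean = X_tr.mean(axis=0)
    sd = X_tr.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X_tr - mean) / sd
    # targets: +1 on the true class's output unit, -1 on the other
    T = np.where(np.eye(2)[dataset.y[train_idx]] > 0, 1.0, -1.0)

    n_in, n_hidden, n_out = cfg.layout
    w1 = rng.uniform(-1, 1, (n_in, n_hidden)) / np.sqrt(n_in)
    b1 = np.zeros(n_hidden)
    w2 = rng.uniform(-1, 1, (n_hidden, n_out)) / np.sqrt(n_hidden)
    b2 = np.zeros(n_out)
    v_w1, v_b1 = np.zeros_like(w1), np.zeros_like(b1)
    v_w2, v_b2 = np.zeros_like(w2), np.zeros_like(b2)

    def grads(x: np.ndarray, t: np.ndarray):
        h = np.tanh(x @ w1 + b1)
        o = np.tanh(h @ w2 + b2)
        delta_o = (o - t) * (1 - o**2)
        delta_h = (delta_o @ w2.T) * (1 - h**2)
        if x.ndim == 1:
            return np.outer(x, delta_h), delta_h, np.outer(h, delta_o), delta_o, np.sum((o - t) ** 2)
        n = x.shape[0]
        return (
            x.T @ delta_h / n,
            delta_h.mean(axis=0),
            h.T @ delta_o / n,
            delta_o.mean(axis=0),
            np.sum((o - t) ** 2),
        )

    prev_err = np.inf
    n_epochs_run = 0
    for epoch in range(cfg.epochs):
        n_epochs_run = epoch + 1
        # exponential annealing from the initial rate down to lr_min; a
        # fixed 0.4 rate with 0.9 momentum drives tanh units into
        # saturation, freezing the error
        cfg_lr = cfg.learning_rate * (cfg.lr_min / cfg.learning_rate) ** (
            epoch / max(cfg.epochs - 1, 1)
        )
        if cfg.batch:
            g1, gb1, g2, gb2, _ = grads(Z, T)
            v_w1 = cfg.momentum * v_w1 - cfg_lr * g1
            v_b1 = cfg.momentum * v_b1 - cfg_lr * gb1
            v_w2 = cfg.momentum * v_w2 - cfg_lr * g2
            v_b2 = cfg.momentum * v_b2 - cfg_lr * gb2
            w1 += v_w1; b1 += v_b1; w2 += v_w2; b2 += v_b2
        else:
            order = rng.permutation(Z.shape[0])
            for i in order:
                g1, gb1, g2, gb2, _ = grads(Z[i], T[i])
                v_w1 = cfg.momentum * v_w1 - cfg_lr * g1
                v_b1 = cfg.momentum * v_b1 - cfg_lr * gb1
                v_w2 = cfg.momentum * v_w2 - cfg_lr * g2
                v_b2 = cfg.momentum * v_b2 - cfg_lr * gb2
                w1 += v_w1; b1 += v_b1; w2 += v_w2; b2 += v_b2
        h = np.tanh(Z @ w1 + b1)
        o = np.tanh(h @ w2 + b2)
        err = float(0.5 * np.sum((o - T) ** 2))
        if abs(prev_err - err) < cfg.tol:
            break
        prev_err = err

    return TrainedMLP(
        w1=w1, b1=b1, w2=w2, b2=b2,
        scaler_mean=mean, scaler_sd=sd,
        train_idx=train_idx, test_idx=test_idx,
        dataset=dataset, n_epochs_run=n_epochs_run,
    )


def evaluate(
    model: TrainedMLP, X: np.ndarray | None = None, y: np.ndarray | None = None
) -> ClassifierReport:
    """Confusion counts and metrics; defaults to the model's held-out split.

    If the evaluation set contains a single class, the undefined rate
    (sensitivity or specificity) and the AUC are reported as NaN.
    """
    if X is None:
        X = model.dataset.X[model.test_idx]
        y = model.dataset.y[model.test_idx]
    if y is None or len(X) == 0:
        raise ValueError("evaluation needs a nonempty labelled set")
    y = np.asarray(y, dtype=int)
    pred = model.predict(X)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    fp = int(np.sum((pred == 1) & (y == 0)))
    fn = int(np.sum((pred == 0) & (y == 1)))
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    acc = (tp + tn) / y.size
    if np.unique(y).size == 2:
        auc = float(roc_auc_score(y, model.decision_scores(X)))
    else:
        auc = float("nan")
    return ClassifierReport(
        TP=tp, TN=tn, FP=fp, FN=fn,
        sensitivity=sens, specificity=spec, accuracy=acc, roc_auc=auc,
    )


def repeated_evaluation(
    dataset: FeatureDataset, cfg: MLPConfig | None = None, n_splits: int = 20
) -> dict:
    """Mean metrics over ``n_splits`` re-seeded 70/30 splits.

    One ~45-observation split yields high-variance metrics; averaging over
    independent splits gives a stable synthetic benchmark.  Split seeds are
    derived deterministically from ``cfg.seed``.
    """
    from dataclasses import replace as _replace

    cfg = cfg or MLPConfig()
    reports = []
    for i in range(n_splits):
        model = train_mlp(dataset, _replace(cfg, seed=cfg.seed + i))
        reports.append(evaluate(model))
    keys = ("sensitivity", "specificity", "accuracy", "roc_auc")
    return {
        k: float(np.nanmean([getattr(r, k) for r in reports])) for k in keys
    } | {"n_splits": n_splits}
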