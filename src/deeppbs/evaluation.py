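"""Per-step metrics, the CRIB-II threshold baseline, and a simple DNN
comparator.

Metrics treat the alert class as positive: accuracy = (TP+TN)/total,
recall = TP/(TP+FN), AUC as the rank statistic over pooled unmasked steps.
The CRIB-II rule flags an infant (once, at admission granularity) when the
score is >= 11.  The DNN scores each 5-min segment independently from its
1500 rolled signal values concatenated with the 9 fixed variables
(1509 inputs; layers 512/128/32/2 with a terminal softmax).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor, softmax
from .losses import PROB_FLOOR
from .preprocessing import SegmentedSample

__all__ = [
    "MetricsReport",
    "compute_metrics",
    "crib2_alert_rule",
    "DNNConfig",
    "SimpleDNN",
    "train_dnn",
    "dnn_baseline",
    "plot_risk_trajectory",
    "plot_roc",
    "CRIB2_ALERT_THRESHOLD",
]

CRIB2_ALERT_THRESHOLD = 11


@dataclass
class MetricsReport:
    tp: int
    fn: int
    fp: int
    tn: int
    accuracy: float
    recall: float | None
    auc: float | None

    @property
    def accuracy_times_recall(self) -> float | None:
        return None if self.recall is None else self.accuracy * self.recall


def compute_metrics(scores: np.ndarray, labels: np.ndarray,
                    mask: np.ndarray | None = None,
                    threshold: float = 0.5) -> MetricsReport:
    """Confusion counts, accuracy, recall and AUC over unmasked steps.

    ``scores`` are alert-class probabilities; ``mask`` (optional) is True on
    steps to exclude.  With no positive labels, recall (and AUC) are
    undefined and reported as None with a warning.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=int).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels are not aligned")
    if mask is not None:
        keep = ~np.asarray(mask, dtype=bool).ravel()
        scores, labels = scores[keep], labels[keep]
    if scores.size == 0:
        raise ValueError("no unmasked steps to evaluate")
    pred = scores >= threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    fn = int(np.sum(~pred & pos))
    fp = int(np.sum(pred & ~pos))
    tn = int(np.sum(~pred & ~pos))
    accuracy = (tp + tn) / scores.size
    if pos.any():
        recall = tp / (tp + fn)
    else:
        warnings.warn("no alert steps present; recall undefined")
        recall = None
    if pos.any() and (~pos).any():
        from sklearn.metrics import roc_auc_score
        auc = float(roc_auc_score(labels, scores))
    else:
        auc = None
    return MetricsReport(tp=tp, fn=fn, fp=fp, tn=tn, accuracy=accuracy,
                         recall=recall, auc=auc)


def crib2_alert_rule(crib2_scores) -> np.ndarray:
    """Per-infant alert labels from the static admission score: alert iff
    CRIB-II >= 11.  Scores must be integers."""
    scores = np.asarray(crib2_scores)
    if scores.dtype.kind == "f":
        if not np.all(np.isfinite(scores)) or np.any(scores != np.round(scores)):
            raise ValueError("CRIB-II scores must be integers")
        scores = scores.astype(int)
    elif scores.dtype.kind not in "iu":
        raise ValueError("CRIB-II scores must be integers")
    return scores >= CRIB2_ALERT_THRESHOLD


# -- simple DNN baseline ------------------------------------------------


@dataclass
class DNNConfig:
    hidden_sizes: tuple[int, ...] = (512, 128, 32, 2)
    learning_rate: float = 0.5
    batch_size: int = 128
    epochs: int = 10
    dropout: float = 0.1
    weight_decay: float = 3e-7
    input_dim: int = 1509   # 1500 segment features + 9 global variables

    def __post_init__(self) -> None:
        if self.hidden_sizes[-1] != 2:
            raise ValueError("terminal layer must have 2 outputs")


class SimpleDNN:
    """Feed-forward 1509 -> 512 -> 128 -> 32 -> 2 scorer of independent
    5-min segments (ReLU throughout, terminal softmax)."""

    def __init__(self, config: DNNConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        dims = (config.input_dim,) + tuple(config.hidden_sizes)
        self.params: dict[str, Tensor] = {}
        for i in range(len(dims) - 1):
            bound = 1.0 / np.sqrt(dims[i])
            self.params[f"W{i}"] = Tensor(
                rng.uniform(-bound, bound, size=(dims[i], dims[i + 1])),
                requires_grad=True)
            self.params[f"b{i}"] = Tensor(
                rng.uniform(-bound, bound, size=(dims[i + 1],)),
                requires_grad=True)
        self.n_layers = len(dims) - 1

    def forward(self, X: np.ndarray | Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        h = X if isinstance(X, Tensor) else Tensor(X)
        for i in range(self.n_layers):
            h = h @ self.params[f"W{i}"] + self.params[f"b{i}"]
            if i < self.n_layers - 1:
                h = h.relu()
                if training and self.config.dropout > 0:
                    mask = (rng.random(h.shape) >= self.config.dropout) \
                        / (1.0 - self.config.dropout)
                    h = h * Tensor(mask)
        return softmax(h, axis=-1)

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None


def assemble_dnn_features(samples: list[SegmentedSample]
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Flatten unmasked segments into independent (1509,) data points."""
    feats, labels = [], []
    for s in samples:
        keep = ~s.pad_mask
        n = int(keep.sum())
        feats.append(np.hstack([s.X[keep],
                                np.tile(s.global_features, (n, 1))]))
        labels.append(s.labels[keep])
    return np.vstack(feats), np.concatenate(labels)


def train_dnn(train_samples: list[SegmentedSample],
              val_samples: list[SegmentedSample],
              config: DNNConfig = DNNConfig(), seed: int = 0
              ) -> tuple[SimpleDNN, dict, np.ndarray]:
    """Train the DNN comparator; keep the best accuracy*recall epoch.

    Returns (model at best state, best metrics, validation scores at best
    state)."""
    from .training import Adadelta

    Xtr, ytr = assemble_dnn_features(train_samples)
    Xva, yva = assemble_dnn_features(val_samples)
    if Xtr.shape[1] != config.input_dim:
        raise ValueError(
            f"feature dimension {Xtr.shape[1]} != {config.input_dim}")
    n_alert = max(int((ytr == 1).sum()), 1)
    w_alert = (ytr == 0).sum() / n_alert
    w = np.where(ytr == 1, w_alert, 1.0)

    model = SimpleDNN(config, seed=seed)
    opt = Adadelta(model.params, lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    rng = np.random.default_rng(seed)
    best = None
    for _epoch in range(config.epochs):
        order = rng.permutation(len(ytr))
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo:lo + config.batch_size]
            model.zero_grad()
            probs = model.forward(Xtr[idx], training=True, rng=rng)
            p_true = probs[np.arange(len(idx)), ytr[idx]].clip_min(PROB_FLOOR)
            loss = (Tensor(w[idx]) * (p_true.log() * -1.0)).sum() \
                * (1.0 / w[idx].sum())
            loss.backward()
            opt.step({k: t.grad for k, t in model.params.items()
                      if t.grad is not None})
        val_scores = model.forward(Xva).data[:, 1]
        rep = compute_metrics(val_scores, yva)
        m = rep.accuracy_times_recall
        if best is None or (m is not None and m > best[0]):
            best = (m if m is not None else -1.0,
                    {"accuracy": rep.accuracy, "recall": rep.recall,
                     "auc": rep.auc, "accuracy_times_recall": m},
                    {k: t.data.copy() for k, t in model.params.items()},
                    val_scores)
    for k, t in model.params.items():
        t.data = best[2][k]
    return model, best[1], best[3]


def dnn_baseline(samples: list[SegmentedSample], config: DNNConfig = DNNConfig(),
                 seed: int = 0, folds: int = 4):
    """Fourfold cross-validated DNN baseline; pooled validation metrics."""
    from .training import stratified_folds

    S = samples[0].X.shape[0]
    died = np.array([s.turning_point < S - 1 for s in samples])
    rng = np.random.default_rng(seed)
    all_scores, all_labels, fold_metrics = [], [], []
    for val_idx in stratified_folds(died, folds, rng):
        train_idx = np.setdiff1d(np.arange(len(samples)), val_idx)
        _, metrics, scores = train_dnn([samples[i] for i in train_idx],
                                       [samples[i] for i in val_idx],
                                       config, seed=seed)
        _, yva = assemble_dnn_features([samples[i] for i in val_idx])
        all_scores.append(scores)
        all_labels.append(yva)
        fold_metrics.append(metrics)
    pooled = compute_metrics(np.concatenate(all_scores),
                             np.concatenate(all_labels))
    return np.concatenate(all_scores), pooled, fold_metrics


# -- plots ---------------------------------------------------------------


def plot_risk_trajectory(trajectory: np.ndarray, labels: np.ndarray,
                         out_path, infant_id: str = "") -> None:
    """Per-infant verified alert probability over 5-min steps."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 3))
    ax.plot(trajectory, lw=1, label="P(alert)")
    if np.any(labels == 1):
        on = int(np.argmax(labels == 1))
        ax.axvspan(on, len(labels) - 1, color="red", alpha=0.15,
                   label="true alert window")
    ax.set_xlabel("5-min step")
    ax.set_ylabel("verified alert probability")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title(infant_id)
    ax.legend(loc="upper left", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_roc(scores_per_fold, labels_per_fold, out_path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    fig, ax = plt.subplots(figsize=(5, 5))
    for i, (s, y) in enumerate(zip(scores_per_fold, labels_per_fold)):
        fpr, tpr, _ = roc_curve(y, s)
        ax.plot(fpr, tpr, lw=1, label=f"fold {i + 1}")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("false positive rate")
    ax.set_ylabel("true positive rate")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
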