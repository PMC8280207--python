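"""Optimization regimen for the detection-verification monitor.

Per fold of a stratified four-fold cross-validation: every epoch the
training set is rebuilt from all dying infants plus n/6 randomly drawn
survivors (n = number of dying infants), batches are optimized with
Adadelta (learning rate 0.5), L2 weight decay 3e-7, global-norm gradient
clipping at 5.0, and an exponential moving average (decay 0.999) of all
trainable parameters; the EMA weights are the ones evaluated on the
held-out fold at regular step intervals, and the checkpoint with the best
accuracy x recall is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor
from .losses import (StepWeights, alert_weight, composite_loss,
                     detection_focal_loss, weighted_nll)
from .model import DeepPBSMonitor, ModelConfig
from .preprocessing import SegmentedSample, Standardizer

__all__ = [
    "TrainConfig",
    "FoldResult",
    "Adadelta",
    "clip_gradients",
    "ema_update",
    "resample_epoch",
    "stratified_folds",
    "evaluate_model",
    "train_model",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.5
    weight_decay: float = 3e-7
    batch_size: int = 6
    epochs: int = 60
    clip_threshold: float = 5.0
    ema_decay: float = 0.999
    eval_interval: int = 50
    beta: float = 1.0
    folds: int = 4
    seed: int = 0
    survivor_divisor: int = 6   # epoch resampling draws n_dead/this survivors
    threshold: float = 0.5      # alert-probability operating point

    def __post_init__(self) -> None:
        if self.eval_interval < 1:
            raise ValueError("eval_interval must be >= 1")
        for name in ("learning_rate", "weight_decay", "batch_size", "epochs",
                     "clip_threshold", "ema_decay", "beta", "folds"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FoldResult:
    fold_index: int
    best_metrics: dict
    best_params: dict[str, np.ndarray]
    bn_state: dict
    history: list[dict] = field(default_factory=list)
    best_details: dict | None = None
    standardizer: Standardizer | None = None


class Adadelta:
    """Adadelta with decoupled-from-nothing classic L2 decay added to grads."""

    def __init__(self, params: dict[str, Tensor], lr: float = 0.5,
                 rho: float = 0.9, eps: float = 1e-6,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr, self.rho, self.eps, self.weight_decay = lr, rho, eps, weight_decay
        self._eg2 = {k: np.zeros_like(t.data) for k, t in params.items()}
        self._edx2 = {k: np.zeros_like(t.data) for k, t in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            g = grads.get(k)
            if g is None:
                continue
            if self.weight_decay:
                g = g + self.weight_decay * t.data
            self._eg2[k] = self.rho * self._eg2[k] + (1 - self.rho) * g * g
            dx = np.sqrt(self._edx2[k] + self.eps) / \
                np.sqrt(self._eg2[k] + self.eps) * g
            self._edx2[k] = self.rho * self._edx2[k] + (1 - self.rho) * dx * dx
            t.data = t.data - self.lr * dx


def clip_gradients(grads: dict[str, np.ndarray], threshold: float = 5.0
                   ) -> tuple[dict[str, np.ndarray], float]:
    """Rescale the whole gradient so its global L2 norm is <= threshold."""
    sq = 0.0
    for k, g in grads.items():
        if not np.all(np.isfinite(g)):
            raise FloatingPointError(f"non-finite gradient in {k}")
        sq += float(np.sum(g * g))
    norm = float(np.sqrt(sq))
    if norm <= threshold or norm == 0.0:
        return grads, norm
    scale = threshold / norm
    return {k: g * scale for k, g in grads.items()}, norm


def ema_update(shadow: dict[str, np.ndarray], current: dict[str, np.ndarray],
               mu: float = 0.999) -> dict[str, np.ndarray]:
    """Convex shadow update: shadow <- mu*shadow + (1-mu)*current."""
    for k in shadow:
        if shadow[k].shape != current[k].shape:
            raise ValueError(f"shape mismatch for {k}")
        shadow[k] = mu * shadow[k] + (1.0 - mu) * current[k]
    return shadow


def resample_epoch(died: np.ndarray, rng: np.random.Generator,
                   survivor_divisor: int = 6) -> np.ndarray:
    """Epoch training subset: all dying infants + n/6 random survivors."""
    died = np.asarray(died, dtype=bool)
    dead_idx = np.flatnonzero(died)
    surv_idx = np.flatnonzero(~died)
    n_surv = int(round(len(dead_idx) / survivor_divisor))
    if n_surv == 0:
        raise ValueError(
            f"{len(dead_idx)} dying infants yields zero survivors per epoch "
            f"(need >= {survivor_divisor // 2 + 1})")
    if n_surv > len(surv_idx):
        warnings.warn("fewer survivors than requested; taking all")
        chosen = surv_idx
    else:
        chosen = rng.choice(surv_idx, size=n_surv, replace=False)
    subset = np.concatenate([dead_idx, chosen])
    rng.shuffle(subset)
    return subset


def stratified_folds(died: np.ndarray, k: int, rng: np.random.Generator
                     ) -> list[np.ndarray]:
    """Disjoint covering folds, stratified by outcome so every validation
    fold contains both classes."""
    died = np.asarray(died, dtype=bool)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (True, False):
        idx = np.flatnonzero(died == cls)
        if len(idx) < k:
            raise ValueError(
                f"only {len(idx)} infants with died={cls}; need >= {k} folds")
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[j % k].append(int(i))
    return [np.sort(np.array(f)) for f in folds]


def _batch_forward_loss(model: DeepPBSMonitor, batch: list[SegmentedSample],
                        weights: StepWeights, beta: float,
                        rng: np.random.Generator):
    X = np.stack([s.X for s in batch])
    G = np.stack([s.global_features for s in batch])
    out = model.forward(X, G, training=True, rng=rng)
    B, S = X.shape[0], X.shape[1]
    det = None
    for b, s in enumerate(batch):
        term = detection_focal_loss(out.TP[b], int(s.turning_point), S)
        det = term if det is None else det + term
    det = det * (1.0 / B)
    labels = np.concatenate([s.labels for s in batch])
    mask = np.concatenate([s.pad_mask for s in batch])
    w = weights.per_step(labels)
    pred = weighted_nll(out.P.reshape((B * S, 2)), labels, w, mask)
    ver = weighted_nll(out.P_verified.reshape((B * S, 2)), labels, w, mask)
    total = composite_loss(det, pred, ver, beta)
    comps = {"detection": float(det.data), "prediction": float(pred.data),
             "verification": float(ver.data), "total": float(total.data)}
    return total, comps


def evaluate_model(model: DeepPBSMonitor, samples: list[SegmentedSample],
                   threshold: float = 0.5, chunk: int = 8):
    """Pooled per-step metrics over all unmasked validation steps, plus
    per-infant selected turning points and risk trajectories."""
    from .evaluation import compute_metrics

    scores, labels = [], []
    details = {"infant_id": [], "selected_tp": [], "true_tp": [],
               "trajectories": {}}
    for lo in range(0, len(samples), chunk):
        part = samples[lo:lo + chunk]
        X = np.stack([s.X for s in part])
        G = np.stack([s.global_features for s in part])
        out = model.forward(X, G, training=False)
        for b, s in enumerate(part):
            keep = ~s.pad_mask
            traj = out.P_verified.data[b, :, 1]
            scores.append(traj[keep])
            labels.append(s.labels[keep])
            details["infant_id"].append(s.infant_id)
            details["selected_tp"].append(int(out.tp[b]))
            details["true_tp"].append(int(s.turning_point))
            details["trajectories"][s.infant_id] = traj
    report = compute_metrics(np.concatenate(scores), np.concatenate(labels),
                             threshold=threshold)
    metrics = {"accuracy": report.accuracy, "recall": report.recall,
               "auc": report.auc,
               "accuracy_times_recall": report.accuracy_times_recall}
    return metrics, details


def train_model(samples: list[SegmentedSample], config: TrainConfig,
                model_config: ModelConfig, progress: bool = False
                ) -> list[FoldResult]:
    """Stratified k-fold cross-validated training; returns one result per
    fold with the best-accuracy*recall EMA checkpoint."""
    died = np.array([s.turning_point < model_config.S - 1 for s in samples])
    root = np.random.SeedSequence(config.seed)
    ss_split, ss_folds = root.spawn(2)
    folds = stratified_folds(died, config.folds, np.random.default_rng(ss_split))
    fold_seeds = ss_folds.spawn(config.folds)

    results = []
    for fi, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(samples)), val_idx)
        scaler = Standardizer.fit([samples[i] for i in train_idx])
        train = [scaler.transform(samples[i]) for i in train_idx]
        val = [scaler.transform(samples[i]) for i in val_idx]

        tl = np.concatenate([s.labels[~s.pad_mask] for s in train])
        n_alert = int((tl == 1).sum())
        n_not = int((tl == 0).sum())
        weights = StepWeights(alert=alert_weight(n_not, n_alert))

        ss_init, ss_resample, ss_dropout = fold_seeds[fi].spawn(3)
        model = DeepPBSMonitor(model_config,
                               seed=int(ss_init.generate_state(1)[0] % 2**31))
        opt = Adadelta(model.params, lr=config.learning_rate,
                       weight_decay=config.weight_decay)
        shadow = {k: t.data.copy() for k, t in model.params.items()}
        rng_re = np.random.default_rng(ss_resample)
        rng_do = np.random.default_rng(ss_dropout)
        eval_model = DeepPBSMonitor(model_config, seed=0)

        def _evaluate(step):
            eval_model.load_parameter_arrays(shadow)
            for name, st in model.bn_state.items():
                eval_model.bn_state[name] = {"mean": st["mean"].copy(),
                                             "var": st["var"].copy()}
            metrics, details = evaluate_model(eval_model, val,
                                              threshold=config.threshold)
            metrics = dict(metrics, step=step)
            return metrics, details

        history: list[dict] = []
        best = None
        step = 0
        died_train = died[train_idx]
        for _epoch in range(config.epochs):
            subset = resample_epoch(died_train, rng_re,
                                    config.survivor_divisor)
            for lo in range(0, len(subset), config.batch_size):
                batch = [train[i] for i in subset[lo:lo + config.batch_size]]
                model.zero_grad()
                total, comps = _batch_forward_loss(model, batch, weights,
                                                   config.beta, rng_do)
                total.backward()
                grads = {k: t.grad for k, t in model.params.items()
                         if t.grad is not None}
                grads, _ = clip_gradients(grads, config.clip_threshold)
                opt.step(grads)
                ema_update(shadow, {k: t.data for k, t in model.params.items()},
                           config.ema_decay)
                step += 1
                record = dict(comps, step=step, fold=fi)
                if step % config.eval_interval == 0:
                    metrics, details = _evaluate(step)
                    record.update({f"val_{k}": v for k, v in metrics.items()
                                   if k != "step"})
                    m = metrics["accuracy_times_recall"]
                    if best is None or (m is not None and m > best[0]):
                        best = (m if m is not None else -1.0, metrics,
                                {k: v.copy() for k, v in shadow.items()},
                                details)
                if progress:  # pragma: no cover
                    print(f"fold {fi} step {step}: " + " ".join(
                        f"{k}={v:.4f}" for k, v in comps.items()))
                history.append(record)
        # final evaluation so short runs still produce a checkpoint
        metrics, details = _evaluate(step)
        history.append(dict({f"val_{k}": v for k, v in metrics.items()
                             if k != "step"}, step=step, fold=fi))
        m = metrics["accuracy_times_recall"]
        if best is None or (m is not None and m > best[0]):
            best = (m if m is not None else -1.0, metrics,
                    {k: v.copy() for k, v in shadow.items()}, details)
        results.append(FoldResult(
            fold_index=fi, best_metrics=best[1], best_params=best[2],
            bn_state={k: {kk: vv.copy() for kk, vv in v.items()}
                      for k, v in model.bn_state.items()},
            history=history, best_details=best[3], standardizer=scaler))
    return results
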