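"""Composite detection / prediction / verification loss.

The detection term is a focal loss on the turning-point distribution with
extra weight on the terminal padded step (the "no turning point" target);
the prediction and verification terms are weighted negative log-likelihood
over unmasked per-step risk probabilities, with the alert class reweighted
to counter the extreme not-alert/alert imbalance.  The composite total is

    L = beta * L_detection + L_prediction + 2 * L_verification
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._tensor import Tensor

__all__ = [
    "LossComponents",
    "StepWeights",
    "alert_weight",
    "detection_focal_loss",
    "weighted_nll",
    "composite_loss",
]

#: Empirical rescaling of the raw imbalance ratio used for alert-step weights.
ALERT_WEIGHT_SCALE = 0.1153
#: Extra detection weight on the terminal padded ("no turning point") step.
PAD_STEP_WEIGHT = 1.3
FOCAL_GAMMA = 2.0
FOCAL_ALPHA = 1.0
PROB_FLOOR = 1e-12


@dataclass
class LossComponents:
    detection: float
    prediction: float
    verification: float
    beta: float

    @property
    def total(self) -> float:
        return self.beta * self.detection + self.prediction + 2.0 * self.verification


@dataclass
class StepWeights:
    """Per-step loss weights for one training fold.

    not-alert steps weigh 1; alert steps weigh
    (n_not_alert / n_alert) * 0.1153, recomputed whenever the training set
    changes.  Detection weights are 1 everywhere except 1.3 on the terminal
    padded step.
    """

    alert: float
    not_alert: float = 1.0

    def per_step(self, labels: np.ndarray) -> np.ndarray:
        return np.where(np.asarray(labels) == 1, self.alert, self.not_alert)


def alert_weight(n_not_alert: int, n_alert: int) -> float:
    """Imbalance weight for alert steps: (n_not_alert / n_alert) * 0.1153."""
    if n_alert <= 0:
        raise ValueError("no alert time steps in training fold; cannot weight")
    return (n_not_alert / n_alert) * ALERT_WEIGHT_SCALE


def detection_focal_loss(TP: Tensor | np.ndarray, true_tp: int, S: int | None = None,
                         gamma: float = FOCAL_GAMMA, alpha: float = FOCAL_ALPHA) -> Tensor:
    """Focal loss on the turning-point distribution.

    loss = w * alpha * (1 - p)^gamma * (-log p) with p = TP[true_tp];
    w = 1.3 when the target is the terminal padded step (no turning point),
    else 1.
    """
    TP = TP if isinstance(TP, Tensor) else Tensor(TP)
    if S is None:
        S = TP.shape[-1]
    if not 0 <= true_tp <= S - 1:
        raise ValueError(f"true turning point {true_tp} outside [0, {S - 1}]")
    p = TP[int(true_tp)] if TP.ndim == 1 else TP[:, int(true_tp)]
    if np.any(p.data <= 0.0):
        warnings.warn("turning-point probability underflow; clamping before log")
    p = p.clip_min(PROB_FLOOR)
    w = PAD_STEP_WEIGHT if true_tp == S - 1 else 1.0
    loss = (1.0 - p) ** gamma * (p.log() * -1.0) * (w * alpha)
    return loss.mean() if loss.ndim > 0 else loss


def weighted_nll(probs: Tensor | np.ndarray, labels: np.ndarray,
                 weights: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
    """Weighted mean of -log p(true label) over unmasked steps.

    ``probs`` holds per-step class probabilities (n_steps, 2); ``mask`` is
    True on steps to exclude (zero-padding).  The weighted mean (rather than
    sum) keeps the loss scale independent of sequence length.
    """
    probs = probs if isinstance(probs, Tensor) else Tensor(probs)
    labels = np.asarray(labels, dtype=int).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    n = labels.size
    keep = np.ones(n, dtype=bool) if mask is None else ~np.asarray(mask, dtype=bool).ravel()
    if not keep.any():
        raise ValueError("all steps masked; weighted NLL undefined")
    idx = np.flatnonzero(keep)
    p_true = probs[idx, labels[idx]].clip_min(PROB_FLOOR)
    w = weights[idx]
    return (Tensor(w) * (p_true.log() * -1.0)).sum() * (1.0 / w.sum())


def composite_loss(detection, prediction, verification, beta: float = 1.0):
    """Eq-exact weighted sum: beta*detection + prediction + 2*verification.

    Works on floats or Tensors (for backprop).
    """
    return detection * beta + prediction + verification * 2.0
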