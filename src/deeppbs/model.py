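"""The DeepPBSMonitor detection-verification sequence model.

The model maps an infant's segmented vital-sign matrix ``X`` (S time steps x
n_v rolled signal values) and a fixed clinical vector ``G`` (n_g values)
to (a) a probability distribution ``TP`` over time steps for the turning
point at which the infant transitions from a stable ("not alert") to an
unstable ("alert") state, and (b) per-step two-class risk probabilities,
both raw (``P``) and verified (``P_verified``).

Seven blocks are composed in order: linear projection, highway network,
embedding LSTM (three residual layers with a learned per-step mixture),
point-wise gate fusion of signal and clinical information, modeling LSTM,
a depthwise-separable-convolution detector, and a before/after verifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._tensor import Tensor, concat, lstm, sigmoid, softmax, stack

__all__ = [
    "ModelConfig",
    "ForwardOutputs",
    "DeepPBSMonitor",
    "select_turning_point",
    "save_checkpoint",
    "load_checkpoint",
]

#: Sentinel meaning "no turning point": the terminal padded step S-1.
NO_TURNING_POINT_IS_LAST = True


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the final operating point of the tool: hidden size 64, one
    highway layer, one detector convolution layer, dropout 0.1, over
    S=960 five-minute steps of n_v=1500 rolled signal values with n_g=9
    fixed clinical variables.
    """

    n_h: int = 64
    l_highway: int = 1
    l_cnn: int = 1
    p_d: float = 0.1
    kernel_size: int = 7
    n_v: int = 1500
    n_g: int = 9
    S: int = 960

    def __post_init__(self) -> None:
        if self.n_h < 1 or self.l_highway < 1 or self.l_cnn < 1:
            raise ValueError("n_h, l_highway and l_cnn must all be >= 1")
        if not 0.0 <= self.p_d < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1): {self.p_d}")
        if self.S < self.kernel_size:
            raise ValueError(
                f"sequence length S={self.S} shorter than detector kernel "
                f"{self.kernel_size}"
            )

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in (
            "n_h", "l_highway", "l_cnn", "p_d", "kernel_size", "n_v", "n_g", "S")}


@dataclass
class ForwardOutputs:
    """Everything a forward pass produces (tensors keep the autodiff graph)."""

    TP: Tensor                      # (B, S) turning-point distribution
    tp: np.ndarray                  # (B,) selected index; S-1 encodes "none"
    P: Tensor                       # (B, S, 2) raw per-step risk
    P_verified: Tensor              # (B, S, 2) verified per-step risk
    intermediates: dict = field(default_factory=dict)


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> Tensor:
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


def select_turning_point(tp_probs: np.ndarray, sequence_length: int | None = None) -> int:
    """Evaluation-time turning-point selection rule.

    If the most probable step exceeds probability 0.5 it is chosen outright.
    Otherwise Round(sequence_length / 960) candidate steps with the highest
    probabilities are collected (at least one, so that short scaled sequences
    still yield a candidate) and the latest-in-time candidate is accepted iff
    its probability exceeds 4 / sequence_length; otherwise the sequence is
    declared to have no turning point, encoded as the final (padded) step.
    Ties anywhere are broken toward the latest step.
    """
    p = np.asarray(tp_probs, dtype=float).ravel()
    if p.size == 0:
        raise ValueError("empty turning-point distribution")
    S = p.size
    L = S if sequence_length is None else int(sequence_length)
    latest_max = S - 1 - int(np.argmax(p[::-1]))
    if p[latest_max] > 0.5:
        return latest_max
    k = max(1, int(round(L / 960.0)))
    # ascending by (probability, index): the last k are the candidates,
    # preferring later steps among equal probabilities
    order = np.lexsort((np.arange(S), p))
    candidate = int(order[-k:].max())
    if p[candidate] > 4.0 / L:
        return candidate
    return S - 1


class DeepPBSMonitor:
    """Parameter container plus the block-by-block forward pass."""

    def __init__(self, config: ModelConfig, seed: int = 0):
        self.config = config
        rng = np.random.default_rng(seed)
        c = config
        H = c.n_h
        p: dict[str, Tensor] = {}

        p["proj.W_x"] = _uniform(rng, (c.n_v, H), c.n_v)
        p["proj.b_x"] = _uniform(rng, (H,), c.n_v)
        p["proj.W_g"] = _uniform(rng, (c.n_g, H), c.n_g)
        p["proj.b_g"] = _uniform(rng, (H,), c.n_g)
        for i in range(c.l_highway):
            p[f"highway{i}.W_g"] = _uniform(rng, (H, H), H)
            p[f"highway{i}.b_g"] = _uniform(rng, (H,), H)
            p[f"highway{i}.W_t"] = _uniform(rng, (H, H), H)
            p[f"highway{i}.b_t"] = _uniform(rng, (H,), H)
        for i in range(3):
            p[f"embed{i}.w_ih"] = _uniform(rng, (H, 4 * H), H)
            p[f"embed{i}.w_hh"] = _uniform(rng, (H, 4 * H), H)
            p[f"embed{i}.b"] = _uniform(rng, (4 * H,), H)
        p["embed.W_l"] = _uniform(rng, (3 * H, 3), 3 * H)
        p["embed.b_l"] = _uniform(rng, (3,), 3 * H)
        p["gate.W_m"] = _uniform(rng, (4 * H, H), 4 * H)
        p["gate.b_m"] = _uniform(rng, (H,), 4 * H)
        p["modeling.w_ih"] = _uniform(rng, (H, 4 * H), H)
        p["modeling.w_hh"] = _uniform(rng, (H, 4 * H), H)
        p["modeling.b"] = _uniform(rng, (4 * H,), H)
        for i in range(c.l_cnn):
            p[f"conv{i}.depth"] = _uniform(rng, (c.kernel_size, H), c.kernel_size)
            p[f"conv{i}.point"] = _uniform(rng, (H, H), H)
            p[f"conv{i}.point_b"] = _uniform(rng, (H,), H)
            p[f"conv{i}.gamma"] = Tensor(np.ones(H), requires_grad=True)
            p[f"conv{i}.beta"] = Tensor(np.zeros(H), requires_grad=True)
        p["det.W_tp"] = _uniform(rng, (H, 1), H)
        p["det.b_tp"] = _uniform(rng, (1,), H)
        p["ver.W_nw"] = _uniform(rng, (H, 2), H)
        p["ver.b_nw"] = _uniform(rng, (2,), H)
        p["ver.W_w"] = _uniform(rng, (H, 2), H)
        p["ver.b_w"] = _uniform(rng, (2,), H)
        for side in ("before", "after"):
            p[f"ver.{side}.w_ih"] = _uniform(rng, (2, 8), 2)
            p[f"ver.{side}.w_hh"] = _uniform(rng, (2, 8), 2)
            p[f"ver.{side}.b"] = _uniform(rng, (8,), 2)
        self.params = p

        # batch-normalization running statistics (not trainable)
        self.bn_state = {
            f"conv{i}": {"mean": np.zeros(H), "var": np.ones(H)}
            for i in range(c.l_cnn)
        }
        self.bn_momentum = 0.1

    # -- parameter plumbing --------------------------------------------

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    def parameter_arrays(self) -> dict[str, np.ndarray]:
        return {k: t.data for k, t in self.params.items()}

    def load_parameter_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, t in self.params.items():
            t.data = np.array(arrays[k], dtype=np.float64)

    # -- dropout --------------------------------------------------------

    def _dropout(self, x: Tensor, training: bool, rng: np.random.Generator | None) -> Tensor:
        p = self.config.p_d
        if not training or p <= 0.0:
            return x
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        mask = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(mask)

    # -- blocks ---------------------------------------------------------

    def linear_projection(self, X: Tensor, G: Tensor) -> tuple[Tensor, Tensor]:
        """X (B,S,n_v), G (B,n_g) -> H_X, H_g both (B,S,n_h).

        The clinical projection h_g is tiled along the S time steps.
        """
        B, S, _ = X.shape
        H_X = (X @ self.params["proj.W_x"] + self.params["proj.b_x"]).relu()
        h_g = (G @ self.params["proj.W_g"] + self.params["proj.b_g"]).relu()
        H_g = h_g.reshape((B, 1, self.config.n_h)).broadcast_to((B, S, self.config.n_h))
        return H_X, H_g

    def highway_forward(self, H: Tensor) -> Tensor:
        """l_highway gated-residual layers: g*t + (1-g)*H."""
        out = H
        for i in range(self.config.l_highway):
            g = sigmoid(out @ self.params[f"highway{i}.W_g"] + self.params[f"highway{i}.b_g"])
            t = (out @ self.params[f"highway{i}.W_t"] + self.params[f"highway{i}.b_t"]).relu()
            out = g * t + (1.0 - g) * out
        return out

    def embedding_lstm(self, H: Tensor) -> Tensor:
        """Three residual LSTM layers mixed by a per-step 3-way softmax."""
        outs = []
        x = H
        for i in range(3):
            x = lstm(x, self.params[f"embed{i}.w_ih"], self.params[f"embed{i}.w_hh"],
                     self.params[f"embed{i}.b"]) + x
            outs.append(x)
        L_X = concat(outs, axis=-1)                       # (B, S, 3*n_h)
        P_l = softmax(L_X @ self.params["embed.W_l"] + self.params["embed.b_l"], axis=-1)
        mixed = None
        for i in range(3):
            term = P_l[..., i:i + 1] * outs[i]
            mixed = term if mixed is None else mixed + term
        return mixed

    def gate_forward(self, L_X: Tensor, H_g: Tensor) -> Tensor:
        """Point-wise convex fusion of signal embedding and clinical embedding."""
        feats = concat([L_X, H_g, L_X * H_g, L_X - H_g], axis=-1)
        p = sigmoid(feats @ self.params["gate.W_m"] + self.params["gate.b_m"])
        return p * L_X + (1.0 - p) * H_g

    def modeling_lstm(self, M: Tensor) -> Tensor:
        """One residual LSTM layer producing the per-step risk state."""
        return lstm(M, self.params["modeling.w_ih"], self.params["modeling.w_hh"],
                    self.params["modeling.b"]) + M

    def _depthwise_separable_conv(self, x: Tensor, i: int) -> Tensor:
        """Length-preserving depthwise conv (kernel 7, symmetric zero pad)
        followed by a pointwise channel mix."""
        B, S, H = x.shape
        K = self.config.kernel_size
        lpad, rpad = (K - 1) // 2, K // 2
        zl = Tensor(np.zeros((B, lpad, H)))
        zr = Tensor(np.zeros((B, rpad, H)))
        xp = concat([zl, x, zr], axis=1)
        w = self.params[f"conv{i}.depth"]
        acc = None
        for j in range(K):
            term = xp[:, j:j + S, :] * w[j]
            acc = term if acc is None else acc + term
        return acc @ self.params[f"conv{i}.point"] + self.params[f"conv{i}.point_b"]

    def _batch_norm(self, x: Tensor, i: int, training: bool) -> Tensor:
        eps = 1e-5
        st = self.bn_state[f"conv{i}"]
        if training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 1), keepdims=True)
            m = self.bn_momentum
            st["mean"] = (1 - m) * st["mean"] + m * mu.data.ravel()
            st["var"] = (1 - m) * st["var"] + m * var.data.ravel()
            xhat = (x - mu) * (var + eps) ** -0.5
        else:
            xhat = (x - Tensor(st["mean"])) * Tensor((st["var"] + eps) ** -0.5)
        return xhat * self.params[f"conv{i}.gamma"] + self.params[f"conv{i}.beta"]

    def detector_forward(self, M_bar: Tensor, training: bool = False) -> tuple[Tensor, Tensor]:
        """Conv stack + softmax over time: the turning-point distribution TP."""
        B, S, H = M_bar.shape
        if S < self.config.kernel_size:
            raise ValueError("sequence shorter than detector kernel")
        F = M_bar
        for i in range(self.config.l_cnn):
            F = self._batch_norm(self._depthwise_separable_conv(F, i), i, training).relu()
        logits = (F @ self.params["det.W_tp"] + self.params["det.b_tp"]).reshape((B, S))
        TP = softmax(logits, axis=1)
        return TP, F

    def verifier_forward(self, M_bar: Tensor, tp: np.ndarray | int) -> tuple[Tensor, Tensor]:
        """Before/after risk heads spliced at the turning point.

        The step at ``tp`` itself belongs to the "after" part (0-based,
        half-open slicing), matching tp = first alert step.
        """
        B, S, H = M_bar.shape
        tp = np.atleast_1d(np.asarray(tp, dtype=int))
        if tp.size == 1 and B > 1:
            tp = np.full(B, int(tp[0]))
        if np.any((tp < 0) | (tp > S - 1)):
            raise ValueError(f"turning point out of range [0, {S - 1}]: {tp}")
        P_b = M_bar @ self.params["ver.W_nw"] + self.params["ver.b_nw"]   # (B,S,2)
        P_a = M_bar @ self.params["ver.W_w"] + self.params["ver.b_w"]     # (B,S,2)
        seq_b = lstm(P_b, self.params["ver.before.w_ih"],
                     self.params["ver.before.w_hh"], self.params["ver.before.b"])
        seq_a = lstm(P_a, self.params["ver.after.w_ih"],
                     self.params["ver.after.w_hh"], self.params["ver.after.b"])
        rows, rows_v = [], []
        for b in range(B):
            t = int(tp[b])
            spliced = concat([P_b[b, :t, :], P_a[b, t:, :]], axis=0)      # (S,2)
            rows.append(spliced)
            rows_v.append(spliced - seq_b[b] + seq_a[b])
        P = softmax(stack(rows, axis=0), axis=-1)
        P_verified = softmax(stack(rows_v, axis=0), axis=-1)
        return P, P_verified

    # -- full pass ------------------------------------------------------

    def forward(
        self,
        X: Tensor | np.ndarray,
        G: Tensor | np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
        sequence_length: int | None = None,
    ) -> ForwardOutputs:
        """Compose all blocks.

        Training mode applies dropout after each block and selects the
        turning point as argmax(TP); evaluation mode is deterministic and
        uses :func:`select_turning_point`.
        """
        X = X if isinstance(X, Tensor) else Tensor(X)
        G = G if isinstance(G, Tensor) else Tensor(G)
        if X.ndim == 2:
            X = X.reshape((1,) + X.shape)
        if G.ndim == 1:
            G = G.reshape((1,) + G.shape)

        H_X, H_g = self.linear_projection(X, G)
        H_X = self._dropout(H_X, training, rng)
        H_g = self._dropout(H_g, training, rng)
        Hw = self._dropout(self.highway_forward(H_X), training, rng)
        L_X = self._dropout(self.embedding_lstm(Hw), training, rng)
        M = self._dropout(self.gate_forward(L_X, H_g), training, rng)
        M_bar = self._dropout(self.modeling_lstm(M), training, rng)
        TP, F = self.detector_forward(M_bar, training=training)

        S = X.shape[1]
        if training:
            # latest step among ties, consistent with the evaluation rule
            rev = TP.data[:, ::-1]
            tp = S - 1 - np.argmax(rev, axis=1)
        else:
            tp = np.array([
                select_turning_point(TP.data[b], sequence_length or S)
                for b in range(X.shape[0])
            ])
        P, P_verified = self.verifier_forward(M_bar, tp)
        return ForwardOutputs(
            TP=TP, tp=tp, P=P, P_verified=P_verified,
            intermediates={"H_X": H_X, "H_g": H_g, "L_X_bar": L_X, "M": M,
                           "M_bar": M_bar, "F": F},
        )

    __call__ = forward


def save_checkpoint(model: DeepPBSMonitor, path: str | Path,
                    ema: dict[str, np.ndarray] | None = None) -> None:
    """Write parameters (and optional EMA shadow copies) plus a JSON config."""
    path = Path(path)
    arrays = {f"param/{k}": v for k, v in model.parameter_arrays().items()}
    for name, st in model.bn_state.items():
        arrays[f"bn/{name}/mean"] = st["mean"]
        arrays[f"bn/{name}/var"] = st["var"]
    if ema is not None:
        arrays.update({f"ema/{k}": v for k, v in ema.items()})
    np.savez(path, **arrays)
    sidecar = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" \
        else path.with_suffix(".json")
    sidecar.write_text(json.dumps(model.config.to_dict(), indent=2))


def load_checkpoint(path: str | Path, use_ema: bool = False) -> DeepPBSMonitor:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    config = ModelConfig(**json.loads(sidecar.read_text()))
    model = DeepPBSMonitor(config, seed=0)
    with np.load(path) as z:
        prefix = "ema/" if use_ema and any(k.startswith("ema/") for k in z.files) \
            else "param/"
        model.load_parameter_arrays(
            {k[len(prefix):]: z[k] for k in z.files if k.startswith(prefix)})
        for name, st in model.bn_state.items():
            st["mean"] = z[f"bn/{name}/mean"]
            st["var"] = z[f"bn/{name}/var"]
    return model
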