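"""A convolutional-recurrent window classifier implemented in numpy.

The architecture follows the DeepConvLSTM family used for wearable-sensor
activity recognition: four temporal (valid, no-padding) convolutions with
ReLU activations slide over the time axis of an ``SWS x N`` window, the
resulting feature sequence feeds two stacked LSTM layers, and the last
time step's hidden state passes through one linear layer and a softmax to
produce class probabilities.  Training is plain mini-batch SGD with
momentum on the cross-entropy loss.

Everything — forward pass, backpropagation through time, the optimizer —
is implemented here directly on numpy arrays with hand-derived gradients
(verified against finite differences in the test suite), so runs are fully
deterministic given the seeds and need no deep-learning runtime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .dataset import WindowedDataset

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "TrainedModel",
    "conv_output_length",
    "build_model",
    "train_model",
    "predict_window_proba",
    "ConvLSTMClassifier",
]


def conv_output_length(sws: int, k: int, n_layers: int = 4) -> int:
    """Time-axis length after ``n_layers`` valid convolutions of kernel ``k``.

    Raises if the window is too short for the stack (result < 1).
    """
    out = sws - n_layers * (k - 1)
    if out < 1:
        raise ValueError(
            f"window of {sws} frames infeasible for {n_layers} conv layers "
            f"of kernel {k} (output length {out} < 1)")
    return out


@dataclass(frozen=True)
class ModelConfig:
    """Architecture parameters (window size, kernel, channels, cells, classes)."""

    window_frames: int
    input_channels: int
    kernel_frames: int = 6
    conv_channels: int = 32
    lstm_cells: int = 64
    n_classes: int = 14
    conv_layers: int = 4
    lstm_layers: int = 2
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("window_frames", "input_channels", "kernel_frames",
                     "conv_channels", "lstm_cells", "n_classes",
                     "conv_layers", "lstm_layers"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        conv_output_length(self.window_frames, self.kernel_frames, self.conv_layers)


@dataclass(frozen=True)
class TrainConfig:
    """Optimization parameters for SGD with momentum."""

    learning_rate: float = 0.001
    momentum: float = 0.9
    batch_size: int = 100
    max_epochs: int = 100
    patience: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if not 0.0 <= self.momentum < 1.0:
            raise ValueError("momentum must be in [0, 1)")
        if self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("batch_size and max_epochs must be positive")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class ConvLSTMClassifier:
    """The network: parameter container plus forward/backward passes."""

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = dtype
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)

        def uni(shape, fan_in):
            s = 1.0 / np.sqrt(fan_in)
            return rng.uniform(-s, s, size=shape).astype(dtype)

        c_in = cfg.input_channels
        for l in range(cfg.conv_layers):
            self.params[f"conv{l}_W"] = uni(
                (cfg.kernel_frames, c_in, cfg.conv_channels), cfg.kernel_frames * c_in)
            self.params[f"conv{l}_b"] = np.zeros(cfg.conv_channels, dtype=dtype)
            c_in = cfg.conv_channels
        in_dim = cfg.conv_channels
        for l in range(cfg.lstm_layers):
            L = cfg.lstm_cells
            self.params[f"lstm{l}_Wx"] = uni((in_dim, 4 * L), L)
            self.params[f"lstm{l}_Wh"] = uni((L, 4 * L), L)
            b = np.zeros(4 * L, dtype=dtype)
            b[L:2 * L] = 1.0   # forget-gate bias
            self.params[f"lstm{l}_b"] = b
            in_dim = L
        self.params["fc_W"] = uni((cfg.lstm_cells, cfg.n_classes), cfg.lstm_cells)
        self.params["fc_b"] = np.zeros(cfg.n_classes, dtype=dtype)

    # ------------------------------------------------------------------ #

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=self.dtype)
        if X.ndim != 3:
            raise ValueError("input must be (batch, window_frames, channels)")
        if X.shape[2] != self.cfg.input_channels:
            raise ValueError(
                f"channel mismatch: model expects N={self.cfg.input_channels}, "
                f"got {X.shape[2]}")
        if X.shape[1] != self.cfg.window_frames:
            raise ValueError(
                f"window-length mismatch: model expects {self.cfg.window_frames} "
                f"frames, got {X.shape[1]}")
        return X

    def _forward(self, X: np.ndarray, train: bool = False,
                 rng: np.random.Generator | None = None):
        """Run the network; returns (probs, cache)."""
        cfg = self.cfg
        k = cfg.kernel_frames
        cache: dict = {"conv": [], "lstm": [], "dropout": []}
        h = X
        for l in range(cfg.conv_layers):
            W = self.params[f"conv{l}_W"]
            b = self.params[f"conv{l}_b"]
            t_out = h.shape[1] - k + 1
            y = np.tensordot(h[:, 0:0 + t_out, :], W[0], axes=([2], [0]))
            for j in range(1, k):
                y += np.tensordot(h[:, j:j + t_out, :], W[j], axes=([2], [0]))
            y += b
            mask = y > 0
            cache["conv"].append((h, mask))
            h = y * mask
        # inverted dropout on the conv feature sequence and between LSTMs
        def dropout(a):
            if train and cfg.dropout_rate > 0.0:
                keep = 1.0 - cfg.dropout_rate
                m = (rng.random(a.shape) < keep).astype(a.dtype) / keep
                cache["dropout"].append(m)
                return a * m
            cache["dropout"].append(None)
            return a

        h = dropout(h)
        B, T, _ = h.shape
        L = cfg.lstm_cells
        for l in range(cfg.lstm_layers):
            Wx = self.params[f"lstm{l}_Wx"]
            Wh = self.params[f"lstm{l}_Wh"]
            b = self.params[f"lstm{l}_b"]
            gates_a = np.tensordot(h, Wx, axes=([2], [0])) + b   # (B,T,4L)
            i = np.empty((B, T, L), dtype=h.dtype)
            f = np.empty_like(i)
            g = np.empty_like(i)
            o = np.empty_like(i)
            c = np.empty_like(i)
            hs = np.empty_like(i)
            h_prev = np.zeros((B, L), dtype=h.dtype)
            c_prev = np.zeros((B, L), dtype=h.dtype)
            for t in range(T):
                a = gates_a[:, t] + h_prev @ Wh
                i[:, t] = _sigmoid(a[:, :L])
                f[:, t] = _sigmoid(a[:, L:2 * L])
                g[:, t] = np.tanh(a[:, 2 * L:3 * L])
                o[:, t] = _sigmoid(a[:, 3 * L:])
                c[:, t] = f[:, t] * c_prev + i[:, t] * g[:, t]
                hs[:, t] = o[:, t] * np.tanh(c[:, t])
                h_prev = hs[:, t]
                c_prev = c[:, t]
            cache["lstm"].append((h, i, f, g, o, c, hs))
            h = hs
            if l < cfg.lstm_layers - 1:
                h = dropout(h)
        h_last = h[:, -1, :]
        logits = h_last @ self.params["fc_W"] + self.params["fc_b"]
        logits64 = logits.astype(np.float64)
        logits64 -= logits64.max(axis=1, keepdims=True)
        ex = np.exp(logits64)
        probs = ex / ex.sum(axis=1, keepdims=True)
        cache["h_last"] = h_last
        return probs, cache

    def predict_proba(self, X: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        """Deterministic evaluation-mode class probabilities (rows sum to 1)."""
        X = self._check_input(X)
        out = []
        for s in range(0, X.shape[0], batch_size):
            probs, _ = self._forward(X[s:s + batch_size], train=False)
            out.append(probs)
        return np.concatenate(out, axis=0)

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray,
                       rng: np.random.Generator | None = None
                       ) -> tuple[float, dict[str, np.ndarray]]:
        """Mean cross-entropy and gradients for one mini-batch."""
        cfg = self.cfg
        X = self._check_input(X)
        y = np.asarray(y, dtype=np.int64)
        if y.max(initial=0) >= cfg.n_classes:
            raise ValueError("label index out of range for n_classes")
        B = X.shape[0]
        probs, cache = self._forward(X, train=True, rng=rng)
        loss = float(-np.log(np.maximum(probs[np.arange(B), y], 1e-300)).mean())

        grads = {kk: np.zeros_like(v) for kk, v in self.params.items()}
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits = (dlogits / B).astype(self.dtype)

        h_last = cache["h_last"]
        grads["fc_W"] = h_last.T @ dlogits
        grads["fc_b"] = dlogits.sum(axis=0)
        dh_last = dlogits @ self.params["fc_W"].T

        L = cfg.lstm_cells
        drop_iter = len(cache["dropout"]) - 1
        dh_seq_ext = None
        for l in range(cfg.lstm_layers - 1, -1, -1):
            x_in, i, f, g, o, c, hs = cache["lstm"][l]
            B_, T, _ = hs.shape
            Wx = self.params[f"lstm{l}_Wx"]
            Wh = self.params[f"lstm{l}_Wh"]
            dWx = np.zeros_like(Wx)
            dWh = np.zeros_like(Wh)
            db = np.zeros_like(self.params[f"lstm{l}_b"])
            dx = np.empty_like(x_in)
            dh_next = np.zeros((B_, L), dtype=self.dtype)
            dc_next = np.zeros((B_, L), dtype=self.dtype)
            for t in range(T - 1, -1, -1):
                dh = dh_next.copy()
                if dh_seq_ext is not None:
                    dh += dh_seq_ext[:, t]
                elif t == T - 1:
                    dh += dh_last
                tc = np.tanh(c[:, t])
                do = dh * tc
                dc = dh * o[:, t] * (1.0 - tc * tc) + dc_next
                di = dc * g[:, t]
                dg = dc * i[:, t]
                c_prev = c[:, t - 1] if t > 0 else np.zeros_like(dc)
                df = dc * c_prev
                da = np.concatenate([
                    di * i[:, t] * (1.0 - i[:, t]),
                    df * f[:, t] * (1.0 - f[:, t]),
                    dg * (1.0 - g[:, t] * g[:, t]),
                    do * o[:, t] * (1.0 - o[:, t]),
                ], axis=1)
                h_prev = hs[:, t - 1] if t > 0 else np.zeros((B_, L), dtype=self.dtype)
                dWx += x_in[:, t].T @ da
                dWh += h_prev.T @ da
                db += da.sum(axis=0)
                dx[:, t] = da @ Wx.T
                dh_next = da @ Wh.T
                dc_next = dc * f[:, t]
            grads[f"lstm{l}_Wx"] = dWx
            grads[f"lstm{l}_Wh"] = dWh
            grads[f"lstm{l}_b"] = db
            mask = cache["dropout"][drop_iter]
            drop_iter -= 1
            if mask is not None:
                dx = dx * mask
            dh_seq_ext = dx

        dh = dh_seq_ext
        k = cfg.kernel_frames
        for l in range(cfg.conv_layers - 1, -1, -1):
            x_in, relu_mask = cache["conv"][l]
            dy = dh * relu_mask
            W = self.params[f"conv{l}_W"]
            dW = np.zeros_like(W)
            t_out = dy.shape[1]
            dx = np.zeros_like(x_in)
            for j in range(k):
                dW[j] = np.tensordot(x_in[:, j:j + t_out, :], dy, axes=([0, 1], [0, 1]))
                dx[:, j:j + t_out, :] += np.tensordot(dy, W[j], axes=([2], [1]))
            grads[f"conv{l}_W"] = dW
            grads[f"conv{l}_b"] = dy.sum(axis=(0, 1))
            dh = dx
        return loss, grads

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_params(self, params: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = params[k].astype(self.dtype)

    def n_parameters(self) -> int:
        return int(sum(v.size for v in self.params.values()))


def build_model(cfg: ModelConfig, seed: int = 0, dtype=np.float32) -> ConvLSTMClassifier:
    """Instantiate an untrained network with seeded initialization."""
    return ConvLSTMClassifier(cfg, seed=seed, dtype=dtype)


@dataclass
class TrainedModel:
    """A trained network plus its configuration and training history."""

    model: ConvLSTMClassifier
    model_config: ModelConfig
    train_config: TrainConfig
    history: dict[str, list] = field(default_factory=dict)
    best_epoch: int = -1
    best_val_f1: float = float("nan")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(X)

    def save(self, path) -> None:
        meta = {
            "model_config": asdict(self.model_config),
            "train_config": asdict(self.train_config),
            "best_epoch": self.best_epoch,
            "best_val_f1": self.best_val_f1,
            "history": self.history,
        }
        np.savez(path, __meta__=json.dumps(meta), **self.model.params)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            params = {k: z[k] for k in z.files if k != "__meta__"}
        mcfg = ModelConfig(**meta["model_config"])
        tcfg = TrainConfig(**meta["train_config"])
        net = ConvLSTMClassifier(mcfg, seed=tcfg.seed)
        net.load_params(params)
        return cls(model=net, model_config=mcfg, train_config=tcfg,
                   history=meta["history"], best_epoch=meta["best_epoch"],
                   best_val_f1=meta["best_val_f1"])


def _window_accuracy(net: ConvLSTMClassifier, ds: WindowedDataset) -> float:
    probs = net.predict_proba(ds.windows)
    return float((probs.argmax(axis=1) == ds.labels).mean())


def train_model(
    net: ConvLSTMClassifier,
    data: WindowedDataset,
    val: WindowedDataset | None,
    tcfg: TrainConfig,
) -> TrainedModel:
    """Mini-batch SGD with momentum; early stop on validation micro-F1.

    The validation metric is window-level micro-averaged F1, which for
    single-label multiclass prediction equals plain accuracy; the
    parameters of the best validation epoch are retained.  With no
    validation set, training runs for ``max_epochs``.
    """
    if data.n_windows == 0:
        raise ValueError("training dataset is empty")
    if data.labels.max(initial=0) >= net.cfg.n_classes:
        raise ValueError("training label index exceeds n_classes")
    rng = np.random.default_rng(tcfg.seed)
    velocity = {k: np.zeros_like(v) for k, v in net.params.items()}
    history: dict[str, list] = {"loss": [], "val_f1": []}
    best_params = net.copy_params()
    best_f1 = -np.inf
    best_epoch = -1
    stale = 0
    use_val = val is not None and val.n_windows > 0

    for epoch in range(tcfg.max_epochs):
        order = rng.permutation(data.n_windows)
        losses = []
        for s in range(0, data.n_windows, tcfg.batch_size):
            idx = order[s:s + tcfg.batch_size]
            loss, grads = net.loss_and_grads(data.windows[idx], data.labels[idx], rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {s // tcfg.batch_size}: "
                    f"{loss}; try a smaller learning rate")
            losses.append(loss)
            for k, gkv in grads.items():
                v = velocity[k]
                v *= tcfg.momentum
                v += gkv
                net.params[k] -= (tcfg.learning_rate * v).astype(net.dtype)
        history["loss"].append(float(np.mean(losses)))

        if use_val:
            f1 = _window_accuracy(net, val)
            history["val_f1"].append(f1)
            if f1 > best_f1:
                best_f1 = f1
                best_epoch = epoch
                best_params = net.copy_params()
                stale = 0
            else:
                stale += 1
                if stale >= tcfg.patience:
                    break
        else:
            history["val_f1"].append(float("nan"))
            best_epoch = epoch

    if use_val:
        net.load_params(best_params)
    return TrainedModel(model=net, model_config=net.cfg, train_config=tcfg,
                        history=history, best_epoch=best_epoch,
                        best_val_f1=float(best_f1) if use_val else float("nan"))


def predict_window_proba(model: TrainedModel | ConvLSTMClassifier,
                         windows: np.ndarray) -> np.ndarray:
    """Per-window class probabilities; rows sum to 1."""
    net = model.model if isinstance(model, TrainedModel) else model
    return net.predict_proba(windows)
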