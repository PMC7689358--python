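"""Network assembly, training loop and results.

``NetworkModel`` follows the Model/Results convention: it is constructed
from training (and optionally validation) data plus a :class:`NetworkSpec`;
``fit(TrainConfig)`` runs seeded minibatch Adam on the mean squared error
and returns a :class:`TrainedNetworkResults` with the selected weights.

Protocol details: phenotypes are centered per trait on the training set
(the stored offset is added back at prediction); genotypes enter as raw
0/1/2 dosages.  In early-stop mode the validation predictive ability
(Pearson correlation, averaged over traits) is computed after every epoch
and the weights of the best epoch — earliest on ties — are restored.  In
fixed-epoch mode validation data is ignored entirely.  Dropout is active
only during training batches, implemented as inverted dropout.
"""
from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from .layers import Conv1D, Dense, LocalConv1D, relu
from .spec import NetworkSpec, TrainConfig, count_parameters

__all__ = ["Network", "NetworkModel", "TrainedNetworkResults", "build_network"]


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


class Network:
    """Assembled network: optional (local) conv, FC hiddens, linear output."""

    def __init__(self, spec: NetworkSpec, p: int, seed: int = 0):
        self.spec = spec
        self.p = p
        rng = np.random.default_rng(seed)
        self.layers: list = []
        width = p
        if spec.has_conv:
            k, s = spec.kernel_size, spec.effective_stride
            if spec.model_class == "CNN":
                conv = Conv1D(p, k, s, spec.n_filters, rng)
            else:
                conv = LocalConv1D(p, k, s, rng)
            self.layers.append(conv)
            width = conv.n_out
        for nodes in spec.fcl_nodes:
            self.layers.append(Dense(width, nodes, rng))
            width = nodes
        self.out = Dense(width, spec.n_outputs, rng)

    @property
    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params)
        out.extend(self.out.params)
        return out

    @property
    def n_params(self) -> int:
        return count_parameters(self.spec, self.p)

    def forward(self, X: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Forward pass; dropout masks are drawn only when ``training``."""
        rate = self.spec.dropout_rate
        self._relu_masks = []
        self._drop_masks = []
        H = X
        for layer in self.layers:
            Z = layer.forward(H, cache=training)
            A = relu(Z)
            if training:
                self._relu_masks.append(Z > 0)
                if rate > 0.0:
                    mask = (rng.random(A.shape) >= rate) / (1.0 - rate)
                    A = A * mask
                    self._drop_masks.append(mask)
                else:
                    self._drop_masks.append(None)
            H = A
        return self.out.forward(H, cache=training)

    def backward(self, dY: np.ndarray):
        """Gradients for all params given dLoss/dOutput; call after a cached
        training forward pass."""
        grads: list = []
        dH, g_out = self.out.backward(dY)
        grads.extend(g_out)
        for layer, zmask, dmask in zip(reversed(self.layers),
                                       reversed(self._relu_masks),
                                       reversed(self._drop_masks)):
            if dmask is not None:
                dH = dH * dmask
            dH = dH * zmask
            dH, g = layer.backward(dH)
            grads = list(g) + grads
        return grads


def build_network(spec: NetworkSpec, p: int, seed: int = 0) -> Network:
    """Deterministically initialized network for ``spec`` on p markers."""
    return Network(spec, p, seed)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else np.nan


@dataclass
class TrainedNetworkResults:
    """Trained network plus training diagnostics."""

    model: "NetworkModel"
    network: Network
    config: TrainConfig
    selected_epoch: int
    val_history: list[float] = field(default_factory=list)
    loss_history: list[float] = field(default_factory=list)
    y_mean: np.ndarray = None  # type: ignore[assignment]

    @property
    def n_params(self) -> int:
        return self.network.n_params

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Deterministic predictions (dropout off), phenotype scale.

        Returns an (n,) vector for single-trait networks, else (n, T)."""
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.network.p:
            raise ValueError(
                f"expected input with {self.network.p} marker columns")
        out = self.network.forward(X, training=False) + self.y_mean
        return out[:, 0] if self.network.spec.n_outputs == 1 else out

    def summary(self) -> str:
        spec = self.network.spec
        lines = [
            f"{spec.model_class} fit ({self.config.mode})",
            "=" * 40,
            f"{'trainable parameters':<26}{self.n_params:>12,d}",
            f"{'selected epoch':<26}{self.selected_epoch:>12d}",
            f"{'final training loss':<26}{self.loss_history[-1]:>12.5f}",
        ]
        if self.val_history:
            lines.append(f"{'best validation r':<26}"
                         f"{max(self.val_history):>12.4f}")
        return "\n".join(lines)


class NetworkModel:
    """An ANN predictor bound to training (and optional validation) data.

    ``y`` may be a vector (single trait) or an (n, T) matrix (multi-trait
    head; the loss is the unweighted sum of per-trait MSEs).
    """

    def __init__(self, y_train, X_train, spec: NetworkSpec,
                 y_val=None, X_val=None):
        X = np.asarray(X_train, dtype=np.float64)
        y = np.asarray(y_train, dtype=np.float64)
        if y.ndim == 1:
            y = y[:, None]
        if X.ndim != 2 or y.shape[0] != X.shape[0]:
            raise ValueError("X_train and y_train are misaligned")
        if y.shape[1] != spec.n_outputs:
            raise ValueError(f"spec declares {spec.n_outputs} outputs but y has "
                             f"{y.shape[1]} trait columns")
        self.X, self.y, self.spec = X, y, spec
        if X_val is not None:
            Xv = np.asarray(X_val, dtype=np.float64)
            yv = np.asarray(y_val, dtype=np.float64)
            if yv.ndim == 1:
                yv = yv[:, None]
            if Xv.shape[0] != yv.shape[0] or Xv.shape[1] != X.shape[1]:
                raise ValueError("validation data misaligned with training data")
            self.X_val, self.y_val = Xv, yv
        else:
            self.X_val = self.y_val = None

    def fit(self, config: TrainConfig | None = None) -> TrainedNetworkResults:
        config = config or TrainConfig()
        early = config.mode == "early_stop"
        if early and self.X_val is None:
            raise ValueError("early_stop mode requires a validation set")
        rng = np.random.default_rng(config.seed)
        net = Network(self.spec, self.X.shape[1], seed=config.seed)
        opt = _Adam(net.params, lr=config.learning_rate)
        y_mean = self.y.mean(axis=0)
        yc = self.y - y_mean
        n = self.X.shape[0]
        B = min(config.batch_size, n)

        loss_history: list[float] = []
        val_history: list[float] = []
        best_r, best_epoch, best_params = -np.inf, 1, None
        for epoch in range(1, config.max_epochs + 1):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, B):
                batch = order[start:start + B]
                Xb, yb = self.X[batch], yc[batch]
                pred = net.forward(Xb, training=True, rng=rng)
                err = pred - yb
                # sum of per-trait MSEs over the batch
                loss = float((err * err).sum() / len(batch))
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"NaN/inf training loss at epoch {epoch}")
                grads = net.backward(2.0 * err / len(batch))
                opt.step(net.params, grads)
                epoch_loss += loss * len(batch)
            loss_history.append(epoch_loss / n)
            if early:
                pv = net.forward(self.X_val, training=False)
                rs = np.array([_pearson(pv[:, t], self.y_val[:, t])
                               for t in range(pv.shape[1])])
                finite = rs[np.isfinite(rs)]
                r = float(finite.mean()) if finite.size else float("nan")
                val_history.append(r)
                if r > best_r:  # strict: earliest epoch wins ties
                    best_r, best_epoch = r, epoch
                    best_params = [p.copy() for p in net.params]
        if early and best_params is not None:
            for p, bp in zip(net.params, best_params):
                p[...] = bp
            selected = best_epoch
        else:
            selected = config.max_epochs
        return TrainedNetworkResults(
            model=self, network=net, config=config, selected_epoch=selected,
            val_history=val_history, loss_history=loss_history, y_mean=y_mean)
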