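"""Declarative network and training configuration, plus parameter accounting.

The three baseline architectures compared throughout the benchmark are

* MLP:  two fully connected hidden layers of 64 nodes
* CNN:  one shared-filter convolution (kernel 10, stride 10, 1 filter)
        in front of the same two hidden layers
* LCNN: one *local* convolutional layer (kernel 10, stride 10, unshared
        window weights) in front of the same two hidden layers

All use ReLU activations on hidden layers, a linear output per trait,
dropout 0.3 after each hidden layer, and are trained with Adam on the MSE.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

from .layers import n_windows

__all__ = ["NetworkSpec", "TrainConfig", "count_parameters", "layer_breakdown",
           "conv_layer_parameters", "mlp_baseline", "cnn_baseline",
           "lcnn_baseline"]

_MODEL_CLASSES = ("MLP", "CNN", "LCNN")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture description of one predictor network.

    ``stride`` of ``None`` means stride = kernel_size (non-overlapping
    windows).  ``conv`` fields are ignored for the MLP class.
    """

    model_class: str
    fcl_nodes: tuple[int, ...] = (64, 64)
    kernel_size: int = 10
    stride: int | None = None
    n_filters: int = 1
    n_outputs: int = 1
    dropout_rate: float = 0.3

    def __post_init__(self):
        if self.model_class not in _MODEL_CLASSES:
            raise ValueError(f"model_class must be one of {_MODEL_CLASSES}")
        object.__setattr__(self, "fcl_nodes", tuple(int(x) for x in self.fcl_nodes))
        if any(x < 1 for x in self.fcl_nodes):
            raise ValueError("fcl_nodes must be positive")
        if self.n_outputs < 1:
            raise ValueError("n_outputs must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.has_conv and self.kernel_size < 1:
            raise ValueError("kernel_size must be positive")

    @property
    def has_conv(self) -> bool:
        return self.model_class in ("CNN", "LCNN")

    @property
    def effective_stride(self) -> int:
        return self.kernel_size if self.stride is None else self.stride

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol.

    ``mode="early_stop"`` evaluates validation predictive ability after each
    of up to ``max_epochs`` (default 50) epochs and keeps the best epoch's
    weights; ``mode="fixed"`` runs exactly ``max_epochs`` (default 25) epochs
    and needs no validation set.
    """

    mode: str = "early_stop"
    max_epochs: int | None = None
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("early_stop", "fixed"):
            raise ValueError("mode must be 'early_stop' or 'fixed'")
        if self.max_epochs is None:
            object.__setattr__(self, "max_epochs",
                               50 if self.mode == "early_stop" else 25)
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be positive")


def mlp_baseline(n_outputs: int = 1) -> NetworkSpec:
    return NetworkSpec("MLP", n_outputs=n_outputs)


def cnn_baseline(n_outputs: int = 1) -> NetworkSpec:
    return NetworkSpec("CNN", n_outputs=n_outputs)


def lcnn_baseline(n_outputs: int = 1) -> NetworkSpec:
    return NetworkSpec("LCNN", n_outputs=n_outputs)


def layer_breakdown(spec: NetworkSpec, p: int) -> list[tuple[str, int, int]]:
    """Per-layer (name, n_weights, n_intercepts) for a spec on p markers."""
    rows: list[tuple[str, int, int]] = []
    width = p
    if spec.has_conv:
        k, s = spec.kernel_size, spec.effective_stride
        nw = n_windows(p, k, s)
        if spec.model_class == "CNN":
            rows.append(("conv", spec.n_filters * k, spec.n_filters))
            width = nw * spec.n_filters
        else:
            rows.append(("local_conv", nw * k, nw))
            width = nw
    for i, nodes in enumerate(spec.fcl_nodes, start=1):
        rows.append((f"fcl{i}", width * nodes, nodes))
        width = nodes
    rows.append(("output", width * spec.n_outputs, spec.n_outputs))
    return rows


def conv_layer_parameters(kernel_size: int, n_filters: int = 1) -> int:
    """Trainable parameters of a shared convolutional filter bank alone:
    n_filters * kernel_size weights plus one intercept per filter (a single
    kernel-10 filter counts 11)."""
    if kernel_size < 1 or n_filters < 1:
        raise ValueError("kernel_size and n_filters must be positive")
    return n_filters * kernel_size + n_filters


def count_parameters(spec: NetworkSpec, p: int, weights_only: bool = False) -> int:
    """Exact count of trainable parameters (weights + intercepts).

    A single shared filter of kernel 10 counts 11 (10 weights + intercept);
    a local conv layer counts n_windows * (k + 1); a fully connected layer
    counts in*out weights + out intercepts.
    """
    rows = layer_breakdown(spec, p)
    if weights_only:
        return sum(w for _, w, _ in rows)
    return sum(w + b for _, w, b in rows)
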