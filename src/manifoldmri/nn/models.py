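"""Trainable GNN node classifiers built on the autograd tensors.

Each architecture is two message-passing layers at the widths reported for
this task (GCN 2x64 dropout 0.5; GAT 64 units with 8 heads then 64 with one
head, dropout 0.6; GraphSAGE 2x128 dropout 0.6) followed by a linear softmax
head to the class count.  Hidden weights are Glorot-uniform and
seed-controlled; the output head is zero-initialized so initial logits are
uniform and the first gradient steps move coherently toward the class
structure — at the small configured learning rate a randomly initialized
head would start with logit gaps too large to reorder within the epoch
budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import layers
from .autograd import Tensor, concat, parameter

_ARCHS = ("gcn", "gat", "sage")


@dataclass
class ModelConfig:
    arch: str = "gcn"
    hidden_units: int = 64
    n_layers: int = 2
    dropout: float = 0.5
    heads_layer1: int = 8
    heads_layer2: int = 1
    n_classes: int = 4

    def __post_init__(self):
        if self.arch not in _ARCHS:
            raise ValueError(f"arch must be one of {_ARCHS}")
        if self.hidden_units <= 0 or self.n_layers <= 0 or self.n_classes < 2:
            raise ValueError("invalid model configuration")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")

    @classmethod
    def for_arch(cls, arch: str, n_classes: int = 4) -> "ModelConfig":
        """Per-architecture defaults used throughout the pipeline."""
        if arch == "gcn":
            return cls(arch="gcn", hidden_units=64, dropout=0.5,
                       n_classes=n_classes)
        if arch == "gat":
            return cls(arch="gat", hidden_units=64, dropout=0.6,
                       heads_layer1=8, heads_layer2=1, n_classes=n_classes)
        if arch == "sage":
            return cls(arch="sage", hidden_units=128, dropout=0.6,
                       n_classes=n_classes)
        raise ValueError(f"unknown arch {arch!r}")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


def _dropout(x: Tensor, p: float, training: bool,
             rng: np.random.Generator) -> Tensor:
    if not training or p <= 0:
        return x
    keep = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * Tensor(keep)


class _BaseModel:
    """Common parameter bookkeeping for the three architectures."""

    config: ModelConfig

    def __init__(self):
        self.params: dict[str, Tensor] = {}

    def _add_param(self, name: str, value: np.ndarray) -> Tensor:
        t = parameter(value)
        self.params[name] = t
        return t

    def parameters(self):
        return list(self.params.values())

    def state(self) -> dict:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state(self, state: dict) -> None:
        for k, v in state.items():
            self.params[k].data = v.copy()

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None


class GCNModel(_BaseModel):
    def __init__(self, n_features: int, config: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        h, k = config.hidden_units, config.n_classes
        self._add_param("W1", _glorot(rng, n_features, h))
        self._add_param("W2", _glorot(rng, h, h))
        self._add_param("W_out", np.zeros((h, k)))  # zero-init head
        self._add_param("b_out", np.zeros((1, k)))

    def prepare(self, A: np.ndarray) -> dict:
        return {"A_norm": Tensor(layers.normalize_adjacency(A))}

    def forward(self, X: Tensor, cache: dict, training: bool,
                rng: np.random.Generator) -> Tensor:
        p = self.config.dropout
        A = cache["A_norm"]
        h = _dropout(X, p, training, rng)
        h = (A @ (h @ self.params["W1"])).relu()
        h = _dropout(h, p, training, rng)
        h = (A @ (h @ self.params["W2"])).relu()
        return h @ self.params["W_out"] + self.params["b_out"]


class GATModel(_BaseModel):
    def __init__(self, n_features: int, config: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        h, k = config.hidden_units, config.n_classes
        for head in range(config.heads_layer1):
            self._add_param(f"W1_{head}", _glorot(rng, n_features, h))
            self._add_param(f"a1_{head}", _glorot(rng, 2 * h, 1))
        in2 = h * config.heads_layer1
        for head in range(config.heads_layer2):
            self._add_param(f"W2_{head}", _glorot(rng, in2, h))
            self._add_param(f"a2_{head}", _glorot(rng, 2 * h, 1))
        self._add_param("W_out", np.zeros((h, k)))  # zero-init head
        self._add_param("b_out", np.zeros((1, k)))

    def prepare(self, A: np.ndarray) -> dict:
        mask = (np.asarray(A) > 0) | np.eye(A.shape[0], dtype=bool)
        return {"mask": mask.astype(float)}

    def _head(self, H: Tensor, W: Tensor, a: Tensor, mask: np.ndarray) -> Tensor:
        HW = H @ W
        f = W.shape[1]
        a_src = Tensor(np.eye(2 * f)[:f]) @ a   # (f, 1) slice of a
        a_dst = Tensor(np.eye(2 * f)[f:]) @ a
        s_src = HW @ a_src                       # (n, 1)
        s_dst = HW @ a_dst
        logits = (s_src + s_dst.T).leaky_relu(0.2)
        # mask non-edges with a large negative constant; subtract the
        # detached row max (softmax is shift-invariant) for stability
        masked = logits * Tensor(mask) + Tensor((1.0 - mask) * -1e30)
        shift = masked.data.max(axis=1, keepdims=True)
        expo = (masked - Tensor(shift)).exp() * Tensor(mask)
        alpha = expo / expo.sum(axis=1, keepdims=True)
        return alpha @ HW

    def forward(self, X: Tensor, cache: dict, training: bool,
                rng: np.random.Generator) -> Tensor:
        cfg = self.config
        mask = cache["mask"]
        p = cfg.dropout
        h = _dropout(X, p, training, rng)
        heads = [
            self._head(h, self.params[f"W1_{i}"], self.params[f"a1_{i}"], mask).relu()
            for i in range(cfg.heads_layer1)
        ]
        h = concat(heads, axis=1)
        h = _dropout(h, p, training, rng)
        outs = [
            self._head(h, self.params[f"W2_{i}"], self.params[f"a2_{i}"], mask)
            for i in range(cfg.heads_layer2)
        ]
        acc = outs[0]
        for o in outs[1:]:
            acc = acc + o
        h = (acc * Tensor(np.array(1.0 / cfg.heads_layer2))).relu()
        return h @ self.params["W_out"] + self.params["b_out"]


class SAGEModel(_BaseModel):
    def __init__(self, n_features: int, config: ModelConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        h, k = config.hidden_units, config.n_classes
        self._add_param("W1", _glorot(rng, 2 * n_features, h))
        self._add_param("W2", _glorot(rng, 2 * h, h))
        self._add_param("W_out", np.zeros((h, k)))  # zero-init head
        self._add_param("b_out", np.zeros((1, k)))

    def prepare(self, A: np.ndarray) -> dict:
        neigh = layers.adjacency_to_neighbor_lists(A)
        return {"M": Tensor(layers.neighbor_mean_matrix(neigh))}

    def forward(self, X: Tensor, cache: dict, training: bool,
                rng: np.random.Generator) -> Tensor:
        p = self.config.dropout
        M = cache["M"]
        h = _dropout(X, p, training, rng)
        h = (concat([h, M @ h], axis=1) @ self.params["W1"]).relu()
        h = _dropout(h, p, training, rng)
        h = (concat([h, M @ h], axis=1) @ self.params["W2"]).relu()
        return h @ self.params["W_out"] + self.params["b_out"]


def build_model(n_features: int, config: ModelConfig, seed: int = 0):
    rng = np.random.default_rng(seed)
    if config.arch == "gcn":
        return GCNModel(n_features, config, rng)
    if config.arch == "gat":
        return GATModel(n_features, config, rng)
    if config.arch == "sage":
        return SAGEModel(n_features, config, rng)
    raise ValueError(f"unknown arch {config.arch!r}")
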