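"""Full-batch node-classification training on the manifold graph.

Protocol: stratified 80-20 train/test split with a further 20% of the
training nodes held out for validation; weighted cross-entropy with class
weights N/(K*N_c); Adam at learning rate 1e-4 with global gradient-norm
clipping at 1.0; dropout active only during training; early stopping on
validation accuracy with best-parameter restoration.  Everything is
deterministic given the seed.

Each epoch shuffles the training nodes and takes one Adam step per
mini-batch of ``batch_size`` of them (the forward pass always spans the
whole graph; only the loss is restricted to the mini-batch).  At the small
configured learning rate the extra steps per epoch are what allow
convergence within the 100-epoch budget.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from ..metrics import ClassificationReport, evaluate_classification
from .autograd import Tensor
from .models import ModelConfig, build_model


@dataclass
class TrainConfig:
    learning_rate: float = 1e-4
    grad_clip_norm: float = 1.0
    max_epochs: int = 100
    early_stop_patience: int = 10
    batch_size: int = 16  # training-node mini-batch for the loss
    test_fraction: float = 0.2
    val_fraction_of_train: float = 0.2
    class_weighting: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.test_fraction < 1) or not (0 < self.val_fraction_of_train < 1):
            raise ValueError("fractions must lie in (0, 1)")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, clip_norm: float | None = None) -> None:
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
            if total > clip_norm:
                grads = [g * (clip_norm / total) for g in grads]
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data = p.data - self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def class_weights(y: np.ndarray, n_classes: int) -> np.ndarray:
    """Balanced weights N / (K * N_c) from integer-encoded training labels."""
    counts = np.bincount(y, minlength=n_classes)
    if np.any(counts == 0):
        raise ValueError("every class must appear in the training labels")
    return y.size / (n_classes * counts.astype(float))


def weighted_cross_entropy(logits: Tensor, y: np.ndarray,
                           weights: np.ndarray) -> Tensor:
    """Mean weighted cross-entropy from raw logits (numerically stable)."""
    n, k = logits.shape
    shift = logits.data.max(axis=1, keepdims=True)  # detached, shift-invariant
    z = logits - Tensor(shift)
    lse = z.exp().sum(axis=1, keepdims=True).log()
    onehot = np.zeros((n, k))
    onehot[np.arange(n), y] = 1.0
    picked = (z * Tensor(onehot)).sum(axis=1, keepdims=True)
    w = weights[y][:, None]
    return ((lse - picked) * Tensor(w)).sum() * Tensor(np.array(1.0 / w.sum()))


def stratified_splits(y: np.ndarray, cfg: TrainConfig):
    idx = np.arange(y.size)
    trainval, test = train_test_split(
        idx, test_size=cfg.test_fraction, stratify=y, random_state=cfg.seed
    )
    train, val = train_test_split(
        trainval, test_size=cfg.val_fraction_of_train, stratify=y[trainval],
        random_state=cfg.seed + 1,
    )
    return np.sort(train), np.sort(val), np.sort(test)


def train_node_classifier(
    tensors,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> tuple[dict, pd.DataFrame, ClassificationReport]:
    """Train a GNN node classifier and evaluate it on the held-out nodes.

    ``tensors`` is the (node features, adjacency, labels) triple produced by
    :func:`manifoldmri.graph.graph_tensors`.  Returns the trained parameter
    arrays, a per-epoch history frame, and the test-set classification
    report.
    """
    X, A, labels = tensors
    X = np.asarray(X, float)
    labels = np.asarray(labels)
    class_order = sorted(set(str(l) for l in labels))
    if model_config.n_classes != len(class_order):
        model_config = ModelConfig(**{**model_config.__dict__,
                                      "n_classes": len(class_order)})
    enc = {c: i for i, c in enumerate(class_order)}
    y = np.asarray([enc[str(l)] for l in labels])
    for c, i in enc.items():
        if np.sum(y == i) < 2:
            raise ValueError(
                f"class {c!r} has fewer than 2 nodes; cannot split"
            )

    idx_train, idx_val, idx_test = stratified_splits(y, train_config)
    for name, part in (("train", idx_train), ("validation", idx_val),
                       ("test", idx_test)):
        if len(np.unique(y[part])) < len(class_order):
            raise ValueError(
                f"a class is absent from the {name} split; adjust fractions"
            )

    model = build_model(X.shape[1], model_config, seed=train_config.seed)
    cache = model.prepare(A)
    Xt = Tensor(X)
    if train_config.class_weighting:
        weights = class_weights(y[idx_train], len(class_order))
    else:
        weights = np.ones(len(class_order))
    optimizer = Adam(model.parameters(), lr=train_config.learning_rate)
    drop_rng = np.random.default_rng(train_config.seed + 2)

    def predict() -> np.ndarray:
        logits = model.forward(Xt, cache, training=False, rng=drop_rng)
        return logits.data.argmax(axis=1)

    history = []
    best_val, best_state, since_improve = -np.inf, model.state(), 0
    eye = np.eye(y.size)
    for epoch in range(train_config.max_epochs):
        order = drop_rng.permutation(idx_train)
        epoch_loss = 0.0
        for start in range(0, order.size, train_config.batch_size):
            batch_idx = order[start:start + train_config.batch_size]
            model.zero_grad()
            logits = model.forward(Xt, cache, training=True, rng=drop_rng)
            loss = weighted_cross_entropy(
                Tensor(eye[batch_idx]) @ logits, y[batch_idx], weights
            )
            loss.backward()
            optimizer.step(clip_norm=train_config.grad_clip_norm)
            epoch_loss += float(loss.data) * batch_idx.size
        epoch_loss /= order.size

        pred = predict()
        train_acc = float(np.mean(pred[idx_train] == y[idx_train]))
        val_acc = float(np.mean(pred[idx_val] == y[idx_val]))
        history.append({"epoch": epoch, "train_loss": epoch_loss,
                        "train_acc": train_acc, "val_acc": val_acc})
        if val_acc > best_val:
            best_val, best_state, since_improve = val_acc, model.state(), 0
        else:
            since_improve += 1
            if since_improve >= train_config.early_stop_patience:
                break

    model.load_state(best_state)
    pred = predict()
    report = evaluate_classification(
        [class_order[i] for i in y[idx_test]],
        [class_order[i] for i in pred[idx_test]],
        class_order,
    )
    return model.state(), pd.DataFrame(history), report
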