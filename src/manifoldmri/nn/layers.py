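"""Graph neural network layer primitives.

Functional, NumPy-level implementations of the three layer families used on
the manifold graph:

* GCN: ``sigma(D~^-1/2 (A + I) D~^-1/2 H W)`` — symmetric normalized
  propagation with self-loops.
* GAT: per-head attention logits ``e_ij = LeakyReLU(a^T [W h_i || W h_j])``
  softmax-normalized over ``N(i) ∪ {i}``, heads concatenated at hidden
  layers and averaged at the output layer.
* GraphSAGE: mean aggregation ``sigma(W [h_i || mean_{j in N(i)} h_j])``
  with the 2F x F' weight shape; an isolated node aggregates itself.

These functions are the reference forward passes; the trainable models in
:mod:`manifoldmri.nn.models` express the same math on autograd tensors.
"""

from __future__ import annotations

import numpy as np

_BIG_NEG = -1e30


def identity(x):
    return x


def relu(x):
    return np.maximum(x, 0.0)


def normalize_adjacency(A: np.ndarray) -> np.ndarray:
    """Symmetric GCN normalization with self-loops: D~^-1/2 (A+I) D~^-1/2."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if np.any(A < 0):
        raise ValueError("A must be nonnegative")
    if np.max(np.abs(A - A.T)) > 1e-10 * max(1.0, np.max(np.abs(A)) or 1.0):
        raise ValueError("A must be symmetric")
    A_tilde = A + np.eye(A.shape[0])
    d_inv_sqrt = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    return A_tilde * d_inv_sqrt[:, None] * d_inv_sqrt[None, :]


def gcn_forward(H: np.ndarray, A_norm: np.ndarray, W: np.ndarray,
                activation=relu) -> np.ndarray:
    """One GCN layer: activation(A_norm @ H @ W)."""
    H, A_norm, W = (np.asarray(x, float) for x in (H, A_norm, W))
    if A_norm.shape[1] != H.shape[0] or H.shape[1] != W.shape[0]:
        raise ValueError("shape mismatch in gcn_forward")
    return activation(A_norm @ H @ W)


def edges_to_masks(edges, n_nodes: int, add_self_loops: bool = True) -> np.ndarray:
    """Dense boolean neighborhood mask from an undirected edge list."""
    mask = np.zeros((n_nodes, n_nodes), dtype=bool)
    for i, j in edges:
        mask[i, j] = mask[j, i] = True
    if add_self_loops:
        np.fill_diagonal(mask, True)
    return mask


def gat_attention(H, W, a, mask, leaky_slope: float = 0.2):
    """Attention coefficients of one head over the masked neighborhoods.

    ``a`` has length 2F' and splits into source/destination halves, so the
    logit matrix is a_src . (HW) broadcast against its transpose.
    """
    HW = H @ W
    f = W.shape[1]
    a = np.asarray(a, float).reshape(2 * f)
    s_src = HW @ a[:f]
    s_dst = HW @ a[f:]
    logits = s_src[:, None] + s_dst[None, :]
    logits = np.where(logits > 0, logits, leaky_slope * logits)
    logits = np.where(mask, logits, _BIG_NEG)
    logits = logits - logits.max(axis=1, keepdims=True)
    expo = np.exp(logits) * mask
    alpha = expo / expo.sum(axis=1, keepdims=True)
    return alpha, HW


def gat_forward(
    H: np.ndarray,
    edges,
    W_heads,
    a_heads,
    combine: str = "concat",
    activation=relu,
    leaky_slope: float = 0.2,
) -> np.ndarray:
    """Multi-head GAT layer on an undirected edge list (self-loops implied)."""
    H = np.asarray(H, float)
    if combine not in ("concat", "average"):
        raise ValueError("combine must be 'concat' or 'average'")
    n = H.shape[0]
    mask = edges_to_masks(edges, n, add_self_loops=True)
    outs = []
    for W, a in zip(W_heads, a_heads):
        alpha, HW = gat_attention(H, np.asarray(W, float), a, mask, leaky_slope)
        outs.append(activation(alpha @ HW))
    if combine == "concat":
        return np.concatenate(outs, axis=1)
    return np.mean(outs, axis=0)


def neighbor_mean_matrix(neighbor_lists) -> np.ndarray:
    """Row-stochastic aggregation matrix M with M[i] averaging N(i).

    An empty neighborhood falls back to the node itself, so ``M @ H`` always
    produces a well-defined neighbor mean.
    """
    n = len(neighbor_lists)
    M = np.zeros((n, n))
    for i, neigh in enumerate(neighbor_lists):
        neigh = list(neigh)
        if neigh:
            M[i, neigh] = 1.0 / len(neigh)
        else:
            M[i, i] = 1.0
    return M


def sage_forward(H: np.ndarray, neighbor_lists, W: np.ndarray,
                 activation=relu) -> np.ndarray:
    """One GraphSAGE mean-aggregator layer: sigma([h_i || mean N(i)] W)."""
    H = np.asarray(H, float)
    W = np.asarray(W, float)
    if W.shape[0] != 2 * H.shape[1]:
        raise ValueError("W must have shape (2F, F') for the concatenated input")
    M = neighbor_mean_matrix(neighbor_lists)
    combined = np.concatenate([H, M @ H], axis=1)
    return activation(combined @ W)


def adjacency_to_neighbor_lists(A: np.ndarray) -> list:
    """Neighbor lists from a (weighted) adjacency matrix, excluding self."""
    A = np.asarray(A)
    return [
        [int(j) for j in np.flatnonzero(A[i]) if j != i]
        for i in range(A.shape[0])
    ]
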