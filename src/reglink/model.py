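"""GCN encoder and rectified dot-product decoder, dense NumPy implementation.

The encoder stacks layers

    H^(l) = ReLU( P H^(l-1) W^(l-1) + b^(l-1) ),   P = lam * A~ + (1 - lam) * I

where ``A~`` is the symmetric degree-normalised adjacency with self-loops
and ``lam`` (the *mixing coefficient*) interpolates between pure expression
features (lam = 0, no message passing) and pure graph smoothing (lam = 1,
the plain GCN propagation rule).  ``H^(0)`` is the preprocessed gene x cell
expression matrix, so genes are nodes and cells are input feature
dimensions.

The decoder scores every gene pair by a rectified inner product,
``R = ReLU(H H^T)``; because the final encoder layer is a ReLU, ``H >= 0``
and the decoder rectification is inactive in the trained model — it matters
only for externally supplied embeddings.  ``R`` is symmetric, so direction
is imposed downstream by restricting candidates to TF -> gene pairs.

Everything is differentiable by hand: :func:`loss_and_grads` returns the
analytic gradients used by the Adam loop in :mod:`reglink.training`.
ReLU subgradient at 0 is taken as 0 throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ReglinkError
from .graph import NormalizedAdjacency
from .io import ExpressionMatrix


@dataclass
class GCNModel:
    """Per-layer weights/biases of the encoder plus the mixing coefficient.

    ``input_scale`` is a fixed global factor applied to the input features
    before the first layer.  It is calibrated once at the start of training
    so that initial pair scores are O(1) — raw Glorot initialisation on
    nonnegative log-expression features produces scores two orders of
    magnitude above the 0/1 labels, and the resulting MSE gradients drive
    the ReLU units dead within a few epochs.
    """

    weights: list[np.ndarray]  # W^(l), shape (d_{l-1}, d_l); d_0 = n_cells
    biases: list[np.ndarray]  # b^(l), shape (d_l,)
    lambda_mix: float = 0.4
    input_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.weights) < 1 or len(self.weights) != len(self.biases):
            raise ReglinkError("model needs >= 1 layer with matching weight/bias lists")
        if not 0.0 <= self.lambda_mix <= 1.0:
            raise ReglinkError("lambda_mix must lie in [0, 1]")
        for l, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.ndim != 2 or b.shape != (w.shape[1],):
                raise ReglinkError(f"layer {l}: bias shape {b.shape} mismatches W {w.shape}")
            if l > 0 and self.weights[l - 1].shape[1] != w.shape[0]:
                raise ReglinkError(f"layer {l}: input dim mismatches layer {l - 1} output")
            if not (np.all(np.isfinite(w)) and np.all(np.isfinite(b))):
                raise ReglinkError(f"layer {l}: non-finite parameters")

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def output_dim(self) -> int:
        return self.weights[-1].shape[1]

    def copy(self) -> "GCNModel":
        return GCNModel([w.copy() for w in self.weights],
                        [b.copy() for b in self.biases],
                        self.lambda_mix, self.input_scale)

    @classmethod
    def init_glorot(
        cls,
        dims: Sequence[int],
        lambda_mix: float = 0.4,
        seed: int | np.random.Generator = 0,
    ) -> "GCNModel":
        """Glorot-uniform initialised model for a dim chain like (M, 256, 128)."""
        if len(dims) < 2:
            raise ReglinkError("dims must list input dim plus at least one layer")
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        weights, biases = [], []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (d_in + d_out))
            weights.append(rng.uniform(-limit, limit, size=(d_in, d_out)))
            biases.append(np.zeros(d_out))
        return cls(weights, biases, lambda_mix)


@dataclass(frozen=True)
class Embeddings:
    """Final nonnegative gene features H (N x d1), aligned to ``node_ids``."""

    matrix: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        if m.shape[0] != len(self.node_ids):
            raise ReglinkError("embedding rows must align with node_ids")
        if not np.all(np.isfinite(m)):
            raise ReglinkError("embeddings must be finite")


@dataclass(frozen=True)
class ScoreMatrix:
    """Symmetric nonnegative N x N regulatory score matrix R."""

    matrix: np.ndarray
    node_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        object.__setattr__(self, "matrix", m)
        n = len(self.node_ids)
        if m.shape != (n, n):
            raise ReglinkError(f"score matrix shape {m.shape} does not match {n} nodes")
        if np.any(m < 0) or not np.all(np.isfinite(m)):
            raise ReglinkError("scores must be finite and nonnegative")

    def index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.node_ids)}


def propagation_matrix(a_norm: NormalizedAdjacency | np.ndarray, lambda_mix: float) -> np.ndarray:
    """``lam * A~ + (1 - lam) * I`` — the mixed message-passing operator."""
    a = a_norm.matrix if isinstance(a_norm, NormalizedAdjacency) else np.asarray(a_norm)
    return lambda_mix * a + (1.0 - lambda_mix) * np.eye(a.shape[0])


def gcn_layer(
    h_prev: np.ndarray,
    a_norm: NormalizedAdjacency | np.ndarray,
    w: np.ndarray,
    b: np.ndarray,
    lambda_mix: float = 1.0,
) -> np.ndarray:
    """One encoder layer: ``ReLU(P @ h_prev @ w + b)`` with the mixed P.

    At ``lambda_mix = 1`` this is exactly the neighbour-aggregation GCN
    update over the normalised adjacency; at 0 the graph is ignored.
    """
    p = propagation_matrix(a_norm, lambda_mix)
    out = np.maximum(p @ (h_prev @ w) + b, 0.0)
    if not np.all(np.isfinite(out)):
        raise ReglinkError("non-finite layer output (exploding weights?)")
    return out


def _forward(
    x: np.ndarray, p: np.ndarray, model: GCNModel
) -> tuple[list[np.ndarray], list[np.ndarray], list[np.ndarray]]:
    """Forward pass caching (activations H_l, pre-activations Z_l, P @ H_{l-1})."""
    hs, zs, phs = [x], [], []
    h = x
    for w, b in zip(model.weights, model.biases):
        ph = p @ h
        z = ph @ w + b
        h = np.maximum(z, 0.0)
        phs.append(ph)
        zs.append(z)
        hs.append(h)
    return hs, zs, phs


def encode(
    x: ExpressionMatrix, a_norm: NormalizedAdjacency, model: GCNModel
) -> Embeddings:
    """Run the full encoder; the last layer's output is the gene embedding."""
    if x.gene_ids != a_norm.node_ids:
        raise ReglinkError("expression gene order must match the adjacency node order")
    p = propagation_matrix(a_norm, model.lambda_mix)
    h = model.input_scale * x.values
    for l, (w, b) in enumerate(zip(model.weights, model.biases)):
        if h.shape[1] != w.shape[0]:
            raise ReglinkError(
                f"layer {l}: input dim {h.shape[1]} does not match W shape {w.shape}"
            )
        h = np.maximum(p @ (h @ w) + b, 0.0)
        if not np.all(np.isfinite(h)):
            raise ReglinkError(f"layer {l}: non-finite output")
    return Embeddings(h, x.gene_ids)


def decode(h: Embeddings) -> ScoreMatrix:
    """Rectified dot-product decoder ``R = ReLU(H H^T)``."""
    return ScoreMatrix(np.maximum(h.matrix @ h.matrix.T, 0.0), h.node_ids)


def score_pairs(r: ScoreMatrix, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
    """Scores ``R[source, target]`` for each pair, order-preserving."""
    index = r.index()
    try:
        ii = [index[s] for s, _ in pairs]
        jj = [index[t] for _, t in pairs]
    except KeyError as exc:
        raise ReglinkError(f"unknown node in score query: {exc.args[0]!r}") from None
    return r.matrix[ii, jj]


def loss_and_grads(
    x: np.ndarray,
    p: np.ndarray,
    model: GCNModel,
    ii: np.ndarray,
    jj: np.ndarray,
    labels: np.ndarray,
    weight_decay: float,
) -> tuple[float, list[np.ndarray], list[np.ndarray]]:
    """MSE-plus-Frobenius loss and its analytic gradients.

    Loss = mean_k (R[i_k, j_k] - y_k)^2 + weight_decay * sum_l ||W_l||_F^2,
    with R = ReLU(H H^T) from the forward pass.  Returns
    (loss, dL/dW per layer, dL/db per layer).  Biases are not regularised.
    """
    if len(labels) == 0:
        raise ReglinkError("loss requires at least one labelled pair")
    hs, zs, phs = _forward(x, p, model)
    h_last = hs[-1]
    s = h_last @ h_last.T
    r = np.maximum(s, 0.0)
    diff = r[ii, jj] - labels
    loss = float(np.mean(diff**2)) + weight_decay * sum(
        float(np.sum(w * w)) for w in model.weights
    )
    if not np.isfinite(loss):
        raise ReglinkError("non-finite training loss")

    d_r = np.zeros_like(s)
    np.add.at(d_r, (ii, jj), 2.0 * diff / len(labels))
    d_s = d_r * (s > 0)
    d_h = (d_s + d_s.T) @ h_last
    grads_w: list[np.ndarray] = [np.empty(0)] * model.n_layers
    grads_b: list[np.ndarray] = [np.empty(0)] * model.n_layers
    for l in reversed(range(model.n_layers)):
        d_z = d_h * (zs[l] > 0)
        grads_w[l] = phs[l].T @ d_z + 2.0 * weight_decay * model.weights[l]
        grads_b[l] = d_z.sum(axis=0)
        if l > 0:
            d_h = (p.T @ d_z) @ model.weights[l].T
    return loss, grads_w, grads_b


def save_model(model: GCNModel, node_ids: Sequence[str], path: str | Path) -> None:
    """Persist a trained model as a single ``.npz`` checkpoint.

    The archive stores every layer's W/b plus a JSON metadata record with
    the format version, the mixing coefficient and the gene-ID order the
    model was trained on.
    """
    arrays = {f"W{l}": w for l, w in enumerate(model.weights)}
    arrays.update({f"b{l}": b for l, b in enumerate(model.biases)})
    meta = {
        "format_version": 1,
        "n_layers": model.n_layers,
        "lambda_mix": model.lambda_mix,
        "input_scale": model.input_scale,
        "node_ids": list(node_ids),
    }
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_model(path: str | Path) -> tuple[GCNModel, tuple[str, ...]]:
    """Load a checkpoint written by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["meta"]))
        if meta.get("format_version") != 1:
            raise ReglinkError(f"unsupported checkpoint version in {path}")
        weights = [archive[f"W{l}"] for l in range(meta["n_layers"])]
        biases = [archive[f"b{l}"] for l in range(meta["n_layers"])]
    model = GCNModel(weights, biases, meta["lambda_mix"], meta.get("input_scale", 1.0))
    return model, tuple(meta["node_ids"])
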