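"""Per-omics classifier: stacked graph convolutions plus an MLP head.

The model is transductive: every sample (labeled or not) is a node of the
similarity graph and participates in propagation ``H_{l+1} = act(A_norm H_l W_l)``
with ``H_0 = X``, but the cross-entropy loss is masked to training nodes only.
After the graph stack, a two-layer perceptron head maps the node embedding to
class logits; a softmax yields the per-sample class distribution.

With ``K = 1`` the normalized adjacency is the identity and the model is an
ordinary fully connected network applied row by row.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import (
    Activation,
    Adam,
    Dropout,
    GraphConv,
    Linear,
    Sequential,
    softmax,
    softmax_cross_entropy,
)
from .errors import DegenerateLabelsError, TrainingDivergedError
from .omics_io import LabelVector, OmicsMatrix, SplitSpec
from .similarity_graph import SimilarityGraph

CHECKPOINT_VERSION = 1


@dataclass
class GCNConfig:
    """Hyperparameters for one omics-specific classifier.

    ``hidden_units`` fixes both the number of graph-convolution layers and
    their widths (default three layers of 200, 200, 100 units).  The head is a
    two-layer perceptron with one hidden layer of ``mlp_hidden`` units.
    Dropout (on every graph-layer input) plus seed-varied initialization
    supply the stochasticity the trial ensembles rely on.
    """

    hidden_units: tuple[int, ...] = (200, 200, 100)
    activation: str = "relu"
    mlp_hidden: int = 100
    learning_rate: float = 1e-3
    pretrain_epochs: int = 500
    train_epochs: int = 300
    dropout_rate: float = 0.5
    seed: int = 0
    class_count: int = 2

    @property
    def num_gcn_layers(self) -> int:
        return len(self.hidden_units)

    def __post_init__(self) -> None:
        if self.num_gcn_layers < 1:
            raise ValueError("need at least one graph-convolution layer")


def seed_for(base_seed: int, tag: str) -> int:
    """Stable per-component seed: base seed mixed with a CRC of the tag."""
    return int((base_seed * 1_000_003 + zlib.crc32(tag.encode())) % (2**31))


def _build_net(d_in: int, graph: SimilarityGraph, config: GCNConfig,
               rng: np.random.Generator) -> Sequential:
    layers = []
    prev = d_in
    for width in config.hidden_units:
        layers.append(Dropout(config.dropout_rate, rng))
        layers.append(GraphConv(prev, width, graph.normalized_csr, rng))
        layers.append(Activation(config.activation))
        prev = width
    layers.append(Linear(prev, config.mlp_hidden, rng))
    layers.append(Activation(config.activation))
    layers.append(Linear(config.mlp_hidden, config.class_count, rng))
    return Sequential(layers)


@dataclass
class ViewModel:
    """A fitted (or freshly initialized) single-omics classifier."""

    modality_name: str
    graph: SimilarityGraph
    net: Sequential
    config: GCNConfig
    final_train_loss: float | None = None

    @property
    def gcn_weights(self) -> list[np.ndarray]:
        return [l.W.value for l in self.net.layers if isinstance(l, GraphConv)]

    def logits(self, X: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(X, training=training)


def init_view_model(X: OmicsMatrix, graph: SimilarityGraph, config: GCNConfig,
                    rng: np.random.Generator | None = None) -> ViewModel:
    if X.n_samples != graph.n:
        raise ValueError(
            f"{X.modality_name}: matrix has {X.n_samples} samples but graph has {graph.n} nodes"
        )
    rng = rng or np.random.default_rng(config.seed)
    net = _build_net(X.n_features, graph, config, rng)
    return ViewModel(X.modality_name, graph, net, config)


def gcn_forward(model: ViewModel, X: OmicsMatrix | np.ndarray) -> np.ndarray:
    """Deterministic class-probability matrix (n x c, rows sum to 1)."""
    values = X.values if isinstance(X, OmicsMatrix) else np.asarray(X, dtype=float)
    return softmax(model.logits(values, training=False))


def predict_proba(model: ViewModel, X: OmicsMatrix | np.ndarray,
                  sample_index_set: Sequence[int] | None = None) -> np.ndarray:
    """Probability vectors for a subset of nodes (all nodes when None)."""
    probs = gcn_forward(model, X)
    if sample_index_set is None:
        return probs
    idx = np.asarray(list(sample_index_set), dtype=int)
    if idx.size and (idx.min() < 0 or idx.max() >= probs.shape[0]):
        raise IndexError(f"sample index out of range for n={probs.shape[0]}")
    return probs[idx]


def _train_mask_indices(labels: LabelVector, split: SplitSpec,
                        train_ids: Sequence[str] | None) -> np.ndarray:
    ids = train_ids if train_ids is not None else sorted(split.train_ids)
    idx = labels.index_of(list(ids))
    if idx.size == 0:
        raise ValueError("empty training set")
    y = labels.labels[idx]
    if np.unique(y).size < 2:
        raise DegenerateLabelsError(
            "training set contains a single class; refusing to fit a classifier"
        )
    return np.sort(idx)


def train_view_model(
    X: OmicsMatrix,
    graph: SimilarityGraph,
    labels: LabelVector,
    split: SplitSpec,
    config: GCNConfig,
    *,
    epochs: int | None = None,
    train_ids: Sequence[str] | None = None,
) -> ViewModel:
    """Fit one omics-specific classifier with full-batch Adam.

    ``train_ids`` restricts the loss mask below ``split.train_ids`` (used when
    a validation subset of the training samples must stay out of the fit).
    Deterministic for a fixed ``config.seed``.
    """
    epochs = config.pretrain_epochs if epochs is None else epochs
    train_idx = _train_mask_indices(labels, split, train_ids)
    rng = np.random.default_rng(config.seed)
    model = init_view_model(X, graph, config, rng)
    opt = Adam(model.net.parameters(), lr=config.learning_rate)
    y = labels.labels
    loss = np.nan
    for epoch in range(epochs):
        logits = model.net.forward(X.values, training=True)
        loss, dlogits, _ = softmax_cross_entropy(logits, y, train_idx)
        if not np.isfinite(loss):
            raise TrainingDivergedError(
                f"{X.modality_name}: non-finite loss at epoch {epoch}", epoch=epoch
            )
        opt.zero_grad()
        model.net.backward(dlogits)
        opt.step()
    model.final_train_loss = float(loss)
    return model


# ---------------------------------------------------------------------------
# checkpointing


def save_checkpoint(model: ViewModel, path: str | Path) -> Path:
    """Serialize weights + config + graph to a single .npz archive."""
    path = Path(path)
    meta = {
        "format_version": CHECKPOINT_VERSION,
        "kind": "view_model",
        "modality_name": model.modality_name,
        "config": asdict(model.config),
        "graph": {
            "modality_name": model.graph.modality_name,
            "n": model.graph.n,
            "sparsity_K": model.graph.sparsity_K,
            "threshold_epsilon": model.graph.threshold_epsilon,
            "sample_ids": model.graph.sample_ids,
            "hash": model.graph.content_hash(),
        },
        "final_train_loss": model.final_train_loss,
    }
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.net.parameters())}
    arrays["adjacency"] = model.graph.adjacency
    arrays["normalized_adjacency"] = model.graph.normalized_adjacency
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)
    return path


def load_checkpoint(path: str | Path, d_in: int) -> ViewModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("format_version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('format_version')}")
        g = meta["graph"]
        cfg = meta["config"]
        cfg["hidden_units"] = tuple(cfg["hidden_units"])
        config = GCNConfig(**cfg)
        graph = SimilarityGraph(
            g["modality_name"], g["n"], data["adjacency"],
            data["normalized_adjacency"], g["sparsity_K"], g["threshold_epsilon"],
            g["sample_ids"],
        )
        if graph.content_hash() != g["hash"]:
            raise ValueError("checkpoint graph hash mismatch")
        rng = np.random.default_rng(config.seed)
        net = _build_net(d_in, graph, config, rng)
        for i, p in enumerate(net.parameters()):
            stored = data[f"param_{i}"]
            if stored.shape != p.value.shape:
                raise ValueError("checkpoint weight shape mismatch")
            p.value[...] = stored
        return ViewModel(meta["modality_name"], graph, net, config,
                         meta["final_train_loss"])
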