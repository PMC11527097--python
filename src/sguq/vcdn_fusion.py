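"""Cross-omics label-space fusion (view correlation discovery network).

Each view's classifier emits a class distribution per sample.  For two or
three views, the outer product of those distributions forms a cross-omics
discovery tensor (c x c or c x c x c) whose entries are the joint
probabilities of every class combination under view independence.  The tensor
is flattened row-major (last index fastest) and fed to a small fully
connected network (the VCDN) that learns cross-view label correlations and
outputs the fused class distribution.

Training alternates, after per-view pretraining: in step A the VCDN is frozen
and each view classifier takes one optimizer step; in step B the view
classifiers are frozen and the VCDN takes one step on its own cross-entropy.
By default step A uses only the per-view cross-entropy losses; setting
``joint_gcn_update`` routes the VCDN loss gradient through the cross tensor
into the view classifiers as well.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._nn import (
    Activation,
    Adam,
    Linear,
    Sequential,
    softmax,
    softmax_backward,
    softmax_cross_entropy,
)
from .errors import TrainingDivergedError
from .omics_gcn import (
    GCNConfig,
    ViewModel,
    _train_mask_indices,
    gcn_forward,
    seed_for,
    train_view_model,
)
from .omics_io import LabelVector, OmicsMatrix, SplitSpec
from .similarity_graph import SimilarityGraph


@dataclass
class CrossOmicsTensor:
    """Outer product of 2 or 3 per-view class distributions for one sample."""

    order: int
    entries: np.ndarray

    @property
    def flattened(self) -> np.ndarray:
        # row-major: last view's class index varies fastest
        return self.entries.reshape(-1)


def cross_tensor(dists: Sequence[np.ndarray]) -> CrossOmicsTensor:
    """Cross-omics discovery tensor for one sample."""
    order = len(dists)
    if order not in (2, 3):
        raise ValueError(f"cross tensor needs 2 or 3 views, got {order}")
    vecs = [np.asarray(d, dtype=float) for d in dists]
    c = vecs[0].shape[0]
    for v in vecs:
        if v.ndim != 1 or v.shape[0] != c:
            raise ValueError("all view distributions must be vectors of equal length")
        if (v < 0).any():
            raise ValueError("distribution entries must be non-negative")
    if order == 2:
        entries = np.einsum("a,b->ab", vecs[0], vecs[1])
    else:
        entries = np.einsum("a,b,c->abc", vecs[0], vecs[1], vecs[2])
    return CrossOmicsTensor(order, entries)


def batch_cross_flatten(prob_list: Sequence[np.ndarray]) -> np.ndarray:
    """Flattened cross tensors for a batch: (n, c**order), row-major."""
    order = len(prob_list)
    if order == 2:
        t = np.einsum("na,nb->nab", prob_list[0], prob_list[1])
    elif order == 3:
        t = np.einsum("na,nb,nc->nabc", prob_list[0], prob_list[1], prob_list[2])
    else:
        raise ValueError(f"need 2 or 3 views, got {order}")
    return t.reshape(t.shape[0], -1)


def _cross_backward(prob_list: list[np.ndarray], dflat: np.ndarray) -> list[np.ndarray]:
    """d(loss)/d(view probabilities) given d(loss)/d(flattened tensor)."""
    n = dflat.shape[0]
    c = prob_list[0].shape[1]
    order = len(prob_list)
    G = dflat.reshape((n,) + (c,) * order)
    if order == 2:
        p1, p2 = prob_list
        return [np.einsum("nab,nb->na", G, p2), np.einsum("nab,na->nb", G, p1)]
    p1, p2, p3 = prob_list
    return [
        np.einsum("nabc,nb,nc->na", G, p2, p3),
        np.einsum("nabc,na,nc->nb", G, p1, p3),
        np.einsum("nabc,na,nb->nc", G, p1, p2),
    ]


@dataclass
class FusionConfig:
    """Hyperparameters for the bi-/tri-view fusion system."""

    gcn: GCNConfig = field(default_factory=GCNConfig)
    epochs: int = 300
    vcdn_hidden_factor: int = 8
    learning_rate: float = 1e-3
    joint_gcn_update: bool = False
    seed: int = 0


def build_vcdn(order: int, class_count: int, hidden_factor: int,
               rng: np.random.Generator) -> Sequential:
    d_in = class_count**order
    return Sequential([
        Linear(d_in, d_in * hidden_factor, rng),
        Activation("relu"),
        Linear(d_in * hidden_factor, class_count, rng),
    ])


@dataclass
class FusionModel:
    """Fitted bi-/tri-view fusion system."""

    view_models: list[ViewModel]
    vcdn: Sequential
    matrices: list[OmicsMatrix]
    class_count: int
    training_log: list[dict] = field(default_factory=list)
    config: FusionConfig | None = None

    @property
    def order(self) -> int:
        return len(self.view_models)

    def training_log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.training_log)


def vcdn_forward(model: FusionModel,
                 sample_index_set: Sequence[int] | None = None) -> np.ndarray:
    """Fused class probabilities per sample (rows sum to 1)."""
    probs = [gcn_forward(vm, X) for vm, X in zip(model.view_models, model.matrices)]
    flat = batch_cross_flatten(probs)
    fused = softmax(model.vcdn.forward(flat, training=False))
    if sample_index_set is None:
        return fused
    idx = np.asarray(list(sample_index_set), dtype=int)
    return fused[idx]


def train_fusion(
    views: Sequence[tuple[OmicsMatrix, SimilarityGraph]],
    labels: LabelVector,
    split: SplitSpec,
    config: FusionConfig,
    *,
    train_ids: Sequence[str] | None = None,
) -> FusionModel:
    """Pretrain each view, then alternate view/VCDN optimization.

    Per-view seeds are derived from ``config.seed`` and the modality name, so
    the training trajectory of one view does not depend on the order views are
    listed in.  Deterministic for a fixed config.
    """
    order = len(views)
    if order not in (2, 3):
        raise ValueError(f"fusion needs 2 or 3 views, got {order}")
    c = config.gcn.class_count
    train_idx = _train_mask_indices(labels, split, train_ids)
    y = labels.labels

    view_models: list[ViewModel] = []
    for X, graph in views:
        cfg = GCNConfig(**{**asdict(config.gcn),
                           "seed": seed_for(config.seed, X.modality_name)})
        cfg.hidden_units = tuple(cfg.hidden_units)
        view_models.append(
            train_view_model(X, graph, labels, split, cfg,
                             epochs=cfg.pretrain_epochs, train_ids=train_ids)
        )

    vcdn = build_vcdn(order, c, config.vcdn_hidden_factor,
                      np.random.default_rng(seed_for(config.seed, "vcdn")))
    view_opts = [Adam(vm.net.parameters(), lr=config.gcn.learning_rate)
                 for vm in view_models]
    vcdn_opt = Adam(vcdn.parameters(), lr=config.learning_rate)
    matrices = [X for X, _ in views]
    log: list[dict] = []

    for epoch in range(config.epochs):
        # --- step A: update view classifiers, VCDN frozen -----------------
        gcn_losses = []
        if not config.joint_gcn_update:
            for vm, X, opt in zip(view_models, matrices, view_opts):
                logits = vm.net.forward(X.values, training=True)
                loss, dlogits, _ = softmax_cross_entropy(logits, y, train_idx)
                _check_finite(loss, epoch, vm.modality_name)
                opt.zero_grad()
                vm.net.backward(dlogits)
                opt.step()
                gcn_losses.append(loss)
        else:
            probs, dlogits_own = [], []
            for vm, X in zip(view_models, matrices):
                logits = vm.net.forward(X.values, training=True)
                loss, dl, p = softmax_cross_entropy(logits, y, train_idx)
                _check_finite(loss, epoch, vm.modality_name)
                gcn_losses.append(loss)
                probs.append(p)
                dlogits_own.append(dl)
            flat = batch_cross_flatten(probs)
            vlogits = vcdn.forward(flat, training=True)
            vloss, dvlogits, _ = softmax_cross_entropy(vlogits, y, train_idx)
            _check_finite(vloss, epoch, "vcdn")
            dflat = vcdn.backward(dvlogits)
            vcdn_opt.zero_grad()  # discard gradients parked on frozen VCDN params
            dprobs = _cross_backward(probs, dflat)
            for vm, opt, dl, p, dp in zip(view_models, view_opts, dlogits_own,
                                          probs, dprobs):
                opt.zero_grad()
                vm.net.backward(dl + softmax_backward(p, dp))
                opt.step()

        # --- step B: update VCDN, view classifiers frozen -----------------
        eval_probs = [gcn_forward(vm, X) for vm, X in zip(view_models, matrices)]
        flat = batch_cross_flatten(eval_probs)
        vlogits = vcdn.forward(flat, training=True)
        vcdn_loss, dvlogits, _ = softmax_cross_entropy(vlogits, y, train_idx)
        _check_finite(vcdn_loss, epoch, "vcdn")
        vcdn_opt.zero_grad()
        vcdn.backward(dvlogits)
        vcdn_opt.step()

        entry = {"epoch": epoch, "loss_vcdn": vcdn_loss}
        for vm, loss in zip(view_models, gcn_losses):
            entry[f"loss_gcn_{vm.modality_name}"] = loss
        log.append(entry)

    return FusionModel(view_models, vcdn, list(matrices), c, log, config)


def _check_finite(loss: float, epoch: int, tag: str) -> None:
    if not np.isfinite(loss):
        raise TrainingDivergedError(f"{tag}: non-finite loss at epoch {epoch}",
                                    epoch=epoch)


# ---------------------------------------------------------------------------
# checkpointing


def save_fusion_checkpoint(model: FusionModel, path: str | Path) -> Path:
    """Serialize the full fusion system (views + VCDN) to one .npz archive."""
    path = Path(path)
    meta = {
        "format_version": 1,
        "kind": "fusion_model",
        "order": model.order,
        "class_count": model.class_count,
        "config": asdict(model.config) if model.config else None,
        "modalities": [vm.modality_name for vm in model.view_models],
        "graph_hashes": [vm.graph.content_hash() for vm in model.view_models],
    }
    arrays = {}
    for k, vm in enumerate(model.view_models):
        for i, p in enumerate(vm.net.parameters()):
            arrays[f"view{k}_param_{i}"] = p.value
        arrays[f"view{k}_adjacency"] = vm.graph.adjacency
        arrays[f"view{k}_norm_adjacency"] = vm.graph.normalized_adjacency
    for i, p in enumerate(model.vcdn.parameters()):
        arrays[f"vcdn_param_{i}"] = p.value
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)
    return path
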