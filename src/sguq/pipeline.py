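"""End-to-end staged pipeline: graphs -> per-stage ensembles -> thresholds.

Orchestrates the full procedure on one dataset:

1. build a similarity graph per modality (shared ``K`` with optional
   per-modality overrides);
2. pick the stage order — best single view, then the best bi-view
   combination containing it, then all three views — by validation accuracy
   (or take an explicit order from the config);
3. run a T-trial ensemble per stage model, recording every sample's
   per-trial case probability;
4. choose the uncertainty thresholds (t1, t2) by exhaustive grid search on
   the optimization set (a validation subset of the training samples by
   default, so test labels never influence thresholds);
5. route the test samples and report accuracy / F1 / AUC plus the per-stage
   routing fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import train_test_split

from .omics_gcn import GCNConfig, gcn_forward, seed_for, train_view_model
from .omics_io import (
    LabelVector,
    OmicsMatrix,
    SplitSpec,
    write_predictions,
)
from .similarity_graph import SimilarityGraph, build_graph
from .staged_policy import (
    Metrics,
    StagedPolicy,
    StageOutputs,
    evaluate,
    optimize_thresholds,
    route,
    stage_fractions,
)
from .uncertainty import TrialEnsemble, run_trials
from .vcdn_fusion import FusionConfig, train_fusion, vcdn_forward


@dataclass
class PipelineConfig:
    """Everything the staged pipeline needs beyond the data itself."""

    K: float = 2.0
    K_per_modality: dict = field(default_factory=dict)
    gcn: GCNConfig = field(default_factory=GCNConfig)
    fusion_epochs: int = 300
    vcdn_hidden_factor: int = 8
    joint_gcn_update: bool = False
    T: int = 10
    base_seed: int = 0
    grid_steps: int = 100
    optimize_on: str = "validation"  # validation | train | all
    val_fraction: float = 0.2
    stage_order: list | None = None  # e.g. [["mRNA"], ["mRNA","meth"], [...]]
    decision_threshold: float = 0.5
    threshold_tie_break: str = "cheapest"  # cheapest | smallest (see staged_policy)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gcn_raw = raw.pop("gcn", {})
        if "hidden_units" in gcn_raw:
            gcn_raw["hidden_units"] = tuple(gcn_raw["hidden_units"])
        return cls(gcn=GCNConfig(**gcn_raw), **raw)


@dataclass
class StagedResult:
    """Outputs of one full staged run."""

    stage_order: list[list[str]]
    graphs: dict[str, SimilarityGraph]
    stage_outputs: StageOutputs
    thresholds: tuple[float, float]
    optimization_accuracy: float
    test_policy: StagedPolicy
    test_metrics: Metrics
    test_fractions: tuple[float, float, float]
    predictions: pd.DataFrame

    def write_predictions(self, path: str | Path) -> Path:
        return write_predictions(self.predictions, path)


def subset_ensemble(ensemble: TrialEnsemble, idx: np.ndarray) -> TrialEnsemble:
    ids = [ensemble.sample_ids[i] for i in idx] if ensemble.sample_ids else None
    return TrialEnsemble(ensemble.model_tag, ensemble.trial_probs[idx], ids,
                         ensemble.decision_threshold)


def subset_stages(stages: StageOutputs, idx: np.ndarray) -> StageOutputs:
    return StageOutputs(*(subset_ensemble(e, idx) for e in stages.ensembles))


def _carve_validation(labels: LabelVector, split: SplitSpec, val_fraction: float,
                      seed: int) -> tuple[list[str], list[str]]:
    """Split the training IDs into (fit, validation), stratified by label."""
    train_ids = sorted(split.train_ids)
    y = labels.labels[labels.index_of(train_ids)]
    fit, val = train_test_split(train_ids, test_size=val_fraction, stratify=y,
                                random_state=seed % (2**31))
    return sorted(fit), sorted(val)


def run_staged_pipeline(
    matrices: Sequence[OmicsMatrix],
    labels: LabelVector,
    split: SplitSpec,
    config: PipelineConfig,
) -> StagedResult:
    if len(matrices) != 3:
        raise ValueError("the staged pipeline needs exactly 3 modalities")
    names = [m.modality_name for m in matrices]
    by_name = {m.modality_name: m for m in matrices}
    graphs = {
        name: build_graph(by_name[name], config.K_per_modality.get(name, config.K))
        for name in names
    }

    need_val = config.optimize_on == "validation" or config.stage_order is None
    if need_val:
        fit_ids, val_ids = _carve_validation(labels, split, config.val_fraction,
                                             config.base_seed)
    else:
        fit_ids, val_ids = sorted(split.train_ids), []

    def single_trainer_factory(name: str):
        def trainer(seed: int) -> np.ndarray:
            cfg = replace(config.gcn, seed=seed)
            model = train_view_model(by_name[name], graphs[name], labels, split,
                                     cfg, train_ids=fit_ids)
            return gcn_forward(model, by_name[name])[:, 1]
        return trainer

    def fusion_trainer_factory(combo: list[str]):
        views = [(by_name[n], graphs[n]) for n in combo]

        def trainer(seed: int) -> np.ndarray:
            fcfg = FusionConfig(
                gcn=config.gcn,
                epochs=config.fusion_epochs,
                vcdn_hidden_factor=config.vcdn_hidden_factor,
                joint_gcn_update=config.joint_gcn_update,
                seed=seed,
            )
            model = train_fusion(views, labels, split, fcfg, train_ids=fit_ids)
            return vcdn_forward(model)[:, 1]
        return trainer

    val_idx = labels.index_of(val_ids) if val_ids else None
    y = labels.labels

    if config.stage_order is not None:
        order = [list(stage) for stage in config.stage_order]
        if [len(s) for s in order] != [1, 2, 3]:
            raise ValueError("stage_order must list 1, 2 and 3 modalities per stage")
    else:
        # stage 1: best single view by validation accuracy of one seeded fit
        accs = {}
        for name in names:
            probs = single_trainer_factory(name)(seed_for(config.base_seed, f"order:{name}"))
            accs[name] = float(np.mean((probs[val_idx] >= config.decision_threshold) ==
                                       (y[val_idx] == 1)))
        first = max(names, key=lambda n: (accs[n], -names.index(n)))
        # stage 2: best pair containing the winner
        pair_accs = {}
        for other in names:
            if other == first:
                continue
            combo = [first, other]
            probs = fusion_trainer_factory(combo)(
                seed_for(config.base_seed, f"order:{'+'.join(combo)}"))
            pair_accs[other] = float(np.mean(
                (probs[val_idx] >= config.decision_threshold) == (y[val_idx] == 1)))
        second = max(pair_accs, key=lambda n: (pair_accs[n], -names.index(n)))
        third = next(n for n in names if n not in (first, second))
        order = [[first], [first, second], [first, second, third]]

    trainers = [
        single_trainer_factory(order[0][0]),
        fusion_trainer_factory(order[1]),
        fusion_trainer_factory(order[2]),
    ]
    ensembles = [
        run_trials(
            trainer,
            seed_for(config.base_seed, f"stage{i + 1}"),
            config.T,
            model_tag="+".join(order[i]),
            sample_ids=labels.sample_ids,
        )
        for i, trainer in enumerate(trainers)
    ]
    stages = StageOutputs(*ensembles)

    if config.optimize_on == "validation":
        opt_idx = val_idx
    elif config.optimize_on == "train":
        opt_idx = labels.index_of(sorted(split.train_ids))
    elif config.optimize_on == "all":
        opt_idx = np.arange(len(labels.sample_ids))
    else:
        raise ValueError(f"unknown optimize_on {config.optimize_on!r}")
    opt_policy = optimize_thresholds(subset_stages(stages, opt_idx), y[opt_idx],
                                     config.grid_steps, config.threshold_tie_break)
    t1, t2 = opt_policy.t1, opt_policy.t2

    test_ids = sorted(split.test_ids)
    test_idx = labels.index_of(test_ids)
    test_policy = route(subset_stages(stages, test_idx), t1, t2)
    metrics = evaluate(y[test_idx], test_policy.final_label, test_policy.final_score)
    fractions = stage_fractions(test_policy)

    predictions = pd.DataFrame({
        "sample_id": test_ids,
        "stage": test_policy.assigned_stage,
        "p_mean": test_policy.final_score,
        "sigma": test_policy.final_sigma,
        "label": test_policy.final_label,
    })
    return StagedResult(order, graphs, stages, (t1, t2),
                        opt_policy.achieved_accuracy, test_policy, metrics,
                        fractions, predictions)
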