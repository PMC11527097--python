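"""Staged routing over uncertainty thresholds, threshold grid search, metrics.

A sample is finalized at the cheapest stage whose ensemble uncertainty is
small enough: stage 1 (single view) when ``sigma_1 <= t1``, else stage 2
(bi-view) when ``sigma_2 <= t2``, else stage 3 (tri-view) unconditionally.
The thresholds are chosen by an exhaustive grid search: each grid spans the
observed uncertainty range of its stage in ``grid_steps`` evenly spaced
values (endpoints included), scanned ascending (t1 outer, t2 inner), keeping
the first combination attaining the best routed accuracy — so ties resolve to
the smallest (t1, t2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from sklearn.metrics import accuracy_score, f1_score, roc_auc_score

from .uncertainty import TrialEnsemble


@dataclass
class StageOutputs:
    """Aligned trial ensembles for the three stages of one dataset."""

    stage1: TrialEnsemble
    stage2: TrialEnsemble
    stage3: TrialEnsemble

    def __post_init__(self) -> None:
        n = self.stage1.n
        if not (self.stage2.n == n and self.stage3.n == n):
            raise ValueError("stage ensembles cover different numbers of samples")
        ids = [e.sample_ids for e in (self.stage1, self.stage2, self.stage3)]
        known = [i for i in ids if i is not None]
        if known and any(i != known[0] for i in known[1:]):
            raise ValueError("stage ensembles are not aligned on the same sample IDs")

    @property
    def ensembles(self) -> tuple[TrialEnsemble, TrialEnsemble, TrialEnsemble]:
        return (self.stage1, self.stage2, self.stage3)

    @property
    def sample_ids(self) -> list[str] | None:
        return self.stage1.sample_ids

    @property
    def stage_tags(self) -> tuple[str, str, str]:
        return tuple(e.model_tag for e in self.ensembles)


@dataclass
class StagedPolicy:
    """Thresholds plus the per-sample routing they induce."""

    t1: float
    t2: float
    stage_order: tuple[str, str, str]
    assigned_stage: np.ndarray  # in {1, 2, 3}
    final_label: np.ndarray
    final_score: np.ndarray  # mean positive-class probability of the assigned stage
    final_sigma: np.ndarray
    sample_ids: list[str] | None = None
    achieved_accuracy: float | None = None


def route(stages: StageOutputs, t1: float, t2: float) -> StagedPolicy:
    """Assign every sample to exactly one stage and pull its prediction."""
    s1, s2, s3 = stages.ensembles
    stage = np.where(s1.uncertainty <= t1, 1, np.where(s2.uncertainty <= t2, 2, 3))
    labels = np.select([stage == 1, stage == 2], [s1.vote_label, s2.vote_label],
                       default=s3.vote_label)
    scores = np.select([stage == 1, stage == 2], [s1.mean_prob, s2.mean_prob],
                       default=s3.mean_prob)
    sigmas = np.select([stage == 1, stage == 2], [s1.uncertainty, s2.uncertainty],
                       default=s3.uncertainty)
    return StagedPolicy(float(t1), float(t2), stages.stage_tags, stage, labels,
                        scores, sigmas, stages.sample_ids)


def threshold_grid(sigma: np.ndarray, grid_steps: int = 100) -> np.ndarray:
    """Evenly spaced candidate thresholds spanning the observed uncertainty
    range, endpoints included."""
    lo, hi = float(np.min(sigma)), float(np.max(sigma))
    if grid_steps < 2 or lo == hi:
        return np.array([hi])
    return np.linspace(lo, hi, grid_steps)


def optimize_thresholds(
    stages: StageOutputs,
    true_labels: np.ndarray,
    grid_steps: int = 100,
    tie_break: str = "smallest",
) -> StagedPolicy:
    """Exhaustive (t1, t2) grid search maximizing routed accuracy.

    Deterministic: ascending t1 outer loop, ascending t2 inner loop, strict
    improvement required to replace the incumbent.  ``tie_break`` governs
    equal-accuracy combinations:

    * ``"smallest"`` — keep the first encountered, i.e. the smallest (t1, t2);
    * ``"cheapest"`` — prefer the combination finalizing more samples at
      stage 1 (then stage 2), so equal accuracy never buys extra modalities.
      On well-separated data many threshold pairs attain the same accuracy
      and the smallest-threshold rule would escalate everything; this rule
      keeps the routing aligned with the method's cost-saving intent.
    """
    if tie_break not in ("smallest", "cheapest"):
        raise ValueError(f"unknown tie_break {tie_break!r}")
    y = np.asarray(true_labels, dtype=int)
    n = y.size
    if n == 0:
        raise ValueError("cannot optimize thresholds on an empty sample set")
    if stages.stage1.n != n:
        raise ValueError("true_labels length does not match the stage ensembles")
    s1, s2, s3 = stages.ensembles
    correct1 = s1.vote_label == y
    correct2 = s2.vote_label == y
    correct3 = s3.vote_label == y
    grid1 = threshold_grid(s1.uncertainty, grid_steps)
    grid2 = threshold_grid(s2.uncertainty, grid_steps)

    best_key = None
    best = (float(grid1[0]), float(grid2[0]))
    for t1 in grid1:
        at1 = s1.uncertainty <= t1
        n1 = int(at1.sum())
        base = correct1[at1].sum()
        rest2 = s2.uncertainty[~at1]
        rest_c2 = correct2[~at1]
        rest_c3 = correct3[~at1]
        for t2 in grid2:
            at2 = rest2 <= t2
            acc = (base + rest_c2[at2].sum() + rest_c3[~at2].sum()) / n
            if tie_break == "smallest":
                key = (acc,)
            else:
                key = (acc, n1, int(at2.sum()))
            if best_key is None or key > best_key:
                best_key, best = key, (float(t1), float(t2))
    policy = route(stages, *best)
    policy.achieved_accuracy = float(best_key[0])
    return policy


class Metrics(NamedTuple):
    acc: float
    f1: float
    auc: float | None


def evaluate(labels_true: np.ndarray, labels_pred: np.ndarray,
             score: np.ndarray | None = None) -> Metrics:
    """Accuracy, positive-class F1 and (when defined) AUC.

    AUC uses ``score`` (the assigned stage's mean case probability).  With a
    single-class truth set the AUC is undefined and reported as None;
    accuracy and F1 are still returned.
    """
    y = np.asarray(labels_true, dtype=int)
    if y.size == 0:
        raise ValueError("empty evaluation set")
    acc = accuracy_score(y, labels_pred)
    f1 = f1_score(y, labels_pred, pos_label=1, zero_division=0)
    auc = None
    if score is not None and np.unique(y).size == 2:
        auc = float(roc_auc_score(y, score))
    return Metrics(float(acc), float(f1), auc)


def stage_fractions(policy: StagedPolicy) -> tuple[float, float, float]:
    """Fraction of samples finalized at each stage; sums to 1."""
    n = policy.assigned_stage.size
    counts = [(policy.assigned_stage == s).sum() for s in (1, 2, 3)]
    return tuple(c / n for c in counts)
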