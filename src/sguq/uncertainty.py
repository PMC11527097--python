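"""T-trial ensemble uncertainty.

A stage model (single view or fusion) is retrained T times with different
seeds; each trial's predicted case probability is recorded per sample.  The
per-sample mean is the ensemble prediction, the sample standard deviation
(T - 1 denominator) is the uncertainty score, and the final label is a
majority vote over per-trial thresholded labels, ties broken by the mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import EnsembleTrialError, TrainingDivergedError


def ensemble_stats(trial_probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row mean and sample standard deviation (T - 1 denominator)."""
    P = np.asarray(trial_probs, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("trial_probs must be n x T with T >= 2")
    if (P < 0).any() or (P > 1).any():
        raise ValueError("trial probabilities must lie in [0, 1]")
    return P.mean(axis=1), P.std(axis=1, ddof=1)


def majority_vote(trial_probs: np.ndarray, decision_threshold: float = 0.5) -> np.ndarray:
    """Majority vote over per-trial thresholded labels.

    A trial votes 1 when its probability reaches ``decision_threshold``.  The
    final label is the one winning strictly more than T/2 trials; an even
    split falls back to the mean probability against the same threshold.
    """
    P = np.asarray(trial_probs, dtype=float)
    if P.ndim != 2 or P.shape[1] < 2:
        raise ValueError("trial_probs must be n x T with T >= 2")
    T = P.shape[1]
    ones = (P >= decision_threshold).sum(axis=1)
    labels = np.where(ones * 2 > T, 1, 0)
    tie = ones * 2 == T
    if tie.any():
        labels[tie] = (P[tie].mean(axis=1) >= decision_threshold).astype(int)
    return labels


@dataclass
class TrialEnsemble:
    """Per-sample trial probabilities with derived ensemble statistics."""

    model_tag: str
    trial_probs: np.ndarray  # n x T, probability of the positive class
    sample_ids: list[str] | None = None
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        self.trial_probs = np.asarray(self.trial_probs, dtype=float)
        self.mean_prob, self.uncertainty = ensemble_stats(self.trial_probs)
        self.vote_label = majority_vote(self.trial_probs, self.decision_threshold)

    @property
    def T(self) -> int:
        return self.trial_probs.shape[1]

    @property
    def n(self) -> int:
        return self.trial_probs.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Export table: sample_id, stage_tag, p_mean, sigma, vote."""
        ids = self.sample_ids or [str(i) for i in range(self.n)]
        return pd.DataFrame({
            "sample_id": ids,
            "stage_tag": self.model_tag,
            "p_mean": self.mean_prob,
            "sigma": self.uncertainty,
            "vote": self.vote_label,
        })


def run_trials(
    trainer: Callable[[int], np.ndarray],
    base_seed: int,
    T: int,
    *,
    model_tag: str = "",
    sample_ids: Sequence[str] | None = None,
) -> TrialEnsemble:
    """Run T independent trainings with seeds ``base_seed + t``.

    ``trainer(seed)`` must train the stage model from scratch under that seed
    and return the predicted positive-class probability for every sample.  A
    diverging trial aborts the whole ensemble, reporting the trial index.
    """
    if T < 2:
        raise ValueError("need T >= 2 trials for a sample standard deviation")
    columns = []
    for t in range(T):
        try:
            probs = np.asarray(trainer(base_seed + t), dtype=float)
        except TrainingDivergedError as exc:
            raise EnsembleTrialError(f"trial {t} diverged: {exc}", trial=t) from exc
        columns.append(probs)
    trial_probs = np.column_stack(columns)
    return TrialEnsemble(model_tag, trial_probs,
                         list(sample_ids) if sample_ids is not None else None)
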