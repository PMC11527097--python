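"""Reading and writing omics feature matrices, labels, splits and predictions.

File layout (all plain CSV with a header row):

* ``<modality>_features.csv`` — first column ``sample_id``, remaining columns
  one per feature, numeric.
* ``labels.csv`` — columns ``sample_id,label`` with integer class labels
  (0 = control, 1 = case for the binary setting).
* ``split.csv`` (optional) — columns ``sample_id,partition`` with values
  ``train`` or ``test``.  When absent a deterministic stratified split is
  produced from a seed.

All matrices loaded from one directory are re-indexed to the sample order of
``labels.csv`` so downstream modules can rely on positional alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .errors import AlignmentError, ParseError

#: column order of the per-sample prediction table written by
#: :func:`write_predictions`.
PREDICTION_COLUMNS = ("sample_id", "stage", "p_mean", "sigma", "label")


@dataclass
class OmicsMatrix:
    """One modality's samples x features table with aligned sample IDs."""

    modality_name: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, d = self.values.shape
        if n != len(self.sample_ids) or d != len(self.feature_ids):
            raise ValueError(
                f"{self.modality_name}: values shape {self.values.shape} does not "
                f"match {len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        if len(set(self.sample_ids)) != n:
            raise AlignmentError(f"{self.modality_name}: duplicate sample IDs")
        if len(set(self.feature_ids)) != d:
            raise ValueError(f"{self.modality_name}: duplicate feature IDs")
        if n < 2:
            raise ValueError(f"{self.modality_name}: need at least 2 samples, got {n}")
        if d < 1:
            raise ValueError(f"{self.modality_name}: need at least 1 feature")
        if not np.isfinite(self.values).all():
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ParseError(
                f"{self.modality_name}: non-finite value at sample "
                f"{self.sample_ids[bad[0]]!r}, feature {self.feature_ids[bad[1]]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class LabelVector:
    """Integer class labels aligned with an ordered list of sample IDs."""

    sample_ids: list[str]
    labels: np.ndarray
    class_count: int = 2

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.shape != (len(self.sample_ids),):
            raise ValueError("labels must have one entry per sample ID")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) >= self.class_count:
            raise ValueError(
                f"labels must lie in [0, {self.class_count}); got range "
                f"[{self.labels.min()}, {self.labels.max()}]"
            )

    def index_of(self, ids: Sequence[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        return np.array([pos[s] for s in ids], dtype=int)


@dataclass
class SplitSpec:
    """Disjoint train/test sample ID sets."""

    train_ids: frozenset[str]
    test_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.train_ids = frozenset(self.train_ids)
        self.test_ids = frozenset(self.test_ids)
        if self.train_ids & self.test_ids:
            raise AlignmentError(
                f"train/test overlap: {sorted(self.train_ids & self.test_ids)[:5]}"
            )

    def masks(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (train, test) masks in the order of ``sample_ids``."""
        train = np.array([s in self.train_ids for s in sample_ids])
        test = np.array([s in self.test_ids for s in sample_ids])
        return train, test


def make_stratified_split(
    labels: LabelVector, test_fraction: float = 0.3, seed: int = 0
) -> SplitSpec:
    """Deterministic stratified train/test split from a seed."""
    train, test = train_test_split(
        labels.sample_ids,
        test_size=test_fraction,
        stratify=labels.labels,
        random_state=seed,
    )
    return SplitSpec(frozenset(train), frozenset(test))


def _read_features_csv(path: Path, modality: str) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={0: str})
    id_col = df.columns[0]
    df = df.set_index(id_col)
    for col in df.columns:
        if df[col].dtype == object:
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            if bad.any():
                row = df.index[bad.to_numpy().argmax()]
                raise ParseError(
                    f"{modality}: non-numeric value at sample {row!r}, feature {col!r}"
                )
            df[col] = coerced
    if df.isna().to_numpy().any():
        loc = np.argwhere(df.isna().to_numpy())[0]
        raise ParseError(
            f"{modality}: missing value at sample {df.index[loc[0]]!r}, "
            f"feature {df.columns[loc[1]]!r}"
        )
    return df


def load_dataset(
    directory: str | Path,
    modality_names: Sequence[str],
    *,
    test_fraction: float = 0.3,
    split_seed: int = 0,
) -> tuple[list[OmicsMatrix], LabelVector, SplitSpec]:
    """Load aligned omics matrices, labels and a train/test split.

    All matrices are reordered to the sample order of ``labels.csv``.  A
    modality with missing or extra sample IDs raises :class:`AlignmentError`
    naming the modality and the offending IDs.  If ``split.csv`` is absent, a
    stratified ``test_fraction`` split seeded by ``split_seed`` is generated.
    """
    directory = Path(directory)
    labels_df = pd.read_csv(directory / "labels.csv", dtype={"sample_id": str})
    if list(labels_df.columns[:2]) != ["sample_id", "label"]:
        raise ParseError("labels.csv must have columns sample_id,label")
    sample_ids = labels_df["sample_id"].tolist()
    labels = LabelVector(sample_ids, labels_df["label"].to_numpy())

    matrices: list[OmicsMatrix] = []
    for modality in modality_names:
        path = directory / f"{modality}_features.csv"
        if not path.exists():
            raise FileNotFoundError(path)
        df = _read_features_csv(path, modality)
        missing = [s for s in sample_ids if s not in df.index]
        if missing:
            raise AlignmentError(
                f"modality {modality!r} is missing sample IDs {missing[:5]}"
            )
        extra = sorted(set(df.index) - set(sample_ids))
        if extra:
            raise AlignmentError(
                f"modality {modality!r} has sample IDs absent from labels.csv: {extra[:5]}"
            )
        df = df.loc[sample_ids]
        matrices.append(
            OmicsMatrix(modality, sample_ids, [str(c) for c in df.columns], df.to_numpy())
        )

    split_path = directory / "split.csv"
    if split_path.exists():
        split_df = pd.read_csv(split_path, dtype=str)
        if list(split_df.columns[:2]) != ["sample_id", "partition"]:
            raise ParseError("split.csv must have columns sample_id,partition")
        unknown = set(split_df["sample_id"]) - set(sample_ids)
        if unknown:
            raise AlignmentError(f"split.csv names unknown sample IDs: {sorted(unknown)[:5]}")
        bad = set(split_df["partition"]) - {"train", "test"}
        if bad:
            raise ParseError(f"split.csv partition values must be train|test, got {bad}")
        train = frozenset(split_df.loc[split_df["partition"] == "train", "sample_id"])
        test = frozenset(split_df.loc[split_df["partition"] == "test", "sample_id"])
        split = SplitSpec(train, test)
    else:
        split = make_stratified_split(labels, test_fraction=test_fraction, seed=split_seed)
    return matrices, labels, split


def write_dataset(
    directory: str | Path,
    matrices: Sequence[OmicsMatrix],
    labels: LabelVector,
    split: SplitSpec | None = None,
) -> Path:
    """Write matrices/labels (and optionally a split) in the load_dataset layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in matrices:
        df = pd.DataFrame(m.values, columns=m.feature_ids)
        df.insert(0, "sample_id", m.sample_ids)
        df.to_csv(directory / f"{m.modality_name}_features.csv", index=False,
                  float_format="%.12g")
    pd.DataFrame({"sample_id": labels.sample_ids, "label": labels.labels}).to_csv(
        directory / "labels.csv", index=False
    )
    if split is not None:
        rows = [(s, "train") for s in sorted(split.train_ids)] + [
            (s, "test") for s in sorted(split.test_ids)
        ]
        pd.DataFrame(rows, columns=["sample_id", "partition"]).to_csv(
            directory / "split.csv", index=False
        )
    return directory


def write_predictions(results: pd.DataFrame, path: str | Path) -> Path:
    """Write the per-sample routing table as CSV.

    Expects one row per sample with columns :data:`PREDICTION_COLUMNS`
    (``sample_id, stage, p_mean, sigma, label``); the column order in the file
    is fixed to that tuple.  Floats are written with 12 significant digits so
    a read-back reproduces them to well below 1e-9.
    """
    missing = set(PREDICTION_COLUMNS) - set(results.columns)
    if missing:
        raise ValueError(f"results table is missing columns {sorted(missing)}")
    path = Path(path)
    results.loc[:, list(PREDICTION_COLUMNS)].to_csv(
        path, index=False, float_format="%.12g"
    )
    return path


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Read a prediction table written by :func:`write_predictions`."""
    return pd.read_csv(path, dtype={"sample_id": str})
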