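"""Synthetic multi-omics data with class-conditional Gaussian structure.

The generator emulates the shape and signal structure the staged classifier
assumes: ``n`` subjects, three modalities of ``d_k`` continuous features,
binary labels, and per-modality signal strength.  For each modality a chosen
subset of "informative" features shifts its mean by +/- delta_k / 2 with the
class label; a shared latent factor (scaled by ``cross_modal_correlation``)
is added to the informative features of every modality so that views carry
correlated, complementary evidence.  A configurable fraction of "hard"
samples has its first-modality shift attenuated by a factor of 10, so those
samples can only be resolved confidently once later modalities join —
exactly the sub-population that exercises staged escalation.

All randomness comes from numpy's PCG64 generator seeded from the spec, so a
fixture regenerates byte-identically from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .omics_io import LabelVector, OmicsMatrix

#: attenuation applied to the modality-1 class shift of "hard" samples
HARD_ATTENUATION = 0.1


@dataclass
class ModalitySpec:
    name: str
    n_features: int
    n_informative: int
    effect_size: float  # class mean separation delta_k (in noise-SD units)
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError(f"{self.name}: n_informative exceeds n_features")
        if self.effect_size < 0:
            raise ValueError(f"{self.name}: effect size must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError(f"{self.name}: noise_sd must be > 0")


def _default_modalities() -> list[ModalitySpec]:
    # three 200-feature modalities with a clearly strongest first view,
    # mirroring a cohort where the transcriptome is the most informative layer
    return [
        ModalitySpec("mRNA", 200, 20, 1.6),
        ModalitySpec("meth", 200, 20, 1.0),
        ModalitySpec("miRNA", 200, 20, 0.8),
    ]


@dataclass
class SyntheticSpec:
    """Study-shaped generator settings.

    Defaults mirror a 351-subject cohort with a 169/182 control/case split
    and 200 features per omics layer.
    """

    n_samples: int = 351
    class_balance: float = 182 / 351  # fraction of positive (case) samples
    modalities: list[ModalitySpec] = field(default_factory=_default_modalities)
    hard_fraction: float = 0.3
    cross_modal_correlation: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must be in (0, 1)")
        if not 0.0 <= self.hard_fraction <= 1.0:
            raise ValueError("hard_fraction must be in [0, 1]")
        if not 0.0 <= self.cross_modal_correlation < 1.0:
            raise ValueError("cross_modal_correlation must be in [0, 1)")
        if self.n_samples < 2:
            raise ValueError("need at least 2 samples")


@dataclass
class GroundTruth:
    """What the generator planted: informative features and hard samples."""

    informative_features: dict[str, list[str]]
    hard_sample_ids: list[str]
    latent_factor: np.ndarray


def generate(spec: SyntheticSpec) -> tuple[list[OmicsMatrix], LabelVector, GroundTruth]:
    """Draw one dataset from the spec (deterministic given ``spec.seed``)."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    n_case = int(round(n * spec.class_balance))
    n_case = min(max(n_case, 1), n - 1)
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_case]] = 1

    n_hard = int(round(n * spec.hard_fraction))
    hard_idx = rng.permutation(n)[:n_hard]
    hard = np.zeros(n, dtype=bool)
    hard[hard_idx] = True

    latent = rng.standard_normal(n)
    signed = np.where(labels == 1, 0.5, -0.5)  # +/- delta/2 after scaling

    matrices: list[OmicsMatrix] = []
    informative: dict[str, list[str]] = {}
    for k, mod in enumerate(spec.modalities):
        X = rng.standard_normal((n, mod.n_features)) * mod.noise_sd
        feature_ids = [f"{mod.name}_f{j:03d}" for j in range(mod.n_features)]
        shift = signed * mod.effect_size
        if k == 0:
            shift = np.where(hard, shift * HARD_ATTENUATION, shift)
        inf_cols = np.arange(mod.n_informative)
        X[:, inf_cols] += shift[:, None]
        X[:, inf_cols] += (spec.cross_modal_correlation * latent)[:, None]
        matrices.append(OmicsMatrix(mod.name, sample_ids, feature_ids, X))
        informative[mod.name] = [feature_ids[j] for j in inf_cols]

    truth = GroundTruth(informative, [sample_ids[i] for i in np.sort(hard_idx)], latent)
    return matrices, LabelVector(sample_ids, labels), truth


def routing_fixture_spec(seed: int = 0, *, hard_fraction: float = 0.3,
                         n_samples: int = 240, n_features: int = 50,
                         effect_sizes: Sequence[float] = (3.0, 2.0, 2.0)) -> SyntheticSpec:
    """Canonical spec for exercising staged routing: a strong first view for
    most samples, attenuated for the hard sub-population, with later views
    carrying enough signal to resolve them."""
    n_inf = max(1, n_features // 5)
    mods = [
        ModalitySpec(name, n_features, n_inf, float(delta))
        for name, delta in zip(("mRNA", "meth", "miRNA"), effect_sizes)
    ]
    return SyntheticSpec(
        n_samples=n_samples,
        class_balance=0.5,
        modalities=mods,
        hard_fraction=hard_fraction,
        cross_modal_correlation=0.2,
        seed=seed,
    )


def make_routing_fixture(seed: int = 0, **overrides):
    """Canonical routing dataset (n = 240, 30% hard samples by default).

    Samples outside the hard sub-population are stage-1-sufficient by
    construction; the :class:`GroundTruth` record identifies both groups.
    """
    spec = routing_fixture_spec(seed, **overrides)
    return generate(spec)
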