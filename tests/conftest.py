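import numpy as np
import pytest

import sguq


@pytest.fixture
def fast_gcn_config():
    """Small architecture so unit tests train in well under a second."""
    return sguq.GCNConfig(hidden_units=(16, 16, 8), mlp_hidden=8,
                          pretrain_epochs=150, train_epochs=150, seed=0)


@pytest.fixture
def small_dataset():
    """60-sample tri-omics dataset with a strong first view and hard samples."""
    spec = sguq.routing_fixture_spec(0, n_samples=60, n_features=12)
    return sguq.generate(spec)


@pytest.fixture
def small_split(small_dataset):
    _, labels, _ = small_dataset
    return sguq.make_stratified_split(labels, test_fraction=0.3, seed=0)


def make_stage_ensemble(sigmas, votes, tag="stage"):
    """Two-trial ensemble with prescribed per-sample uncertainty and vote.

    With T = 2 the sample standard deviation of (m + s/sqrt(2), m - s/sqrt(2))
    is exactly s; the mean m is pushed to 0.55 (vote 1) or 0.45 (vote 0) so
    the tie-break on the mean fixes the vote.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    votes = np.asarray(votes, dtype=int)
    means = np.where(votes == 1, 0.55, 0.45)
    d = sigmas / np.sqrt(2.0)
    probs = np.column_stack([means + d, means - d])
    assert (probs >= 0).all() and (probs <= 1).all(), "sigma too large for helper"
    ens = sguq.TrialEnsemble(tag, probs)
    np.testing.assert_allclose(ens.uncertainty, sigmas, atol=1e-12)
    assert (ens.vote_label == votes).all()
    return ens
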