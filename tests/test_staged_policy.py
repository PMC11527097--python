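import numpy as np
import pytest
from scipy.stats import rankdata

import sguq
from conftest import make_stage_ensemble


def naive_metrics(y, pred, score):
    """Independent confusion-matrix / rank-statistic reference."""
    y = np.asarray(y)
    pred = np.asarray(pred)
    acc = np.mean(y == pred)
    tp = np.sum((y == 1) & (pred == 1))
    fp = np.sum((y == 0) & (pred == 1))
    fn = np.sum((y == 1) & (pred == 0))
    f1 = 0.0 if (2 * tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    ranks = rankdata(score)  # mid-ranks handle ties, Mann-Whitney AUC
    n1, n0 = np.sum(y == 1), np.sum(y == 0)
    auc = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    return acc, f1, auc


def random_stage_outputs(rng, n, lattice=False):
    """Random ensembles; `lattice` puts uncertainties on the 100-point grid."""
    if lattice:
        s1 = rng.integers(0, 100, size=n) / 99 * 0.6
        s2 = rng.integers(0, 100, size=n) / 99 * 0.6
        s1[rng.integers(n)] = 0.0
        s1[rng.integers(n)] = 0.6
        s2[rng.integers(n)] = 0.0
        s2[rng.integers(n)] = 0.6
    else:
        s1 = rng.random(n) * 0.6
        s2 = rng.random(n) * 0.6
    s3 = rng.random(n) * 0.6
    votes = rng.integers(0, 2, size=(3, n))
    return sguq.StageOutputs(
        make_stage_ensemble(s1, votes[0], "s1"),
        make_stage_ensemble(s2, votes[1], "s2"),
        make_stage_ensemble(s3, votes[2], "s3"),
    )


def routed_accuracy(stages, y, t1, t2):
    """Direct simulation of the staged protocol, no shared code paths."""
    hits = 0
    for i in range(len(y)):
        if stages.stage1.uncertainty[i] <= t1:
            label = stages.stage1.vote_label[i]
        elif stages.stage2.uncertainty[i] <= t2:
            label = stages.stage2.vote_label[i]
        else:
            label = stages.stage3.vote_label[i]
        hits += label == y[i]
    return hits / len(y)


class TestRoute:
    def test_threshold_extremes(self):
        rng = np.random.default_rng(0)
        stages = random_stage_outputs(rng, 10)
        assert (sguq.route(stages, np.inf, 0.0).assigned_stage == 1).all()
        assert (sguq.route(stages, -1.0, -1.0).assigned_stage == 3).all()

    def test_hand_traced_six_sample_example(self):
        s1 = [0.01, 0.2, 0.2, 0.01, 0.3, 0.2]
        s2 = [0.0, 0.05, 0.5, 0.0, 0.5, 0.05]
        stages = sguq.StageOutputs(
            make_stage_ensemble(s1, [1, 0, 1, 0, 1, 0], "a"),
            make_stage_ensemble(s2, [0, 1, 0, 1, 0, 1], "b"),
            make_stage_ensemble(np.zeros(6), [1, 1, 0, 0, 1, 1], "c"),
        )
        policy = sguq.route(stages, 0.1, 0.1)
        np.testing.assert_array_equal(policy.assigned_stage, [1, 2, 3, 1, 3, 2])
        # labels pulled from the assigned stage's vote
        np.testing.assert_array_equal(policy.final_label, [1, 1, 0, 0, 1, 1])
        assert sguq.stage_fractions(policy) == pytest.approx((2 / 6, 2 / 6, 2 / 6))

    @pytest.mark.parametrize("seed", range(10))
    def test_routing_is_a_partition(self, seed):
        rng = np.random.default_rng(seed)
        stages = random_stage_outputs(rng, 15)
        t1, t2 = rng.random(2)
        policy = sguq.route(stages, t1, t2)
        assert set(np.unique(policy.assigned_stage)) <= {1, 2, 3}
        assert policy.assigned_stage.shape == (15,)
        # exhaustive + exclusive by construction of the assignment rule
        s1 = stages.stage1.uncertainty <= t1
        s2 = ~s1 & (stages.stage2.uncertainty <= t2)
        s3 = ~s1 & ~s2
        np.testing.assert_array_equal(policy.assigned_stage,
                                      1 * s1 + 2 * s2 + 3 * s3)

    def test_misaligned_stages_rejected(self):
        rng = np.random.default_rng(1)
        a = random_stage_outputs(rng, 6)
        with pytest.raises(ValueError):
            sguq.StageOutputs(a.stage1, a.stage2,
                              make_stage_ensemble(np.zeros(5), np.zeros(5, int)))


class TestOptimizeThresholds:
    @pytest.mark.parametrize("seed", range(15))
    def test_grid_attains_exact_cutpoint_optimum(self, seed):
        """On lattice uncertainties the 100-step grid contains every observed
        cut-point, so the grid optimum equals the exhaustive optimum."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 13))
        stages = random_stage_outputs(rng, n, lattice=True)
        y = rng.integers(0, 2, size=n)
        policy = sguq.optimize_thresholds(stages, y, grid_steps=100)
        best = max(
            routed_accuracy(stages, y, t1, t2)
            for t1 in np.unique(stages.stage1.uncertainty)
            for t2 in np.unique(stages.stage2.uncertainty)
        )
        assert policy.achieved_accuracy == pytest.approx(best, abs=1e-12)
        assert routed_accuracy(stages, y, policy.t1, policy.t2) == pytest.approx(
            policy.achieved_accuracy, abs=1e-12)

    def test_degenerate_optimum_returns_minimal_thresholds(self):
        # every stage predicts everything correctly -> accuracy 1 at the very
        # first grid point; the literal tie rule keeps the smallest (t1, t2)
        rng = np.random.default_rng(3)
        s1, s2 = rng.random(8) * 0.6, rng.random(8) * 0.6
        y = np.ones(8, dtype=int)
        stages = sguq.StageOutputs(
            make_stage_ensemble(s1, y, "a"),
            make_stage_ensemble(s2, y, "b"),
            make_stage_ensemble(rng.random(8) * 0.6, y, "c"),
        )
        policy = sguq.optimize_thresholds(stages, y, tie_break="smallest")
        assert policy.achieved_accuracy == 1.0
        assert policy.t1 == pytest.approx(s1.min())
        assert policy.t2 == pytest.approx(s2.min())

    def test_cheapest_tie_break_prefers_stage_one(self):
        rng = np.random.default_rng(4)
        s1, s2 = rng.random(8) * 0.6, rng.random(8) * 0.6
        y = np.ones(8, dtype=int)
        stages = sguq.StageOutputs(
            make_stage_ensemble(s1, y, "a"),
            make_stage_ensemble(s2, y, "b"),
            make_stage_ensemble(rng.random(8) * 0.6, y, "c"),
        )
        policy = sguq.optimize_thresholds(stages, y, tie_break="cheapest")
        assert policy.achieved_accuracy == 1.0
        assert (policy.assigned_stage == 1).all()

    @pytest.mark.parametrize("seed", range(8))
    def test_optimum_dominates_all_stage_one_policy(self, seed):
        rng = np.random.default_rng(seed)
        stages = random_stage_outputs(rng, 12)
        y = rng.integers(0, 2, size=12)
        policy = sguq.optimize_thresholds(stages, y)
        all_stage1 = np.mean(stages.stage1.vote_label == y)
        assert policy.achieved_accuracy >= all_stage1 - 1e-12

    def test_empty_sample_set_rejected(self):
        rng = np.random.default_rng(0)
        stages = random_stage_outputs(rng, 4)
        with pytest.raises(ValueError):
            sguq.optimize_thresholds(stages, np.array([], dtype=int))


class TestEvaluate:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1])
        m = sguq.evaluate(y, y, y.astype(float))
        assert m == (1.0, 1.0, 1.0)

    def test_all_positive_on_balanced_truth(self):
        y = np.array([0, 1] * 10)
        pred = np.ones(20, dtype=int)
        m = sguq.evaluate(y, pred, np.full(20, 0.9))
        assert m.acc == pytest.approx(0.5)
        assert m.f1 == pytest.approx(2 / 3)
        assert m.auc == pytest.approx(0.5)  # constant scores -> chance AUC

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_independent_reference(self, seed):
        rng = np.random.default_rng(seed)
        n = 40
        y = rng.integers(0, 2, size=n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        pred = rng.integers(0, 2, size=n)
        score = rng.random(n)
        m = sguq.evaluate(y, pred, score)
        ref = naive_metrics(y, pred, score)
        assert m.acc == pytest.approx(ref[0], abs=1e-9)
        assert m.f1 == pytest.approx(ref[1], abs=1e-9)
        assert m.auc == pytest.approx(ref[2], abs=1e-9)

    def test_single_class_truth_has_undefined_auc(self):
        m = sguq.evaluate(np.ones(5, int), np.ones(5, int), np.linspace(0, 1, 5))
        assert m.acc == 1.0 and m.f1 == 1.0 and m.auc is None


def test_stage_fractions_all_stage_one():
    rng = np.random.default_rng(0)
    stages = random_stage_outputs(rng, 9)
    policy = sguq.route(stages, np.inf, 0.0)
    assert sguq.stage_fractions(policy) == (1.0, 0.0, 0.0)
    assert sum(sguq.stage_fractions(policy)) == pytest.approx(1.0)
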