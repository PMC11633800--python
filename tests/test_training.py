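"""Weighted BCE, augmentation, patient-level splits, early stopping, training loop."""

import numpy as np
import pytest

from ramil.bags import SyntheticSpec, generate_feature_bags
from ramil.training import (
    AugmentSpec,
    EarlyStopper,
    LossSpec,
    TrainConfig,
    augment,
    augment_bag,
    split_validation,
    stratified_kfold,
    train,
    weighted_bce,
)


class TestWeightedBCE:
    def test_balanced_two_bag_case(self):
        # both bags at q = 0.5 with equal class weights: L = ln 2
        assert weighted_bce([0.5, 0.5], [1, 0], LossSpec(1, 1)) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_cohort_count_weights(self):
        # imbalance weights from 95 positive / 146 negative training bags
        spec = LossSpec(P=95, N=146)
        assert spec.beta_P == pytest.approx(146 / 241)
        assert spec.beta_N == pytest.approx(95 / 241)
        assert spec.beta_P == pytest.approx(0.6058, abs=5e-5)
        assert spec.beta_N == pytest.approx(0.3942, abs=5e-5)
        assert spec.beta_P + spec.beta_N == pytest.approx(1.0)

    def test_perfect_prediction_limit(self):
        assert weighted_bce([1 - 1e-9, 1e-9], [1, 0], LossSpec(1, 1)) < 1e-6

    def test_balanced_reduction(self, rng):
        # P = N  =>  weighted loss equals half of the unweighted BCE sum
        q = rng.uniform(0.05, 0.95, size=10)
        y = np.array([1] * 5 + [0] * 5)
        weighted = weighted_bce(q, y, LossSpec(5, 5))
        unweighted = -(np.log(q[y == 1]).sum() + np.log(1 - q[y == 0]).sum())
        assert weighted == pytest.approx(0.5 * unweighted)

    def test_monotone_in_q_for_positive_bag(self):
        qs = np.linspace(0.05, 0.95, 10)
        losses = [weighted_bce([q], [1], LossSpec(1, 1)) for q in qs]
        assert all(l1 > l2 for l1, l2 in zip(losses, losses[1:]))

    def test_single_class_falls_back_with_warning(self):
        with pytest.warns(UserWarning, match="unweighted"):
            val = weighted_bce([0.5], [1], LossSpec(1, 0))
        assert val == pytest.approx(np.log(2))


class TestAugment:
    def test_zero_probabilities_identity(self, rng):
        spec = AugmentSpec(hflip_p=0, vflip_p=0, rotate_p=0)
        x = rng.random((10, 10))
        assert np.array_equal(augment(x, spec, rng), x)

    def test_forced_hflip_twice_identity(self, rng):
        spec = AugmentSpec(hflip_p=1.0, vflip_p=0, rotate_p=0)
        x = rng.random((8, 8))
        once = augment(x, spec, np.random.default_rng(0))
        twice = augment(once, spec, np.random.default_rng(0))
        assert not np.array_equal(once, x)
        assert np.array_equal(twice, x)

    def test_stream_determinism(self, rng):
        spec = AugmentSpec()
        x = rng.random((12, 12))
        a = augment(x, spec, np.random.default_rng(7))
        b = augment(x, spec, np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_bag_coherent_transform(self, rng):
        spec = AugmentSpec(hflip_p=1.0, vflip_p=1.0, rotate_p=0)
        bag = rng.random((4, 6, 6))
        out = augment_bag(bag, spec, np.random.default_rng(0))
        for k in range(4):
            assert np.array_equal(out[k], bag[k][::-1, ::-1])


class TestSplits:
    def test_validation_split_cohort_sizes(self):
        labels = np.array([1] * 95 + [0] * 146)
        tr, val = split_validation(labels, 0.10, seed=0)
        assert len(val) == 24  # nearest integer to 24.1
        assert len(tr) + len(val) == 241
        assert len(np.intersect1d(tr, val)) == 0
        # stratified: validation positive count within +-1 of the exact share
        assert labels[val].sum() in (9, 10)

    def test_validation_split_deterministic(self):
        labels = np.array([1, 0] * 20)
        a = split_validation(labels, 0.2, seed=5)
        b = split_validation(labels, 0.2, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_validation_split_needs_both_classes(self):
        with pytest.raises(ValueError):
            split_validation(np.ones(10, dtype=int), 0.2, seed=0)

    def test_kfold_balanced_disjoint_exhaustive(self):
        labels = np.array([1] * 95 + [0] * 146)
        folds = stratified_kfold(labels, k=5, seed=1)
        all_test = np.concatenate([te for _, te in folds])
        assert sorted(all_test.tolist()) == list(range(241))
        for tr, te in folds:
            assert labels[te].sum() == 19  # 95 positives / 5 folds exactly
            assert len(np.intersect1d(tr, te)) == 0

    def test_kfold_deterministic(self):
        labels = np.array([1, 0, 0] * 10)
        a = stratified_kfold(labels, k=3, seed=4)
        b = stratified_kfold(labels, k=3, seed=4)
        for (_, ta), (_, tb) in zip(a, b):
            assert np.array_equal(ta, tb)


class TestEarlyStopper:
    def test_monotone_trace_never_stops(self):
        stopper = EarlyStopper(patience=3)
        assert not any(stopper.update(e, 0.5 + 0.01 * e) for e in range(1, 50))

    def test_constant_trace_stops_at_patience_plus_one(self):
        stopper = EarlyStopper(patience=20)
        stopped_at = None
        for epoch in range(1, 100):
            if stopper.update(epoch, 0.7):
                stopped_at = epoch
                break
        assert stopped_at == 21  # first epoch improves over -inf, then 20 stale

    def test_best_epoch_is_argmax_of_injected_trace(self):
        trace = [0.5, 0.72, 0.68, 0.80, 0.79, 0.80, 0.75, 0.74, 0.73]
        stopper = EarlyStopper(patience=5)
        for epoch, v in enumerate(trace, start=1):
            if stopper.update(epoch, v):
                break
        assert stopper.best_epoch == 4  # strict improvement only; later tie ignored
        assert stopper.best == pytest.approx(0.80)


def tiny_dataset(n=24, seed=0):
    spec = SyntheticSpec(
        n_bags=n, positive_fraction=0.5, K=6, m_witnesses=2,
        effect_size=3.0, noise_sd=1.0, mode="feature_space", L=6, seed=seed,
    )
    bags = generate_feature_bags(spec)
    return [b.features for b in bags], [b.label for b in bags]


class TestTrainLoop:
    def test_single_class_rejected(self):
        X, _ = tiny_dataset()
        cfg = TrainConfig(max_epochs=3, patience=2, seed=0)
        with pytest.raises(ValueError, match="both classes"):
            train(X, [1] * len(X), cfg)

    def test_history_and_best_checkpoint(self):
        X, y = tiny_dataset()
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=8, patience=7, C=3, D=8, seed=1)
        result = train(X, y, cfg, variant="ramil")
        h = result.history
        assert list(h.columns) == ["epoch", "train_loss", "val_auc"]
        assert len(h) <= 8
        assert result.best_val_auc == pytest.approx(h["val_auc"].max())
        assert result.best_epoch == int(h.loc[h["val_auc"].idxmax(), "epoch"])

    def test_seed_reproducibility(self):
        X, y = tiny_dataset()
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=4, patience=3, C=3, D=8, seed=9)
        r1 = train(X, y, cfg)
        r2 = train(X, y, cfg)
        assert np.allclose(r1.history["train_loss"], r2.history["train_loss"])
        for k in r1.model.params:
            assert np.array_equal(r1.model.params[k], r2.model.params[k])

    @pytest.mark.parametrize("variant", ["mean", "max", "gated"])
    def test_baseline_variants_train(self, variant):
        X, y = tiny_dataset()
        cfg = TrainConfig(learning_rate=1e-2, max_epochs=4, patience=3, D=8, seed=2)
        result = train(X, y, cfg, variant=variant)
        assert np.isfinite(result.history["train_loss"]).all()


class TestTrainingSanity:
    def test_synthetic_recovery_beats_chance_decisively(self, feature_benchmark):
        """Witness-bag recovery: restarts reliably reach strong held-out AUC
        and attention concentrates on witness instances (sign test)."""
        assert feature_benchmark.median_auc >= 0.75
        assert feature_benchmark.sign_test_p < 0.01
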