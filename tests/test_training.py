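import numpy as np
import pytest

from ulcerstage.losses import ScheduleConfig, lr_at
from ulcerstage.model import BackboneSpec, StagingNetwork
from ulcerstage.training import (FoldAssignment, TrainConfig, fit_network,
                                 run_fold, stratified_kfold)

TABLE_LABELS = np.repeat(np.arange(6), [54, 60, 73, 39, 15, 14])


def micro_network(seed=0):
    spec = BackboneSpec(depth=1, dim=8, heads=2, patch_size=8, img_size=16,
                        tap_blocks=(1,))
    return StagingNetwork(spec, seed=seed, attention_heads=2,
                          head_dropout=0.0, stochastic_depth=0.0)


def micro_data(n_per_class=8, n_classes=3, seed=0):
    """Tiny linearly separable image set: class index shifts the mean."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    for c in range(n_classes):
        X.append(rng.normal(c * 1.0, 0.2, size=(n_per_class, 3, 16, 16)))
        y += [c] * n_per_class
    return np.concatenate(X), np.array(y)


class TestStratifiedKFold:
    def test_reference_counts_split_balanced(self):
        """Class with 73 items over k=5 deals into folds of 15,15,15,14,14."""
        assign = stratified_kfold(TABLE_LABELS, 5, seed=0)
        s2 = np.flatnonzero(TABLE_LABELS == 2)
        sizes = sorted(np.bincount(assign.fold_of[s2], minlength=5), reverse=True)
        assert sizes == [15, 15, 15, 14, 14]

    def test_partition_and_disjoint_validation(self):
        assign = stratified_kfold(TABLE_LABELS, 5, seed=3)
        seen = np.concatenate([val for _, val in assign.folds])
        assert sorted(seen) == list(range(len(TABLE_LABELS)))
        for train, val in assign.folds:
            assert not set(train) & set(val)
            assert len(train) + len(val) == len(TABLE_LABELS)

    def test_per_class_imbalance_at_most_one(self):
        for seed in range(5):
            assign = stratified_kfold(TABLE_LABELS, 5, seed=seed)
            for c in range(6):
                counts = np.bincount(assign.fold_of[TABLE_LABELS == c], minlength=5)
                assert counts.max() - counts.min() <= 1

    def test_deterministic_in_seed(self):
        a = stratified_kfold(TABLE_LABELS, 5, seed=11)
        b = stratified_kfold(TABLE_LABELS, 5, seed=11)
        c = stratified_kfold(TABLE_LABELS, 5, seed=12)
        assert np.array_equal(a.fold_of, b.fold_of)
        assert not np.array_equal(a.fold_of, c.fold_of)

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            stratified_kfold(TABLE_LABELS, 1, seed=0)

    def test_small_class_warns_not_duplicates(self):
        labels = np.array([0] * 10 + [1] * 3)
        with pytest.warns(UserWarning, match="3 items"):
            assign = stratified_kfold(labels, 5, seed=0)
        assert (assign.fold_of >= 0).all()
        assert np.bincount(assign.fold_of[labels == 1]).max() == 1


class TestFitNetwork:
    def test_history_learning_rates_match_schedule_exactly(self):
        X, y = micro_data()
        cfg = TrainConfig(schedule=ScheduleConfig(eta_max=1e-3, t_warmup=1, t_total=4),
                          max_epochs=4, checkpoint_epochs=(), seed=0, mixup=None)
        net = micro_network()
        history, _, _ = fit_network(net, X, y, X, y, cfg)
        for row in history:
            assert row["lr"] == lr_at(row["epoch"], cfg.schedule)

    def test_gradient_accumulation_update_count(self):
        """24 samples, micro-batch 8, accumulation 2 -> ceil(3/2) = 2 updates."""
        X, y = micro_data(n_per_class=8, n_classes=3)
        cfg = TrainConfig(schedule=ScheduleConfig(eta_max=1e-4, t_warmup=1, t_total=3),
                          micro_batch=8, accumulation=2, max_epochs=1,
                          checkpoint_epochs=(), seed=0, mixup=None)
        history, _, _ = fit_network(micro_network(), X, y, X, y, cfg)
        assert history[0]["updates"] == 2

    def test_early_stop_with_frozen_metric_at_patience_plus_one(self):
        """Zero learning rate freezes macro F1, so patience 7 stops at epoch 8."""
        X, y = micro_data(n_per_class=4, n_classes=2)
        cfg = TrainConfig(schedule=ScheduleConfig(eta_max=0.0, t_warmup=1, t_total=20),
                          patience=7, max_epochs=20, checkpoint_epochs=(),
                          seed=0, mixup=None)
        history, _, best = fit_network(micro_network(), X, y, X, y, cfg)
        assert len(history) == 8
        assert best == 1

    def test_snapshots_at_checkpoint_epochs_plus_best(self):
        X, y = micro_data(n_per_class=4, n_classes=3)
        cfg = TrainConfig(schedule=ScheduleConfig(eta_max=1e-3, t_warmup=1, t_total=5),
                          max_epochs=5, checkpoint_epochs=(2, 4), seed=0, mixup=None)
        history, snapshots, best = fit_network(micro_network(), X, y, X, y, cfg)
        assert {"epoch2", "epoch4", "best"} <= set(snapshots)
        assert 1 <= best <= len(history)

    def test_best_epoch_is_argmax_of_history(self):
        X, y = micro_data(n_per_class=6, n_classes=3)
        cfg = TrainConfig(schedule=ScheduleConfig(eta_max=2e-3, t_warmup=1, t_total=6),
                          max_epochs=6, checkpoint_epochs=(), seed=0, mixup=None)
        history, _, best = fit_network(micro_network(), X, y, X, y, cfg)
        f1s = [row["val_macro_f1"] for row in history]
        assert f1s[best - 1] == max(f1s)

    def test_same_seed_reproduces_first_epoch_loss(self):
        X, y = micro_data()
        cfg = TrainConfig(schedule=ScheduleConfig(eta_max=1e-3, t_warmup=1, t_total=2),
                          max_epochs=2, checkpoint_epochs=(), seed=5, mixup=None)
        h1, _, _ = fit_network(micro_network(seed=1), X, y, X, y, cfg)
        h2, _, _ = fit_network(micro_network(seed=1), X, y, X, y, cfg)
        assert h1[0]["train_loss"] == pytest.approx(h2[0]["train_loss"], abs=1e-6)


class TestRunFold:
    def test_persists_checkpoints_history_and_config(self, tmp_path):
        X, y = micro_data(n_per_class=6, n_classes=3)
        cfg = TrainConfig(schedule=ScheduleConfig(eta_max=1e-3, t_warmup=1, t_total=3),
                          max_epochs=3, checkpoint_epochs=(2,), seed=0, mixup=None)
        run_fold(micro_network(), X, y, X[::3], y[::3], cfg,
                 out_dir=tmp_path / "fold0", fold_id=0)
        assert (tmp_path / "fold0" / "epoch2.ckpt.npz").exists()
        assert (tmp_path / "fold0" / "best.ckpt.npz").exists()
        assert (tmp_path / "fold0" / "config.yaml").exists()
        header = (tmp_path / "fold0" / "history.csv").read_text().splitlines()[0]
        assert header == "epoch,train_loss,val_loss,val_acc,val_macro_f1,lr"

    def test_single_class_fold_rejected(self):
        X, y = micro_data(n_per_class=4, n_classes=1)
        cfg = TrainConfig(schedule=ScheduleConfig(eta_max=1e-3, t_warmup=1, t_total=2),
                          max_epochs=2, checkpoint_epochs=(), seed=0, mixup=None)
        with pytest.raises(ValueError):
            run_fold(micro_network(), X, y, X, y, cfg)


class TestTrainConfig:
    def test_checkpoint_epochs_validated_against_schedule(self):
        with pytest.raises(ValueError):
            TrainConfig(schedule=ScheduleConfig(t_total=10), checkpoint_epochs=(15,))

    def test_accumulation_and_patience_bounds(self):
        with pytest.raises(ValueError):
            TrainConfig(accumulation=0)
        with pytest.raises(ValueError):
            TrainConfig(patience=0)
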