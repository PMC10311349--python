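"""Contrastive loss values, LR schedule, and training behaviour at toy scale."""

import numpy as np
import pytest

import panelhic as ph
from panelhic import nn, training
from panelhic.training import ContrastiveBatch, contrastive_loss, learning_rate


class TestLearningRateSchedule:
    def test_endpoints(self):
        cfg = ph.TrainConfig(epochs=100, warmup_epochs=5, lr=1e-3, final_lr=1e-6)
        assert learning_rate(0, cfg) == 0.0
        assert learning_rate(5, cfg) == pytest.approx(1e-3)
        assert learning_rate(95, cfg) == pytest.approx(1e-6)
        assert learning_rate(100, cfg) == pytest.approx(1e-6)

    def test_warmup_is_linear_and_decay_monotone(self):
        cfg = ph.TrainConfig(epochs=100, warmup_epochs=5, lr=1e-3, final_lr=1e-6)
        assert learning_rate(2, cfg) == pytest.approx(0.4e-3)
        lrs = [learning_rate(e, cfg) for e in range(5, 96)]
        assert np.all(np.diff(lrs) <= 1e-15)


class TestContrastiveLoss:
    def test_equal_similarity_single_negative_is_log2(self):
        h = np.array([[1.0, 0.0]])
        pos = np.array([[1.0, 0.0]])
        neg = np.array([[[1.0, 0.0]]])  # same similarity as the positive
        loss = contrastive_loss(ContrastiveBatch(h_i=h, h_i_plus=pos,
                                                 h_j_minus=neg))
        assert float(loss.data) == pytest.approx(np.log(2.0), abs=1e-12)

    def test_dominant_positive_drives_loss_to_zero(self):
        h = np.array([[10.0, 0.0]])
        pos = np.array([[10.0, 0.0]])     # sim = 100
        neg = np.array([[[-10.0, 0.0]]])  # sim = -100
        loss = contrastive_loss(ContrastiveBatch(h_i=h, h_i_plus=pos,
                                                 h_j_minus=neg))
        assert float(loss.data) < 1e-8

    def test_matches_scalar_loop_oracle_with_explicit_negatives(self):
        rng = np.random.default_rng(0)
        b, k, m = 5, 4, 6
        h = rng.normal(size=(b, m))
        pos = rng.normal(size=(b, m))
        neg = rng.normal(size=(b, k, m))
        tau = 1.0
        # independent scalar-loop evaluation of the InfoNCE objective
        expect = 0.0
        for i in range(b):
            sp = np.exp(np.dot(h[i], pos[i]) / tau)
            sn = sum(np.exp(np.dot(h[i], neg[i, j]) / tau) for j in range(k))
            expect += -np.log(sp / (sp + sn))
        expect /= b
        loss = contrastive_loss(ContrastiveBatch(h_i=h, h_i_plus=pos,
                                                 h_j_minus=neg, tau=tau))
        assert float(loss.data) == pytest.approx(expect, abs=1e-8)

    def test_in_batch_negatives_match_scalar_loop(self):
        rng = np.random.default_rng(1)
        b, m = 5, 6
        h = rng.normal(size=(b, m))
        pos = rng.normal(size=(b, m))
        expect = 0.0
        for i in range(b):
            sims = np.array([np.dot(h[i], pos[j]) for j in range(b)])
            e = np.exp(sims)
            expect += -np.log(e[i] / e.sum())
        expect /= b
        loss = contrastive_loss(ContrastiveBatch(h_i=h, h_i_plus=pos))
        assert float(loss.data) == pytest.approx(expect, abs=1e-8)

    def test_zero_negatives_is_an_error(self):
        h = np.ones((1, 2))
        with pytest.raises(ValueError, match="negative"):
            contrastive_loss(ContrastiveBatch(h_i=h, h_i_plus=h,
                                              h_j_minus=np.ones((1, 0, 2))))
        with pytest.raises(ValueError, match="negatives"):
            contrastive_loss(ContrastiveBatch(h_i=h, h_i_plus=h))


@pytest.fixture(scope="module")
def tiny_world():
    """A 160-bin study chromosome with a 2-sample panel, w=40, d=4."""
    base = ph.GenomeSpec.random(n_bins=160, n_loops=14, seed=21)
    study_ct = ph.CellTypeSpec(base=base, dropped_loop_fraction=0.2, seed=31)
    raw = ph.sample_counts(ph.expected_map(study_ct), 400_000, seed=41)
    dataset = ph.build_dataset(raw, w=40, trim=10,
                               levels=(1.0, 0.25, 0.0625), seed=51)
    rng = np.random.default_rng(61)
    corners = list(dataset.corners)
    rng.shuffle(corners)
    train_set = ph.PatchDataset(dataset.level_maps, dataset.target_map,
                                corners[:8], 40)
    val_set = ph.PatchDataset(dataset.level_maps, dataset.target_map,
                              corners[8:11], 40)
    panel_maps = []
    for s in (71, 81):
        ct = ph.CellTypeSpec(base=base, dropped_loop_fraction=0.2, seed=s)
        cm = ph.sample_counts(ph.expected_map(ct), 400_000, seed=s + 1)
        panel_maps.append(ph.ice_balance(cm))
    return train_set, val_set, panel_maps


class TestPretraining:
    def test_loss_decreases_and_is_seed_deterministic(self, tiny_world):
        train_set, _, _ = tiny_world
        cfg = ph.TrainConfig(batch_size=8, epochs=10, pretrain_epochs=4,
                             patience=5, seed=3)
        m1 = ph.RefPanelUNet(ph.ModelConfig(w=40, d=4), seed=3)
        losses1 = ph.pretrain_encoder(train_set, m1, cfg)
        assert losses1[-1] < losses1[0]
        m2 = ph.RefPanelUNet(ph.ModelConfig(w=40, d=4), seed=3)
        losses2 = ph.pretrain_encoder(train_set, m2, cfg)
        assert losses1 == losses2

    def test_single_region_dataset_is_rejected(self, tiny_world):
        train_set, _, _ = tiny_world
        solo = ph.PatchDataset(train_set.level_maps, train_set.target_map,
                               train_set.corners[:1], 40)
        cfg = ph.TrainConfig(batch_size=8, epochs=10, pretrain_epochs=1, seed=0)
        with pytest.raises(ValueError, match="two regions"):
            ph.pretrain_encoder(solo, ph.RefPanelUNet(
                ph.ModelConfig(w=40, d=4), seed=0), cfg)


class TestMainTraining:
    def test_short_training_beats_untrained_model(self, tiny_world):
        train_set, val_set, panel_maps = tiny_world
        cfg = ph.TrainConfig(batch_size=4, epochs=6, warmup_epochs=2,
                             patience=6, refs_per_example=2, seed=5)
        model = ph.RefPanelUNet(ph.ModelConfig(w=40, d=4), seed=5)
        untrained_val = training._validation_l1(model, val_set, panel_maps, {})
        result = ph.train(model, train_set, val_set, panel_maps, cfg)
        assert result.best_val < untrained_val
        assert list(result.history.columns) == ["epoch", "train_l1", "val_l1", "lr"]

    def test_missing_validation_set_is_rejected(self, tiny_world):
        train_set, _, panel_maps = tiny_world
        cfg = ph.TrainConfig(epochs=2, warmup_epochs=1, seed=0)
        with pytest.raises(ValueError, match="validation"):
            ph.train(ph.RefPanelUNet(ph.ModelConfig(w=40, d=4)), train_set,
                     None, panel_maps, cfg)

    def test_early_stopping_halts_on_non_improving_validation(
            self, tiny_world, monkeypatch):
        train_set, val_set, panel_maps = tiny_world
        vals = iter([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        monkeypatch.setattr(training, "_validation_l1",
                            lambda *a, **k: next(vals))
        cfg = ph.TrainConfig(batch_size=4, epochs=50, warmup_epochs=2,
                             patience=1, refs_per_example=2, seed=0)
        model = ph.RefPanelUNet(ph.ModelConfig(w=40, d=4), seed=0)
        result = ph.train(model, train_set, val_set, panel_maps, cfg)
        assert result.history["epoch"].iloc[-1] == 2  # stopped, not 50
        assert result.best_epoch == 1

    def test_same_seed_reproduces_training_history(self, tiny_world):
        train_set, val_set, panel_maps = tiny_world
        cfg = ph.TrainConfig(batch_size=4, epochs=3, warmup_epochs=1,
                             patience=5, refs_per_example=2, seed=7)
        runs = []
        for _ in range(2):
            model = ph.RefPanelUNet(ph.ModelConfig(w=40, d=4), seed=7)
            runs.append(ph.train(model, train_set, val_set, panel_maps,
                                 cfg).history)
        assert runs[0].equals(runs[1])
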