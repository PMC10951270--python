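"""Dataset splitting, learning-rate schedules, training-loop contracts."""

import numpy as np
import pytest

from glycospec.network import GlycoSpectrumNetwork, ModelConfig
from glycospec.simulate import SimConfig, generate_dataset
from glycospec.training import (
    TrainConfig,
    evaluate_spectra,
    finetune,
    lr_at,
    split_dataset,
    train,
    train_b_model,
)

TINY = ModelConfig(hidden_size=12, dropout=0.0)
TINY_B = ModelConfig(hidden_size=12, dropout=0.0, with_B=True)


@pytest.fixture(scope="module")
def dataset():
    obs, truths, _ = generate_dataset(SimConfig(seed=31, n_precursors=30))
    return obs


@pytest.fixture(scope="module")
def dataset_b():
    obs, truths, _ = generate_dataset(
        SimConfig(seed=32, n_precursors=24, with_B=True)
    )
    return obs


class TestSplit:
    @pytest.mark.parametrize("n,sizes", [(10, (6, 2, 2)), (100, (60, 20, 20))])
    def test_sizes(self, n, sizes):
        parts = split_dataset(list(range(n)), seed=0)
        assert tuple(len(p) for p in parts) == sizes

    def test_disjoint_and_complete(self):
        parts = split_dataset(list(range(57)), seed=3)
        merged = sorted(x for p in parts for x in p)
        assert merged == list(range(57))

    def test_seed_reproducible(self):
        a = split_dataset(list(range(40)), seed=5)
        b = split_dataset(list(range(40)), seed=5)
        assert a == b
        c = split_dataset(list(range(40)), seed=6)
        assert a != c

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            split_dataset([1, 2, 3, 4], seed=0)


class TestLearningRateSchedule:
    def test_warmup_endpoints(self):
        cfg = TrainConfig()
        assert lr_at(0, cfg) == 0.0
        assert lr_at(5, cfg) == pytest.approx(0.001)

    def test_cosine_midpoint(self):
        cfg = TrainConfig()
        assert lr_at(12.5, cfg) == pytest.approx(0.0005)

    def test_warm_restarts_double(self):
        cfg = TrainConfig()
        # restart boundaries: warmup 5 + intervals 15, 30, ...
        assert lr_at(20.0, cfg) == pytest.approx(0.001)
        assert lr_at(35.0, cfg) == pytest.approx(0.0005)  # mid of 30-epoch leg
        assert lr_at(50.0, cfg) == pytest.approx(0.001)

    def test_linear_warmup(self):
        cfg = TrainConfig()
        assert lr_at(2.5, cfg) == pytest.approx(0.0005)


class TestTrain:
    def test_loss_decreases_and_history_complete(self, dataset):
        net = GlycoSpectrumNetwork(TINY, seed=1)
        tc = TrainConfig(seed=1, max_epochs=8, batch_size=8)
        hist = train(net, dataset[:24], dataset[24:], tc)
        assert len(hist) == 8
        assert hist["loss_total"].iloc[-1] < hist["loss_total"].iloc[0]
        for col in ("loss_total", "loss_pep", "loss_gly", "loss_ratio"):
            assert hist[col].notna().all()

    def test_dwa_weights_sum_to_task_count(self, dataset):
        net = GlycoSpectrumNetwork(TINY, seed=2)
        tc = TrainConfig(seed=2, max_epochs=5, batch_size=8)
        hist = train(net, dataset[:16], dataset[16:20], tc)
        w = hist[["w_total", "w_pep", "w_gly", "w_ratio"]].to_numpy()
        assert np.allclose(w.sum(axis=1), 4.0, atol=1e-9)
        assert np.allclose(w[:2], 1.0)  # first two epochs uniform

    def test_reproducible_history(self, dataset):
        tc = TrainConfig(seed=7, max_epochs=3, batch_size=8)
        h1 = train(GlycoSpectrumNetwork(TINY, seed=3), dataset[:16], [], tc)
        h2 = train(GlycoSpectrumNetwork(TINY, seed=3), dataset[:16], [], tc)
        assert np.allclose(
            h1["loss_total"].to_numpy(), h2["loss_total"].to_numpy(), atol=1e-6
        )

    def test_frozen_parameters_bitwise_unchanged(self, dataset):
        net = GlycoSpectrumNetwork(TINY, seed=4)
        frozen = net.peptide_encoder_param_names()
        before = {k: net.params()[k].data.copy() for k in frozen}
        tc = TrainConfig(seed=4, max_epochs=2, batch_size=8)
        train(net, dataset[:16], [], tc, frozen=frozen)
        after = net.params()
        for k in frozen:
            assert np.array_equal(before[k], after[k].data)
        # and unfrozen parameters did change
        assert any(
            not np.array_equal(p.data, before.get(k, p.data + 1))
            for k, p in after.items()
            if k not in frozen
        )


class TestFinetune:
    def test_plateau_reduces_lr(self, dataset):
        net = GlycoSpectrumNetwork(TINY, seed=5)
        # constant loss surface: empty-gradient plateau via zero lr-equivalents
        tc = TrainConfig(
            seed=5, max_epochs=8, batch_size=8, finetune_lr=1e-9,
            finetune_patience=2, plateau_threshold=1e-3,
        )
        hist = finetune(net, dataset[:8], dataset[8:12], tc)
        # with an (effectively) frozen model validation never improves:
        # after the first epoch sets the incumbent best, patience 2 decays lr
        # at epochs 3 and 6
        assert hist["lr"].iloc[-1] == pytest.approx(1e-11, rel=1e-6)

    def test_improving_run_keeps_lr(self, dataset):
        net = GlycoSpectrumNetwork(TINY, seed=6)
        tc = TrainConfig(
            seed=6, max_epochs=4, batch_size=8, finetune_lr=0.003,
            finetune_patience=5,
        )
        hist = finetune(net, dataset[:16], dataset[16:24], tc)
        assert np.allclose(hist["lr"].to_numpy(), 0.003)

    def test_finetuning_does_not_worsen_validation(self, dataset):
        base = GlycoSpectrumNetwork(TINY, seed=7)
        tc = TrainConfig(seed=7, max_epochs=6, batch_size=8)
        train(base, dataset[:16], dataset[16:24], tc)
        from glycospec.training import _validation_loss

        before = _validation_loss(base, dataset[16:24])
        finetune(base, dataset[:16], dataset[16:24],
                 TrainConfig(seed=8, max_epochs=4, batch_size=8))
        after = _validation_loss(base, dataset[16:24])
        assert after <= before + 1e-9


class TestTrainB:
    def test_only_b_head_changes(self, dataset_b):
        net = GlycoSpectrumNetwork(TINY_B, seed=8)
        before = {k: p.data.copy() for k, p in net.params().items()}
        tc = TrainConfig(seed=8, max_epochs=3, batch_size=8)
        train_b_model(net, dataset_b[:16], dataset_b[16:20], tc)
        after = net.params()
        for k, p in after.items():
            if k.startswith("b_head"):
                assert not np.array_equal(before[k], p.data)
            else:
                assert np.array_equal(before[k], p.data)

    def test_y_predictions_unchanged(self, dataset_b):
        net = GlycoSpectrumNetwork(TINY_B, seed=9)
        rec = dataset_b[0]
        y_before = net.predict(rec.index).y.copy()
        tc = TrainConfig(seed=9, max_epochs=2, batch_size=8)
        train_b_model(net, dataset_b[:12], [], tc)
        assert np.array_equal(net.predict(rec.index).y, y_before)

    def test_b_similarity_improves(self, dataset_b):
        net = GlycoSpectrumNetwork(TINY_B, seed=10)
        hold = dataset_b[18:]
        before = evaluate_spectra(net, hold)["sa_B"].median()
        tc = TrainConfig(seed=10, max_epochs=12, batch_size=8)
        train_b_model(net, dataset_b[:18], [], tc)
        after = evaluate_spectra(net, hold)["sa_B"].median()
        assert after < before

    def test_requires_b_head(self, dataset_b):
        net = GlycoSpectrumNetwork(TINY, seed=11)
        with pytest.raises(ValueError):
            train_b_model(net, dataset_b[:8], [], TrainConfig(max_epochs=1))
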