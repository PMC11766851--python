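"""Scheduler, optimiser loop, evaluation, checkpointing, ablation parity."""

import numpy as np
import pytest

from ecatbrats.model import (ECATBraTS, ModelConfig, attention_parameter_count,
                             tiny_model_config)
from ecatbrats.blocks import AttentionConfig, ShuffleConfig
from ecatbrats.encoder import EncoderConfig
from ecatbrats.training import (TrainConfig, cosine_lr, evaluate,
                                load_checkpoint, save_checkpoint, tiny_cohort,
                                train)


class TestCosineLR:
    def test_start_is_lr_max(self):
        cfg = TrainConfig(lr_max=5e-5, lr_min=0.0, epochs=100)
        assert cosine_lr(0, cfg) == pytest.approx(5e-5)

    def test_end_is_lr_min(self):
        cfg = TrainConfig(lr_max=5e-5, lr_min=1e-6, epochs=100)
        assert cosine_lr(100, cfg) == pytest.approx(1e-6)

    def test_midpoint_is_average(self):
        cfg = TrainConfig(lr_max=4e-4, lr_min=2e-4, epochs=100)
        assert cosine_lr(50, cfg) == pytest.approx(3e-4)

    def test_epoch_beyond_horizon_rejected(self):
        cfg = TrainConfig(epochs=10)
        with pytest.raises(ValueError):
            cosine_lr(11, cfg)

    def test_lr_min_above_lr_max_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_max=1e-5, lr_min=1e-4)


def _mini_setup(seed=0, epochs=3):
    cohort = tiny_cohort(2, seed=seed)
    model = ECATBraTS(tiny_model_config(seed))
    cfg = TrainConfig(lr_max=1e-3, epochs=epochs, batch_size=2, seed=seed,
                      val_interval=10)
    return model, cohort, cfg


class TestTrainLoop:
    def test_zero_epochs_leaves_weights_unchanged(self):
        model, cohort, _ = _mini_setup()
        before = {k: v.copy() for k, v in model.state_dict().items()}
        cfg = TrainConfig(epochs=0)
        state = train(model, cohort, cfg)
        assert state.epoch == 0 and state.history == []
        after = model.state_dict()
        for k in before:
            np.testing.assert_array_equal(before[k], after[k])

    def test_same_seed_gives_identical_loss_history(self):
        histories = []
        for _ in range(2):
            model, cohort, cfg = _mini_setup(seed=5, epochs=3)
            state = train(model, cohort, cfg)
            histories.append([h["train_loss"] for h in state.history])
        assert histories[0] == histories[1]

    def test_loss_decreases_over_early_epochs(self):
        """Average training loss over epochs 3-5 falls below epochs 0-2."""
        model, cohort, cfg = _mini_setup(seed=1, epochs=6)
        cfg.lr_max = 5e-3
        state = train(model, cohort, cfg)
        losses = [h["train_loss"] for h in state.history]
        assert np.mean(losses[3:]) < np.mean(losses[:3])
        assert losses[-1] < losses[0]

    def test_empty_cohort_rejected(self):
        model, _, cfg = _mini_setup()
        with pytest.raises(ValueError, match="empty"):
            train(model, [], cfg)

    def test_case_without_mask_rejected_for_training(self):
        model, cohort, cfg = _mini_setup()
        cohort[0].mask = None
        with pytest.raises(ValueError, match="no mask"):
            train(model, cohort, cfg)


class _IdentityModel:
    """Stand-in 'model' whose prediction is the ground truth itself."""

    def __init__(self, cases):
        self._lookup = {id(c.volume.intensities): c.mask for c in cases}
        self._cases = list(cases)
        self._i = 0

    def predict(self, intensities):
        case = self._cases[self._i]
        self._i += 1
        return case.mask.channels.astype(np.float32)


class TestEvaluate:
    def test_ground_truth_scores_perfectly(self, tiny_cases):
        report = evaluate(_IdentityModel(tiny_cases), tiny_cases)
        assert np.allclose(report.per_case["dsc"], 1.0)
        assert np.allclose(report.per_case["iou"], 1.0)
        assert np.allclose(report.per_case["hd"], 0.0)

    def test_empty_cohort_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="empty"):
            evaluate(tiny_model, [])

    def test_cases_without_masks_are_skipped_and_counted(self, tiny_cases):
        import copy
        cases = [copy.copy(c) for c in tiny_cases]
        cases[1] = copy.copy(cases[1])
        cases[1].mask = None
        report = evaluate(_IdentityModel(cases), cases)
        assert report.skipped == 1
        assert set(report.per_case["case_id"]) == {cases[0].case_id}

    def test_mean_row_recomputable_from_region_rows(self, tiny_cases):
        report = evaluate(_IdentityModel(tiny_cases), tiny_cases)
        for metric in ("dsc", "iou", "hd"):
            region_means = [report.summary.loc[(metric, r), "mean"]
                            for r in ("WT", "TC", "ET")]
            assert report.summary.loc[(metric, "Mean"), "mean"] == pytest.approx(
                np.mean(region_means))


class TestCheckpoint:
    def test_roundtrip_reproduces_evaluation_bitwise(self, tmp_path, tiny_cases):
        model, cohort, cfg = _mini_setup(seed=2, epochs=1)
        state = train(model, cohort, cfg)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, cfg, state)
        restored, meta = load_checkpoint(path)
        r1 = evaluate(model, cohort)
        r2 = evaluate(restored, cohort)
        for col in ("dsc", "iou", "hd"):
            np.testing.assert_array_equal(r1.per_case[col].to_numpy(),
                                          r2.per_case[col].to_numpy())
        assert meta["epoch"] == 1
        assert meta["model_config"]["encoder"]["embed_dim"] == 8

    def test_checkpoint_preserves_running_stats(self, tmp_path):
        model, cohort, cfg = _mini_setup(seed=3, epochs=1)
        train(model, cohort, cfg)
        path = tmp_path / "c.npz"
        save_checkpoint(path, model, cfg,
                        __import__("ecatbrats.training", fromlist=["TrainState"]
                                   ).TrainState())
        restored, _ = load_checkpoint(path)
        a = dict(model.named_buffers())
        b = dict(restored.named_buffers())
        assert a.keys() == b.keys()
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])


def _variant(shuffle: bool, attention: bool) -> ModelConfig:
    return ModelConfig(
        encoder=EncoderConfig(embed_dim=8, num_heads=(2, 2, 2, 2),
                              window_size=(4, 4, 4)),
        shuffle=ShuffleConfig(enabled=shuffle),
        attention=AttentionConfig(enabled=attention),
        seed=0,
    )


class TestAblationParity:
    def test_four_variants_constructible_and_counts_match_closed_form(self):
        counts = {}
        for shuffle in (True, False):
            for attention in (True, False):
                model = ECATBraTS(_variant(shuffle, attention))
                counts[(shuffle, attention)] = model.parameter_count()
        # shuffling is parameter-free
        assert counts[(True, True)] == counts[(False, True)]
        assert counts[(True, False)] == counts[(False, False)]
        # attention adds exactly the closed-form FC parameter count
        expected_delta = attention_parameter_count(_variant(True, True))
        assert counts[(True, True)] - counts[(True, False)] == expected_delta

    def test_shuffle_groups_two_supported(self):
        cfg = _variant(True, True)
        cfg.shuffle.groups = 2
        model = ECATBraTS(cfg)
        assert model.cfg.shuffle.groups == 2
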