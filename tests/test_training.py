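"""Schedule, losses, hyperparameter sampling, freezing, and the train loop."""

import math

import numpy as np
import pytest

import molfuse as mf
from molfuse.encoder import TinyTransformerEncoder
from molfuse.exceptions import DomainError, NonFiniteLossError
from molfuse.fusion import Mode, collate
from molfuse.training import (HyperparameterSpace, TrainConfig, compute_loss,
                              freeze_layers, lr_schedule,
                              sample_hyperparameters, train_model)
from test_fusion import build


def tiny_train_config_full_freeze():
    from molfuse.experiments import tiny_train_config
    return tiny_train_config(seed=0, epochs=3)


class TestLrSchedule:
    def test_closed_form_over_grid(self):
        for w in range(1, 6):
            for e in range(1, 101):
                expected = 0.01 * min(e / w, math.sqrt(w / e))
                assert lr_schedule(e, w, 0.01) == pytest.approx(
                    expected, abs=1e-15)

    def test_peak_at_warmup(self):
        for w in range(1, 6):
            rates = [lr_schedule(e, w, 1.0) for e in range(1, 101)]
            assert max(rates) == pytest.approx(1.0)
            assert rates[w - 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("w, e, expected", [
        (4, 1, 0.25), (4, 4, 1.0), (4, 16, 0.5),
    ])
    def test_hand_values(self, w, e, expected):
        assert lr_schedule(e, w, 1.0) == pytest.approx(expected)

    def test_epoch_domain(self):
        with pytest.raises(DomainError):
            lr_schedule(0, 2, 1.0)


class TestComputeLoss:
    def test_perfect_fit_zero(self, regression_task):
        assert compute_loss([1.0, 2.0], [1.0, 2.0], regression_task) == 0.0

    def test_rmse_hand_value(self, regression_task):
        got = compute_loss([0.0, 0.0], [3.0, 4.0], regression_task)
        assert got == pytest.approx(math.sqrt(12.5), abs=1e-12)

    def test_bce_coin_flip(self, classification_task):
        got = compute_loss([0.5, 0.5], [0.0, 1.0], classification_task)
        assert got == pytest.approx(math.log(2.0), abs=1e-12)

    def test_bce_rejects_soft_targets(self, classification_task):
        with pytest.raises(DomainError):
            compute_loss([0.5], [0.3], classification_task)

    def test_length_mismatch(self, regression_task):
        with pytest.raises(DomainError):
            compute_loss([1.0], [1.0, 2.0], regression_task)

    def test_matches_independent_formulas_on_random_vectors(self):
        rng = np.random.default_rng(0)
        reg_rmse = mf.TaskSpec(name="r", task_type="regression")
        reg_mae = mf.TaskSpec(name="m", task_type="regression",
                              training_loss="mae")
        clf = mf.TaskSpec(name="c", task_type="classification")
        for _ in range(20):
            n = int(rng.integers(2, 50))
            p = rng.standard_normal(n)
            t = rng.standard_normal(n)
            assert compute_loss(p, t, reg_rmse) == pytest.approx(
                np.sqrt(((p - t) ** 2).sum() / n), abs=1e-9)
            assert compute_loss(p, t, reg_mae) == pytest.approx(
                np.abs(p - t).sum() / n, abs=1e-9)
            probs = rng.uniform(0.01, 0.99, n)
            y = (rng.random(n) < 0.5).astype(float)
            ref = -(y * np.log(probs) + (1 - y) * np.log(1 - probs)).mean()
            assert compute_loss(probs, y, clf) == pytest.approx(ref,
                                                                abs=1e-9)


class TestSampleHyperparameters:
    def test_bounds_respected_over_many_draws(self):
        space = HyperparameterSpace()
        seen_warmup, seen_freeze = set(), set()
        for seed in range(2000):
            cfg = sample_hyperparameters(space, seed)
            assert 1e-5 <= cfg.lr_coder <= 1e-2
            assert 1e-9 <= cfg.lr_lang <= 1e-6
            assert 0.1 <= cfg.dense_dropout <= 0.5
            seen_warmup.add(cfg.warmup_epochs)
            seen_freeze.add(cfg.freeze_layer_count)
        assert seen_warmup == {1, 2, 3, 4, 5}
        assert seen_freeze == {0, 1, 2, 3}

    def test_same_seed_same_config(self):
        space = HyperparameterSpace()
        assert sample_hyperparameters(space, 17) \
            == sample_hyperparameters(space, 17)

    def test_loguniform_spreads_across_decades(self):
        space = HyperparameterSpace()
        draws = [sample_hyperparameters(space, s).lr_coder
                 for s in range(500)]
        decades = {int(np.floor(np.log10(d))) for d in draws}
        assert {-5, -4, -3} <= decades


class TestFreezeLayers:
    def test_frozen_layers_bit_identical_after_epoch(self, regression_task,
                                                     tok_spec,
                                                     prepared_records):
        from dataclasses import replace
        model = build(regression_task, seed=5)
        cfg = replace(tiny_train_config_full_freeze(),
                      freeze_layer_count=model.encoder.layer_count)
        frozen_before = {name: p.data.copy()
                         for name, p in model.encoder.named_parameters()}
        train_model(model, prepared_records[:20], prepared_records[20:30],
                    cfg, tok_spec.pad_id)
        # a fully frozen encoder is bit-identical; only post-encoder
        # parameters updated
        for name, p in model.encoder.named_parameters():
            np.testing.assert_array_equal(p.data, frozen_before[name])

    def test_freeze_zero_touches_embeddings_only(self, regression_task):
        # embedding tables are always excluded from fine-tuning updates;
        # n counts transformer blocks
        model = build(regression_task, seed=5)
        freeze_layers(model.encoder, 0)
        assert not model.encoder.tok_embed.requires_grad
        assert not model.encoder.pos_embed.requires_grad
        for block in model.encoder.blocks:
            assert all(p.requires_grad for p in block.parameters())

    def test_unfrozen_encoder_updates(self, regression_task, tok_spec,
                                      prepared_records, tiny_config):
        model = build(regression_task, seed=5)
        before = model.encoder.blocks[0].ff1.W.data.copy()
        train_model(model, prepared_records[:20], prepared_records[20:30],
                    tiny_config, tok_spec.pad_id)
        assert not np.array_equal(model.encoder.blocks[0].ff1.W.data, before)

    def test_freeze_count_out_of_range(self, regression_task):
        model = build(regression_task)
        with pytest.raises(DomainError):
            freeze_layers(model.encoder, model.encoder.layer_count + 1)


class TestTrainModel:
    def test_loss_decreases_on_small_regression(self, regression_task,
                                                tok_spec, prepared_records):
        model = build(regression_task, seed=2)
        cfg = TrainConfig(lr_coder=5e-3, lr_lang=5e-3, epochs=5,
                          dense_dropout=0.1, seed=2)
        res = train_model(model, prepared_records[:40],
                          prepared_records[40:], cfg, tok_spec.pad_id)
        assert res.history.train_loss.iloc[-1] \
            < res.history.train_loss.iloc[0]

    def test_history_length_equals_epochs(self, regression_task, tok_spec,
                                          prepared_records, tiny_config):
        model = build(regression_task)
        res = train_model(model, prepared_records[:20],
                          prepared_records[20:30], tiny_config,
                          tok_spec.pad_id)
        assert len(res.history) == tiny_config.epochs
        assert res.best_epoch in res.history.epoch.values

    def test_graph_only_has_single_param_group(self, regression_task,
                                               tok_spec, prepared_records,
                                               tiny_config):
        model = build(regression_task, mode="graph")
        assert model.encoder_parameters() == []
        res = train_model(model, prepared_records[:20],
                          prepared_records[20:30], tiny_config,
                          tok_spec.pad_id)
        assert np.isfinite(res.best_metric)

    def test_identical_seeds_identical_metrics(self, regression_task,
                                               tok_spec, prepared_records,
                                               tiny_config):
        metrics = []
        for _ in range(2):
            model = build(regression_task, seed=9)
            res = train_model(model, prepared_records[:30],
                              prepared_records[30:40], tiny_config,
                              tok_spec.pad_id)
            metrics.append(res.history.valid_metric.tolist())
        assert metrics[0] == metrics[1]

    def test_dual_learning_rates_follow_schedule(self, regression_task,
                                                 tok_spec, prepared_records):
        cfg = TrainConfig(lr_coder=1e-3, lr_lang=1e-5, warmup_epochs=2,
                          epochs=4, dense_dropout=0.1, seed=0)
        model = build(regression_task)
        res = train_model(model, prepared_records[:20],
                          prepared_records[20:30], cfg, tok_spec.pad_id)
        for _, row in res.history.iterrows():
            e = int(row.epoch)
            assert row.lr_coder == pytest.approx(lr_schedule(e, 2, 1e-3))
            assert row.lr_lang == pytest.approx(lr_schedule(e, 2, 1e-5))

    def test_nonfinite_loss_aborts(self, regression_task, tok_spec,
                                   prepared_records):
        model = build(regression_task)
        cfg = TrainConfig(lr_coder=1e6, lr_lang=1e6, epochs=5,
                          dense_dropout=0.1, seed=0)
        with pytest.raises(NonFiniteLossError):
            train_model(model, prepared_records[:30],
                        prepared_records[30:40], cfg, tok_spec.pad_id)
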