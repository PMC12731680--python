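"""Metrics against brute-force oracles, loss closed forms, training contracts."""

import numpy as np
import pytest

from crackspec.errors import ParameterError
from crackspec.nn import NetworkConfig, build_model
from crackspec.train_eval import (ConfusionCounts, TrainConfig,
                                  compute_metrics, confusion_counts,
                                  evaluate_model, focal_dice_loss,
                                  paired_comparison, split_dataset, train)


class TestSplitDataset:
    def test_400_ids_at_8_1_1(self):
        tr, va, te = split_dataset(list(range(400)), (8, 1, 1), seed=0)
        assert (len(tr), len(va), len(te)) == (320, 40, 40)
        assert sorted(tr + va + te) == list(range(400))

    def test_exact_apportionment_small(self):
        tr, va, te = split_dataset(list(range(10)), (8, 1, 1), seed=1)
        assert (len(tr), len(va), len(te)) == (8, 1, 1)

    def test_determinism_and_seed_sensitivity(self):
        ids = list(range(60))
        assert split_dataset(ids, seed=4) == split_dataset(ids, seed=4)
        assert split_dataset(ids, seed=4) != split_dataset(ids, seed=5)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            split_dataset([], (8, 1, 1))


class TestFocalDiceLoss:
    def test_perfect_prediction_is_zero(self):
        target = np.zeros((4, 8, 8))
        target[:, 2:4, 2:4] = 1.0
        loss = focal_dice_loss(target.copy(), target)
        assert loss == pytest.approx(0.0, abs=1e-5)

    def test_inverted_prediction_is_clamp_maximum(self):
        target = np.zeros((2, 6, 6))
        target[0, 1, 1] = 1.0
        worst = focal_dice_loss(1.0 - target, target)
        mild = focal_dice_loss(np.full_like(target, 0.5), target)
        assert worst > mild > 0

    def test_uniform_half_on_background_matches_closed_form(self):
        gamma, alpha, dw = 2.0, 0.8, 0.5
        target = np.zeros((1, 10, 10))
        prob = np.full_like(target, 0.5)
        n = target.size
        focal = -(1 - alpha) * 0.25 * np.log(0.5)       # p_t = 0.5 per pixel
        dice = 1.0 - 1.0 / (0.5 * n + 0.0 + 1.0)        # smooth = 1
        expected = dw * dice + (1 - dw) * focal
        assert focal_dice_loss(prob, target, gamma=gamma, alpha=alpha,
                               dice_weight=dw) == pytest.approx(expected,
                                                                rel=1e-6)

    def test_gradient_matches_finite_differences(self, rng):
        prob = rng.uniform(0.05, 0.95, size=(3, 5, 5))
        target = (rng.random((3, 5, 5)) > 0.7).astype(float)
        loss, grad = focal_dice_loss(prob, target, return_grad=True)
        for _ in range(8):
            idx = np.unravel_index(rng.integers(prob.size), prob.shape)
            eps = 1e-6
            p2 = prob.copy()
            p2[idx] += eps
            num = (focal_dice_loss(p2, target) - loss) / eps
            assert num == pytest.approx(grad[idx], rel=1e-3, abs=1e-7)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(Exception):
            focal_dice_loss(np.zeros((2, 4, 4)), np.zeros((2, 5, 5)))


class TestConfusion:
    def test_perfect_prediction_counts(self):
        gt = np.zeros((10, 10), dtype=np.uint8)
        gt[:1, :5] = 1
        c = confusion_counts(gt, gt)
        assert (c.TP, c.FP, c.FN, c.TN) == (5, 0, 0, 95)

    def test_all_positive_prediction(self):
        gt = np.zeros((10, 10), dtype=np.uint8)
        gt[0, :5] = 1
        c = confusion_counts(np.ones_like(gt), gt)
        assert (c.TP, c.FP, c.FN) == (5, 95, 0)

    def test_matches_pixel_loop_oracle(self, rng):
        for _ in range(200):
            pred = (rng.random((8, 8)) > 0.6).astype(np.uint8)
            gt = (rng.random((8, 8)) > 0.8).astype(np.uint8)
            c = confusion_counts(pred, gt)
            tp = fp = fn = tn = 0
            for i in range(8):
                for j in range(8):
                    if pred[i, j] and gt[i, j]:
                        tp += 1
                    elif pred[i, j]:
                        fp += 1
                    elif gt[i, j]:
                        fn += 1
                    else:
                        tn += 1
            assert (c.TP, c.FP, c.FN, c.TN) == (tp, fp, fn, tn)


class TestMetrics:
    def test_worked_example(self):
        rep = compute_metrics(ConfusionCounts(3, 1, 2, 94))
        assert rep.iou == pytest.approx(0.5)
        assert rep.precision == pytest.approx(0.75)
        assert rep.recall == pytest.approx(0.6)
        assert rep.f1 == pytest.approx(2 / 3, abs=1e-4)

    def test_both_empty_sentinel(self):
        rep = compute_metrics(ConfusionCounts(0, 0, 0, 100))
        assert (rep.iou, rep.precision, rep.recall, rep.f1) == (1, 1, 1, 1)

    def test_f1_iou_identity_on_random_counts(self, rng):
        for _ in range(300):
            c = ConfusionCounts(*rng.integers(0, 50, size=4))
            rep = compute_metrics(c)
            assert rep.f1 == pytest.approx(2 * rep.iou / (1 + rep.iou),
                                           abs=1e-12)
            assert rep.iou <= rep.f1 + 1e-12


class TestPairedComparison:
    def test_identical_runs(self):
        t, p = paired_comparison([0.7] * 5, [0.7] * 5)
        assert (t, p) == (0.0, 1.0)

    def test_consistent_improvement_significant(self):
        a = np.array([0.75, 0.76, 0.74, 0.75, 0.76])
        b = a - 0.05 + 1e-3 * np.array([1, -1, 0.5, -0.5, 0.2])
        t, p = paired_comparison(a, b)
        assert p < 0.05 and t > 0
        # closed-form check: t = mean(d) / (sd(d)/sqrt(n))
        d = a - b
        t_manual = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        assert t == pytest.approx(t_manual)

    def test_swap_negates_t_preserves_p(self, rng):
        a = rng.random(5)
        b = rng.random(5)
        t1, p1 = paired_comparison(a, b)
        t2, p2 = paired_comparison(b, a)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class _ConstantModel:
    """Stub with frozen output for exercising the training-loop contract."""

    kind = "stub"

    def __init__(self):
        self.cfg = NetworkConfig(in_bands=3, encoder_units=1,
                                 base_channels=2)
        self.input_mean, self.input_std = 0.0, 1.0

    def parameters(self):
        return []

    def layers(self):
        return []

    def zero_grad(self):
        pass

    def prepare_input(self, cubes):
        return cubes

    def forward(self, x, training=False):
        return np.full(x.shape[:3], 0.3, dtype=np.float32)

    def backward(self, grad):
        pass


def _toy_dataset(rng, n=3):
    data = []
    for _ in range(n):
        cube = rng.random((8, 8, 3), dtype=np.float32)
        mask = np.zeros((8, 8), dtype=np.uint8)
        mask[2:4, 2:6] = 1
        data.append((cube, mask))
    return data


class TestTrainLoop:
    def test_early_stop_after_patience_without_improvement(self, rng):
        ds = _toy_dataset(rng)
        cfg = TrainConfig(epochs=50, batch_size=2, learning_rate=0.0,
                          patience=4, crop_size=None, seed=0)
        _, history = train(_ConstantModel(), ds, ds, cfg)
        assert len(history["val_loss"]) == cfg.patience + 1

    def test_history_never_exceeds_epochs(self, rng):
        ds = _toy_dataset(rng)
        cfg = TrainConfig(epochs=3, batch_size=2, learning_rate=0.0,
                          patience=10, crop_size=None, seed=0)
        _, history = train(_ConstantModel(), ds, ds, cfg)
        assert len(history["train_loss"]) == 3

    def test_training_reduces_loss_and_is_reproducible(self, rng):
        ds = _toy_dataset(rng, n=4)
        cfg = NetworkConfig(in_bands=3, encoder_units=1, base_channels=3)
        tc = TrainConfig(epochs=6, batch_size=2, learning_rate=3e-3,
                         patience=7, crop_size=None, scheduler_t0=6, seed=1)
        m1, h1 = train(build_model("cnn1d", cfg, seed=1), ds, ds, tc)
        m2, h2 = train(build_model("cnn1d", cfg, seed=1), ds, ds, tc)
        assert h1["train_loss"][-1] < h1["train_loss"][0]
        assert h1["train_loss"] == h2["train_loss"]
        for p, q in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p.data, q.data)

    def test_evaluate_model_reports_pooled_and_per_image(self, rng):
        ds = _toy_dataset(rng, n=2)
        cfg = NetworkConfig(in_bands=3, encoder_units=1, base_channels=2)
        model = build_model("cnn1d", cfg, seed=0)
        pooled, per_image = evaluate_model(model, ds)
        assert len(per_image) == 2
        assert 0.0 <= pooled.f1 <= 1.0
        assert pooled.counts.total == 2 * 64
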