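"""Schedule, augmentation, perturbations, metrics and optimization
sanity (single-batch memorization)."""

import numpy as np
import pytest

from pointattn.geometry import PointCloud
from pointattn.networks import ClassifierConfig, build_classifier
from pointattn.synthetic import ShapeSpec, make_dataset, make_shape
from pointattn.training import (EvalReport, TrainConfig, augment, cosine_lr,
                                cross_entropy, evaluate, miou, perturb,
                                perturbation_sweep, train)
from pointattn.autodiff import Tensor


class TestSchedule:
    def test_closed_form_endpoints_and_midpoint(self):
        E = 40
        assert cosine_lr(0, E) == pytest.approx(0.03)
        assert cosine_lr(E // 2, E) == pytest.approx(0.015)
        assert cosine_lr(E, E) == pytest.approx(0.0, abs=1e-15)

    def test_trace_matches_closed_form_and_nonincreasing(self):
        E = 17
        trace = np.array([cosine_lr(e, E) for e in range(E + 1)])
        expected = 0.015 * (1 + np.cos(np.pi * np.arange(E + 1) / E))
        np.testing.assert_allclose(trace, expected, rtol=1e-12)
        assert (np.diff(trace) <= 0).all()


class TestAugment:
    def test_translation_within_bounds_and_multiset_preserved(self):
        cloud = make_shape(ShapeSpec("cube", n=64, jitter=0.0, seed=0))
        cfg = TrainConfig(scale_low=1.0, scale_high=1.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            out = augment(cloud, cfg, rng)
            # undo the pure translation and compare point multisets
            t = out.coords.mean(axis=0) - cloud.coords.mean(axis=0)
            assert (np.abs(t) <= 0.2 + 1e-9).all()
            restored = np.sort((out.coords - t).round(12), axis=0)
            np.testing.assert_allclose(restored,
                                       np.sort(cloud.coords.round(12), axis=0),
                                       atol=1e-9)

    def test_zero_width_ranges_identity_up_to_shuffle(self):
        cloud = make_shape(ShapeSpec("sphere", n=32, jitter=0.0, seed=1))
        cfg = TrainConfig(translate_range=0.0, scale_low=1.0, scale_high=1.0)
        out = augment(cloud, cfg, np.random.default_rng(2))
        np.testing.assert_allclose(np.sort(out.coords, axis=0),
                                   np.sort(cloud.coords, axis=0), atol=1e-12)

    def test_labels_shuffled_consistently(self):
        coords = np.random.default_rng(3).normal(size=(16, 3))
        labels = np.arange(16)
        cloud = PointCloud(coords, point_labels=labels, cloud_label=0)
        cfg = TrainConfig(translate_range=0.0, scale_low=1.0, scale_high=1.0)
        out = augment(cloud, cfg, np.random.default_rng(4))
        np.testing.assert_allclose(out.coords, coords[out.point_labels])


class TestPerturb:
    def test_zero_rotation_identity(self):
        cloud = make_shape(ShapeSpec("torus", n=20, seed=2))
        out = perturb(cloud, "rotate", angle_deg=0.0, axis="x")
        np.testing.assert_allclose(out.coords, cloud.coords, atol=1e-12)

    def test_rotation_preserves_norms(self):
        cloud = make_shape(ShapeSpec("torus", n=50, seed=3))
        out = perturb(cloud, "rotate", angle_deg=25.0, axis="y")
        np.testing.assert_allclose(np.linalg.norm(out.coords, axis=1),
                                   np.linalg.norm(cloud.coords, axis=1),
                                   rtol=1e-12)

    def test_full_dropout_identity_up_to_order(self):
        cloud = make_shape(ShapeSpec("cube", n=30, seed=4))
        out = perturb(cloud, "dropout", np.random.default_rng(0), n_keep=30)
        np.testing.assert_allclose(np.sort(out.coords, axis=0),
                                   np.sort(cloud.coords, axis=0))

    def test_dropout_validation(self):
        cloud = make_shape(ShapeSpec("cube", n=10, seed=5))
        with pytest.raises(ValueError):
            perturb(cloud, "dropout", np.random.default_rng(0), n_keep=0)
        with pytest.raises(ValueError):
            perturb(cloud, "dropout", np.random.default_rng(0), n_keep=11)

    def test_translate_offsets(self):
        cloud = make_shape(ShapeSpec("cube", n=10, seed=6))
        out = perturb(cloud, "translate", offset=np.array([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.coords - cloud.coords,
                                   np.broadcast_to([1.0, 2, 3], (10, 3)))


def _report_oracle(y, preds):
    """Brute-force counting oracle for OA and mean class recall."""
    oa = 100.0 * np.mean(preds == y)
    recalls = [100.0 * np.mean(preds[y == c] == c) for c in np.unique(y)]
    return oa, float(np.mean(recalls))


class TestEvaluate:
    class _Stub:
        """Model stand-in with fixed predictions."""

        def __init__(self, preds):
            self.preds = preds

    def test_counting_oracle_on_random_sets(self, monkeypatch):
        import pointattn.training as tr
        rng = np.random.default_rng(9)
        for _ in range(25):
            n = int(rng.integers(5, 60))
            m = int(rng.integers(2, 6))
            y = rng.integers(0, m, size=n)
            preds = rng.integers(0, m, size=n)
            clouds = [PointCloud(np.zeros((1, 3)), cloud_label=int(c))
                      for c in y]
            monkeypatch.setattr(tr, "predict",
                                lambda ds, model, batch_size=32: preds)
            report = tr.evaluate(clouds, self._Stub(preds))
            oa, mca = _report_oracle(y, preds)
            assert report.overall_accuracy == pytest.approx(oa)
            assert report.mean_class_accuracy == pytest.approx(mca)

    def test_two_class_size_imbalance_definition(self, monkeypatch):
        import pointattn.training as tr
        y = np.array([0] * 90 + [1] * 10)
        preds = np.array([0] * 90 + [0] * 10)   # class 1 fully wrong
        clouds = [PointCloud(np.zeros((1, 3)), cloud_label=int(c)) for c in y]
        monkeypatch.setattr(tr, "predict",
                            lambda ds, model, batch_size=32: preds)
        report = tr.evaluate(clouds, self._Stub(preds))
        assert report.overall_accuracy == pytest.approx(90.0)
        assert report.mean_class_accuracy == pytest.approx(50.0)

    def test_report_invariant_to_dataset_order(self, monkeypatch):
        import pointattn.training as tr
        rng = np.random.default_rng(10)
        y = rng.integers(0, 3, size=30)
        preds = rng.integers(0, 3, size=30)
        clouds = [PointCloud(np.zeros((1, 3)), cloud_label=int(c)) for c in y]
        perm = rng.permutation(30)

        monkeypatch.setattr(tr, "predict",
                            lambda ds, model, batch_size=32: preds)
        r1 = tr.evaluate(clouds, self._Stub(preds))
        monkeypatch.setattr(tr, "predict",
                            lambda ds, model, batch_size=32: preds[perm])
        r2 = tr.evaluate([clouds[i] for i in perm], self._Stub(preds))
        assert r1.overall_accuracy == pytest.approx(r2.overall_accuracy)
        assert r1.mean_class_accuracy == pytest.approx(r2.mean_class_accuracy)


def _miou_oracle(pred, gt, parts):
    ious = []
    for p in parts:
        inter = np.sum((pred == p) & (gt == p))
        union = np.sum((pred == p) | (gt == p))
        ious.append(1.0 if union == 0 else inter / union)
    return np.mean(ious)


class TestMiou:
    def test_perfect_prediction(self):
        labels = np.array([0, 0, 1, 1])
        cls, inst = miou([labels], [labels], [0], {0: [0, 1]})
        assert cls == pytest.approx(100.0)
        assert inst == pytest.approx(100.0)

    def test_half_swapped_two_part_shape_is_one_third(self):
        # equal part sizes, half of each part swapped: IoU = 1/3 per part
        gt = np.array([0, 0, 1, 1])
        pred = np.array([0, 1, 0, 1])
        cls, inst = miou([pred], [gt], [0], {0: [0, 1]})
        assert inst == pytest.approx(100.0 / 3.0)
        assert cls == pytest.approx(100.0 / 3.0)

    def test_absent_part_counts_as_unity(self):
        gt = np.array([0, 0, 0])
        pred = np.array([0, 0, 0])
        cls, inst = miou([pred], [gt], [0], {0: [0, 1]})
        assert inst == pytest.approx(100.0)

    def test_label_outside_part_set_rejected(self):
        with pytest.raises(ValueError, match="part set"):
            miou([np.array([0])], [np.array([2])], [0], {0: [0, 1]})

    def test_random_sets_match_brute_force(self):
        rng = np.random.default_rng(12)
        part_sets = {0: [0, 1, 2], 1: [3, 4]}
        preds, gts, cats = [], [], []
        for _ in range(30):
            cat = int(rng.integers(0, 2))
            parts = part_sets[cat]
            n = int(rng.integers(3, 40))
            gts.append(rng.choice(parts, size=n))
            preds.append(rng.choice(parts, size=n))
            cats.append(cat)
        cls, inst = miou(preds, gts, cats, part_sets)
        shape_ious = [_miou_oracle(p, g, part_sets[c])
                      for p, g, c in zip(preds, gts, cats)]
        assert inst == pytest.approx(100.0 * np.mean(shape_ious))
        per_cat = [np.mean([s for s, c in zip(shape_ious, cats) if c == cat])
                   for cat in (0, 1)]
        assert cls == pytest.approx(100.0 * np.mean(per_cat))


class TestCrossEntropy:
    def test_matches_log_softmax_identity(self):
        rng = np.random.default_rng(13)
        logits = rng.normal(size=(6, 4))
        y = rng.integers(0, 4, size=6)
        val = float(cross_entropy(Tensor(logits), y).data)
        ref = -np.mean(logits[np.arange(6), y]
                       - np.log(np.exp(logits).sum(axis=1)))
        assert val == pytest.approx(ref, rel=1e-10)


class TestOptimization:
    def test_single_batch_memorization(self):
        """A small network drives the loss on one batch of 8 clouds below
        0.01 within 200 steps."""
        clouds = [make_shape(ShapeSpec(fam, n=64, jitter=0.01, seed=s))
                  for s, fam in enumerate(
                      ["sphere", "cube", "torus", "cylinder"] * 2)]
        cfg = ClassifierConfig(layer_channels=(8, 8, 16, 16), k=8,
                               global_dim=32, head_width=32, n_classes=4,
                               attn_hidden=8, dropout=0.0)
        model = build_classifier(cfg, seed=0, dtype=np.float32)
        tcfg = TrainConfig(epochs=200, batch_size=8, augment=False, seed=0,
                           weight_decay=0.0)
        train(clouds, model, tcfg)
        losses = [e["loss"] for e in model.epoch_log]
        assert min(losses) < 0.01

    def test_empty_dataset_rejected(self):
        model = build_classifier(ClassifierConfig(
            layer_channels=(4, 4, 4, 4), k=2, global_dim=8, head_width=8,
            n_classes=2, attn_hidden=4), seed=0)
        with pytest.raises(ValueError):
            train([], model, TrainConfig(epochs=1))

    def test_epoch_log_records_cosine_trace(self):
        clouds = [make_shape(ShapeSpec("sphere", n=16, seed=s,
                                       jitter=0.02)) for s in range(4)]
        for i, c in enumerate(clouds):
            c.cloud_label = i % 2
        cfg = ClassifierConfig(layer_channels=(4, 4, 4, 4), k=4,
                               global_dim=8, head_width=8, n_classes=2,
                               attn_hidden=4)
        model = build_classifier(cfg, seed=0, dtype=np.float32)
        E = 6
        train(clouds, model, TrainConfig(epochs=E, batch_size=4, seed=0))
        lrs = [e["lr"] for e in model.epoch_log]
        np.testing.assert_allclose(
            lrs, [0.015 * (1 + np.cos(np.pi * e / E)) for e in range(E)],
            rtol=1e-9)
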