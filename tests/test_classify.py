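"""Classifier contracts: softmax correctness and stability, the augmentation
policy's parameter ranges, the two-stage training schedule, prediction, and
the hand-written CNN's gradients."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from herdid import (
    AugmentationParams,
    ClassifierSpec,
    TrainingSchedule,
    augment,
    augment_batch,
    predict_batch,
    predict_labels,
    softmax,
    softmax_matrix,
    train_two_stage,
)
from herdid.classify import NearestCentroidBackbone, draw_augmentation
from herdid.errors import ArgumentError, DataError
from herdid.smallcnn import SmallCNN


class TestSoftmax:
    def test_two_equal_logits_split_evenly(self):
        cv = softmax([0.0, 0.0])
        np.testing.assert_allclose(cv.p, [0.5, 0.5])

    def test_constant_vector_is_uniform_and_shift_invariant(self):
        k = 7
        cv = softmax(np.full(k, 3.2))
        np.testing.assert_allclose(cv.p, np.full(k, 1 / k), atol=1e-12)
        z = np.array([0.3, -1.2, 2.0])
        np.testing.assert_allclose(softmax(z).p, softmax(z + 100.0).p, atol=1e-12)

    def test_reference_values(self):
        # independent evaluation of e^{z_i}/sum_j e^{z_j} at z = (1, 2, 3)
        cv = softmax([1.0, 2.0, 3.0])
        np.testing.assert_allclose(
            cv.p, [0.09003057, 0.24472847, 0.66524096], atol=1e-8
        )
        assert cv.predicted_label == 2
        assert cv.confidence == pytest.approx(0.66524096, abs=1e-8)

    def test_stable_under_huge_logits(self):
        cv = softmax([1000.0, 999.0])
        assert np.all(np.isfinite(cv.p))
        assert cv.p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_non_finite_logits_rejected(self):
        with pytest.raises(ArgumentError):
            softmax([np.nan, 0.0])
        with pytest.raises(ArgumentError):
            softmax([np.inf, 0.0])

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_extended_precision_oracle(self, seed):
        """Float64 softmax agrees with a long-double evaluation to 1e-12."""
        rng = np.random.default_rng(seed)
        z = rng.uniform(-50, 50, size=rng.integers(2, 20))
        expected = np.exp(z.astype(np.longdouble))
        expected = (expected / expected.sum()).astype(float)
        np.testing.assert_allclose(softmax(z).p, expected, atol=1e-12)

    def test_confidence_permutation_equivariant(self):
        z = np.array([0.4, -1.0, 2.2, 0.0])
        perm = np.array([2, 0, 3, 1])
        base = softmax(z)
        permuted = softmax(z[perm])
        np.testing.assert_allclose(permuted.p, base.p[perm], atol=1e-15)
        assert permuted.confidence == pytest.approx(base.confidence)


class TestAugmentation:
    def test_realized_factors_stay_in_configured_ranges(self):
        params = AugmentationParams()
        rng = np.random.default_rng(1)
        draws = [draw_augmentation(params, rng) for _ in range(1000)]
        assert all(0.2 <= d.brightness <= 1.5 for d in draws)
        assert all(0.9 <= d.zoom <= 1.1 for d in draws)
        # both flips occur and are roughly balanced
        assert 300 < sum(d.hflip for d in draws) < 700
        assert 300 < sum(d.vflip for d in draws) < 700

    def test_same_seed_reproduces_image(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, size=(24, 32), dtype=np.uint8)
        a = augment(img, AugmentationParams(), rng_seed=17)
        b = augment(img, AugmentationParams(), rng_seed=17)
        np.testing.assert_array_equal(a, b)
        assert a.dtype == img.dtype

    def test_no_op_params_leave_image_unchanged(self):
        img = np.random.default_rng(0).random((16, 16))
        params = AugmentationParams(
            zoom_range=0.0, brightness_range=(1.0, 1.0),
            horizontal_flip=False, vertical_flip=False,
        )
        np.testing.assert_allclose(augment(img, params, rng_seed=5), img)

    def test_batch_values_stay_clipped(self):
        rng = np.random.default_rng(2)
        batch = rng.random((8, 16, 32))
        out = augment_batch(batch, AugmentationParams(), rng)
        assert out.shape == batch.shape
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ArgumentError):
            AugmentationParams(zoom_range=1.5)
        with pytest.raises(ArgumentError):
            AugmentationParams(brightness_range=(0.0, 1.0))


class TestSmallCNNGradients:
    def test_backprop_matches_numeric_gradients(self):
        """Analytic gradients agree with central differences on a tiny net."""
        m = SmallCNN(input_hw=(8, 8), n_classes=3, channels=(2, 3, 4), fc_dim=5,
                     dtype=np.float64)
        m.initialize(0)
        rng = np.random.default_rng(1)
        x = rng.random((4, 8, 8))
        y = np.array([0, 1, 2, 0])

        def loss():
            z, _ = m._forward(x[:, None])
            zs = z - z.max(axis=1, keepdims=True)
            p = np.exp(zs)
            p /= p.sum(axis=1, keepdims=True)
            return -np.log(p[np.arange(4), y]).mean()

        z, cache = m._forward(x[:, None], keep_cache=True)
        zs = z - z.max(axis=1, keepdims=True)
        p = np.exp(zs)
        p /= p.sum(axis=1, keepdims=True)
        dz = p.copy()
        dz[np.arange(4), y] -= 1
        dz /= 4
        grads = m._backward(dz, cache)

        eps = 1e-6
        for name, grad in grads.items():
            flat = m.params[name].ravel()
            for i in rng.choice(flat.size, size=min(6, flat.size), replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss()
                flat[i] = old - eps
                lm = loss()
                flat[i] = old
                numeric = (lp - lm) / (2 * eps)
                rel = abs(numeric - grad.ravel()[i]) / max(
                    1e-8, abs(numeric) + abs(grad.ravel()[i])
                )
                assert rel < 1e-4, f"gradient mismatch in {name}"


class TestTrainTwoStage:
    def test_empty_train_set_rejected(self):
        spec = ClassifierSpec(n_classes=2)
        with pytest.raises(ArgumentError):
            train_two_stage(spec, np.zeros((0, 16, 32)), np.zeros(0), TrainingSchedule())

    def test_label_out_of_range_rejected(self, separable_images):
        images, labels = separable_images
        spec = ClassifierSpec(n_classes=2)
        with pytest.raises(DataError, match="outside"):
            train_two_stage(spec, images, labels + 5, TrainingSchedule())

    def test_zero_stage2_equals_stage1_only(self, separable_images):
        images, labels = separable_images
        spec = ClassifierSpec(n_classes=2)
        s1 = TrainingSchedule(stage1_epochs=3, stage2_epochs=0, seed=5)
        s2 = TrainingSchedule(stage1_epochs=3, stage2_epochs=0, seed=5)
        a = train_two_stage(spec, images, labels, s1, AugmentationParams())
        b = train_two_stage(spec, images, labels, s2, AugmentationParams())
        probe = images[::7]
        np.testing.assert_array_equal(a.predict_logits(probe), b.predict_logits(probe))

    def test_same_seed_trains_identically(self, separable_images):
        images, labels = separable_images
        spec = ClassifierSpec(n_classes=2)
        sched = TrainingSchedule(stage1_epochs=2, stage2_epochs=3, seed=9)
        a = train_two_stage(spec, images, labels, sched, AugmentationParams())
        b = train_two_stage(spec, images, labels, sched, AugmentationParams())
        probe = images[::5]
        np.testing.assert_array_equal(a.predict_logits(probe), b.predict_logits(probe))

    def test_separable_fixture_reaches_high_training_accuracy(self, separable_images):
        """A linear reference attains 1.0 on this construction; the trained
        model must approach it (>= 0.95 training accuracy)."""
        images, labels = separable_images
        spec = ClassifierSpec(n_classes=2)
        # flips stay off: the class signal IS the left/right position, and a
        # horizontal flip would map each class exactly onto the other
        aug = AugmentationParams(horizontal_flip=False, vertical_flip=False)
        model = train_two_stage(spec, images, labels, TrainingSchedule(seed=0), aug)
        acc = float(np.mean(predict_labels(model, images) == labels))
        assert acc >= 0.95

    def test_learns_across_seeds(self, separable_images):
        """Held-out accuracy >= 0.9 on the separable fixture for 5 seeds."""
        images, labels = separable_images
        rng = np.random.default_rng(123)
        order = rng.permutation(len(images))
        train, test = order[:70], order[70:]
        spec = ClassifierSpec(n_classes=2)
        aug = AugmentationParams(horizontal_flip=False, vertical_flip=False)
        for seed in range(5):
            model = train_two_stage(
                spec, images[train], labels[train],
                TrainingSchedule(seed=seed), aug,
            )
            acc = float(np.mean(predict_labels(model, images[test]) == labels[test]))
            assert acc >= 0.9, f"seed {seed} reached only {acc:.2f}"


@pytest.fixture(scope="module")
def model():
    rng = np.random.default_rng(0)
    x = rng.random((20, 16, 32))
    y = np.arange(20) % 2
    spec = ClassifierSpec(backbone="nearest-centroid-reference", n_classes=2)
    return train_two_stage(spec, x, y, TrainingSchedule(seed=0))


class TestPredictBatch:

    def test_empty_batch_gives_empty_list(self, model):
        assert predict_batch(model, np.zeros((0, 16, 32))) == []

    def test_outputs_are_probability_vectors_in_order(self, model):
        rng = np.random.default_rng(1)
        images = rng.random((9, 16, 32))
        out = predict_batch(model, images)
        assert len(out) == 9
        for cv in out:
            assert cv.p.sum() == pytest.approx(1.0, abs=1e-9)
            assert cv.predicted_label == int(np.argmax(cv.p))
            assert cv.confidence == pytest.approx(float(cv.p.max()))

    def test_geometry_mismatch_rejected(self, model):
        with pytest.raises(ArgumentError, match="geometry"):
            predict_batch(model, np.zeros((2, 8, 8)))


class TestNearestCentroidBackbone:
    def test_deterministic_and_centroid_consistent(self):
        rng = np.random.default_rng(4)
        x = np.concatenate([rng.random((10, 8, 8)), rng.random((10, 8, 8)) + 1.0])
        y = np.array([0] * 10 + [1] * 10)
        b = NearestCentroidBackbone((8, 8), 2)
        b.initialize(0)
        b.fit(x, y)
        pred = np.argmax(b.logits(x), axis=1)
        assert np.array_equal(pred, y)
        b2 = NearestCentroidBackbone((8, 8), 2)
        b2.initialize(99)  # seed is irrelevant by design
        b2.fit(x, y)
        np.testing.assert_array_equal(b.logits(x), b2.logits(x))


class TestCheckpointRoundTrip:
    def test_save_load_preserves_predictions(self, separable_images, tmp_path):
        from herdid.classify import load_checkpoint, save_checkpoint

        images, labels = separable_images
        spec = ClassifierSpec(n_classes=2)
        sched = TrainingSchedule(stage1_epochs=1, stage2_epochs=2, seed=3)
        model = train_two_stage(spec, images, labels, sched, AugmentationParams())
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        loaded = load_checkpoint(path)
        probe = images[::9]
        np.testing.assert_array_equal(
            model.predict_logits(probe), loaded.predict_logits(probe)
        )
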