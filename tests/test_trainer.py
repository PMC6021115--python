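"""Loss, optimizer and training-protocol semantics."""

import numpy as np
import pytest

from rbcshape import (LabeledDataset, ModelSpec, ShapeClass, TrainingConfig,
                      build_model, generate_dataset, rmse, sgdm_step,
                      split_validation, train)


class TestRmse:
    def test_zero_iff_equal(self, rng):
        x = rng.normal(size=20)
        assert rmse(x, x) == 0.0
        assert rmse(x, x + 1) > 0.0

    def test_symmetric_targets_hand_value(self):
        # sqrt((127^2 + 127^2) / 2) = 127
        assert rmse([127.0, -127.0], [0.0, 0.0]) == pytest.approx(127.0)

    def test_single_element_is_absolute_error(self):
        assert rmse([64.0], [54.0]) == pytest.approx(10.0)

    def test_empty_and_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            rmse([], [])
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])


class TestSgdmStep:
    def cfg(self, lr=0.001, mom=0.9):
        return TrainingConfig(learning_rate=lr, momentum=mom)

    def test_zero_momentum_is_plain_gradient_descent(self):
        p = [np.array([1.0, 2.0])]
        g = [np.array([10.0, -10.0])]
        v = [np.zeros(2)]
        (p2,), (v2,) = sgdm_step(p, g, v, TrainingConfig(momentum=0.0))
        np.testing.assert_allclose(p2, [1.0 - 0.01, 2.0 + 0.01])

    def test_zero_gradient_pure_coasting(self):
        p = [np.array([1.0])]
        v = [np.array([0.5])]
        (p2,), (v2,) = sgdm_step(p, [np.zeros(1)], v, self.cfg())
        np.testing.assert_allclose(v2, [0.45])
        np.testing.assert_allclose(p2, [1.45])

    def test_two_step_unroll_matches_closed_form(self):
        # constant gradient g, v0 = 0: displacement after two steps is
        # -alpha * g * (1 + (1 + gamma))
        g = np.array([3.0])
        p = [np.array([0.0])]
        v = [np.zeros(1)]
        cfg = self.cfg(lr=0.001, mom=0.9)
        for _ in range(2):
            p, v = sgdm_step(p, [g], v, cfg)
        np.testing.assert_allclose(p[0], -0.001 * g * (1 + 1.9))

    def test_non_finite_gradient_rejected(self):
        with pytest.raises(FloatingPointError):
            sgdm_step([np.zeros(1)], [np.array([np.nan])], [np.zeros(1)],
                      self.cfg())


class TestSplitValidation:
    def _ds(self, n):
        imgs = np.zeros((n, 90, 90), np.uint8)
        return LabeledDataset(imgs, [ShapeClass.SLIPPER] * n)

    def test_8000_images_give_400_validation(self):
        tr, val = split_validation(self._ds(8000), TrainingConfig())
        assert len(val) == 400 and len(tr) == 7600

    def test_half_fraction_on_two_images(self):
        cfg = TrainingConfig(validation_fraction=0.5)
        tr, val = split_validation(self._ds(2), cfg)
        assert len(tr) == 1 and len(val) == 1

    def test_same_seed_identical_partition(self):
        ds = self._ds(100)
        cfg = TrainingConfig(shuffle_seed=9)
        a = split_validation(ds, cfg)
        b = split_validation(ds, cfg)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.images, y.images)

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_validation(self._ds(5), TrainingConfig())


class TestTrain:
    def _prepped(self, n=40):
        ds = generate_dataset({"slipper": n // 2, "croissant": n // 2}, seed=0)
        from rbcshape.preprocess import mirror_augment, preprocess_images
        aug = mirror_augment(ds)
        return LabeledDataset(preprocess_images(aug.images), aug.labels)

    def test_zero_epochs_returns_model_unchanged(self):
        ds = self._prepped()
        m = build_model(ModelSpec.small(2), init_seed=0)
        before = [p.copy() for p in m.parameters()]
        m2, trace = train(m, ds, TrainingConfig(max_epochs=0))
        assert trace.stop_reason == "max_epochs"
        assert trace.iterations == [] and trace.validations == []
        for a, b in zip(before, m2.parameters()):
            np.testing.assert_array_equal(a, b)

    def test_other_labels_rejected(self):
        ds = generate_dataset({"other": 20}, seed=0)
        m = build_model(ModelSpec.small(2), init_seed=0)
        with pytest.raises(ValueError, match="other"):
            train(m, LabeledDataset(ds.images.astype(float), ds.labels))

    def test_empty_dataset_rejected(self):
        m = build_model(ModelSpec.small(2), init_seed=0)
        with pytest.raises(ValueError):
            train(m, LabeledDataset(np.zeros((0, 90, 90)), []))

    def test_early_stop_after_patience_rising_validations(self):
        """A stubbed validation evaluator that rises every call must trip
        the stop at exactly the patience-th consecutive increase."""
        ds = self._prepped(60)
        m = build_model(ModelSpec.small(2), init_seed=0)
        calls = []

        def rising_val(model):
            calls.append(len(calls))
            return float(10 + len(calls))

        cfg = TrainingConfig(max_epochs=50, batch_size=8,
                             validation_frequency=2, patience=5,
                             shuffle_seed=0)
        m2, trace = train(m, ds, cfg, val_fn=rising_val)
        assert trace.stop_reason == "early_stop"
        # first increase is observed at the 2nd validation; the 5th
        # consecutive increase happens at validation #6
        assert len(trace.validations) == 6

    def test_reproducible_trace(self):
        ds = self._prepped(60)
        cfg = TrainingConfig(max_epochs=1, batch_size=16, shuffle_seed=4)
        _, t1 = train(build_model(ModelSpec.small(2), init_seed=1), ds, cfg)
        _, t2 = train(build_model(ModelSpec.small(2), init_seed=1), ds, cfg)
        assert t1.iterations == t2.iterations
        assert t1.validations == t2.validations

    def test_validation_entries_follow_frequency(self):
        ds = self._prepped(60)
        cfg = TrainingConfig(max_epochs=2, batch_size=8,
                             validation_frequency=3, shuffle_seed=0)
        _, trace = train(build_model(ModelSpec.small(2), init_seed=0), ds, cfg)
        assert all(it % 3 == 0 for it, _ in trace.validations)
        assert all(l >= 0 for _, l in trace.iterations)

    def test_fullbatch_no_momentum_descends_on_convex_surrogate(self):
        """gamma=0 and batch = |train| is full-batch gradient descent; on a
        linear model with quadratic loss the loss never increases for a
        small enough step.  Uses the optimizer directly on the surrogate."""
        rng = np.random.default_rng(0)
        A = rng.normal(size=(30, 4))
        y = rng.normal(size=30)
        w = [np.zeros(4)]
        v = [np.zeros(4)]
        cfg = TrainingConfig(momentum=0.0, learning_rate=0.01)
        losses = []
        for _ in range(50):
            r = A @ w[0] - y
            losses.append(float(r @ r))
            w, v = sgdm_step(w, [2 * A.T @ r], v, cfg)
        assert all(b <= a + 1e-12 for a, b in zip(losses, losses[1:]))
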