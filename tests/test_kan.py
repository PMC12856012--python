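import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crayfish_sexing.kan import (
    KanLayer,
    KanModel,
    KanSpec,
    KanTrainConfig,
    SplineGrid,
    bspline_basis,
    predict_kan,
    train_kan,
)


def cox_de_boor_reference(x, k, order, knots):
    """Naive recursive Cox-de Boor evaluation of one basis function."""
    if order == 0:
        return 1.0 if knots[k] <= x < knots[k + 1] else 0.0
    left = 0.0
    if knots[k + order] != knots[k]:
        left = (x - knots[k]) / (knots[k + order] - knots[k]) * \
            cox_de_boor_reference(x, k, order - 1, knots)
    right = 0.0
    if knots[k + order + 1] != knots[k + 1]:
        right = (knots[k + order + 1] - x) / (knots[k + order + 1] - knots[k + 1]) * \
            cox_de_boor_reference(x, k + 1, order - 1, knots)
    return left + right


class TestSplineBasis:
    def test_order_zero_is_interval_indicator(self):
        g = SplineGrid(grid_size=4, spline_order=0)
        x = np.array([-0.9, -0.3, 0.1, 0.9])
        b = bspline_basis(x, g)
        assert b.shape == (4, 4)
        np.testing.assert_array_equal(b.sum(axis=1), 1.0)
        assert set(np.unique(b)) == {0.0, 1.0}

    @settings(derandomize=True, max_examples=60)
    @given(st.floats(-1.0, 1.0, exclude_max=True),
           st.integers(1, 8), st.integers(1, 4))
    def test_partition_of_unity_inside_domain(self, x, grid_size, order):
        g = SplineGrid(grid_size, order)
        b = bspline_basis(np.array([x]), g)
        assert abs(b.sum() - 1.0) < 1e-9
        assert (b >= -1e-12).all() and (b <= 1 + 1e-12).all()

    def test_matches_recursive_reference_oracle(self):
        g = SplineGrid(grid_size=5, spline_order=3)
        t = g.knots
        for x in [0.3, -0.77, 0.999, -1.0, 0.0]:
            b = bspline_basis(np.array([x]), g)[0]
            ref = [cox_de_boor_reference(x, k, 3, t) for k in range(g.n_basis)]
            np.testing.assert_allclose(b, ref, atol=1e-12)

    def test_knot_vector_length(self):
        g = SplineGrid(grid_size=5, spline_order=3)
        assert len(g.knots) == 5 + 2 * 3 + 1
        assert np.all(np.diff(g.knots) > 0)

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            SplineGrid(grid_size=0)
        with pytest.raises(ValueError):
            SplineGrid(low=1.0, high=-1.0)


class TestLayerForward:
    def test_zero_weights_zero_output(self):
        layer = KanLayer(3, 2, SplineGrid())
        layer.base_weights[...] = 0.0
        layer.spline_weights[...] = 0.0
        out = layer.forward(np.random.default_rng(0).uniform(-1, 1, (4, 3)))
        np.testing.assert_array_equal(out, 0.0)

    def test_spline_weights_zero_leaves_base_path(self):
        rng = np.random.default_rng(1)
        layer = KanLayer(4, 3, SplineGrid(), rng)
        layer.spline_weights[...] = 0.0
        x = rng.uniform(-1, 1, (5, 4))
        sil = x / (1.0 + np.exp(-x))
        np.testing.assert_allclose(layer.forward(x), sil @ layer.base_weights.T,
                                   atol=1e-12)

    def test_forward_matches_scalar_double_loop_oracle(self):
        rng = np.random.default_rng(2)
        g = SplineGrid(5, 3)
        layer = KanLayer(3, 2, g, rng)
        x = rng.uniform(-1.2, 1.2, (6, 3))
        out = layer.forward(x)
        sig = lambda v: 1.0 / (1.0 + np.exp(-v))
        ref = np.zeros_like(out)
        for n in range(6):
            for j in range(2):
                acc = 0.0
                for i in range(3):
                    xi = x[n, i]
                    acc += layer.base_weights[j, i] * xi * sig(xi)
                    bv = bspline_basis(np.array([xi]), g)[0]
                    for k in range(g.n_basis):
                        acc += layer.spline_weights[j, i, k] * bv[k]
                ref[n, j] = acc
        np.testing.assert_allclose(out, ref, atol=1e-10)

    def test_dimension_mismatch_rejected(self):
        layer = KanLayer(3, 2, SplineGrid())
        with pytest.raises(ValueError, match="expects"):
            layer.forward(np.zeros((2, 4)))


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(3)
        model = KanModel(KanSpec((3, 4, 1)), seed=7)
        x = rng.uniform(-1, 1, (5, 3))
        y = np.array([0.0, 1.0, 1.0, 0.0, 1.0])
        model.loss_and_grads(x, y)
        analytic = [g.copy() for _, g in model.params]
        eps = 1e-6
        for (p, _), ga in zip(model.params, analytic):
            flat, gflat = p.ravel(), ga.ravel()
            idx = rng.choice(flat.size, size=min(10, flat.size), replace=False)
            for i in idx:
                old = flat[i]
                flat[i] = old + eps
                lp = model.loss_and_grads(x, y)
                flat[i] = old - eps
                lm = model.loss_and_grads(x, y)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                assert abs(num - gflat[i]) <= 1e-4 * max(1.0, abs(num))


class TestTraining:
    def test_separable_data_high_training_accuracy(self):
        rng = np.random.default_rng(4)
        n = 200
        x = np.vstack([rng.normal(-1.5, 1, (n // 2, 2)),
                       rng.normal(1.5, 1, (n // 2, 2))])
        y = np.array(["F"] * (n // 2) + ["M"] * (n // 2))
        model, _ = train_kan(KanSpec((2, 8, 1)), x, y,
                             KanTrainConfig(max_epochs=300, seed=0))
        labels, proba = predict_kan(model, x)
        acc = float(np.mean(labels == y))
        assert acc >= 0.95
        # prediction consistency: labels follow the 0.5 threshold
        np.testing.assert_array_equal(labels, np.where(proba >= 0.5, "M", "F"))

    def test_lr_drops_are_exact_multiplications(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(-1, 1, (50, 2))
        y = (rng.random(50) < 0.5).astype(float)
        cfg = KanTrainConfig(max_epochs=120, plateau_factor=0.5,
                             plateau_patience=3, seed=1)
        _, hist = train_kan(KanSpec((2, 4, 1)), x, y, cfg)
        lrs = np.array(hist["lr"])
        assert np.all(np.diff(lrs) <= 0)
        changed = lrs[1:][lrs[1:] != lrs[:-1]]
        prev = lrs[:-1][lrs[1:] != lrs[:-1]]
        np.testing.assert_allclose(changed, prev * 0.5)

    def test_label_shuffled_data_stops_near_chance_loss(self):
        rng = np.random.default_rng(6)
        n = 200
        x = np.vstack([rng.normal(-1.5, 1, (n // 2, 2)),
                       rng.normal(1.5, 1, (n // 2, 2))])
        y = np.array(["F"] * (n // 2) + ["M"] * (n // 2))
        rng.shuffle(y)
        cfg = KanTrainConfig(max_epochs=300, early_stop_patience=5,
                             early_stop_delta=5e-3, seed=2)
        _, hist = train_kan(KanSpec((2, 4, 1)), x, y, cfg)
        assert len(hist["loss"]) < 300  # early stopping fired
        assert abs(hist["loss"][-1] - np.log(2)) < 0.15

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError):
            train_kan(KanSpec((2, 4, 1)), np.zeros((3, 2)),
                      np.array([0.0, 2.0, 1.0]))


class TestPredict:
    def test_sigmoid_boundary_and_range(self):
        model = KanModel(KanSpec((2, 1)), seed=0)
        # zero weights -> zero logit -> probability 0.5 -> labelled male
        model.layers[0].base_weights[...] = 0.0
        model.layers[0].spline_weights[...] = 0.0
        labels, proba = predict_kan(model, np.array([[0.3, -0.4]]))
        assert proba[0] == 0.5 and labels[0] == "M"
        rng = np.random.default_rng(7)
        model2 = KanModel(KanSpec((2, 3, 1)), seed=1)
        _, p = predict_kan(model2, rng.uniform(-5, 5, (20, 2)))
        assert np.all((p > 0) & (p < 1))
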