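import math

import numpy as np
import pytest

from phenocomplete import (
    ModelParams,
    ModelSpec,
    TrainConfig,
    fit,
    forward,
    impute,
    joint_loss,
    load_checkpoint,
    save_checkpoint,
)
from phenocomplete.autoencoder import init_params, loss_and_grads
from phenocomplete.synthetic_data import SyntheticConfig, generate

from conftest import make_matrix


def tiny_net():
    """P=2 (1 continuous, 1 binary), one hidden unit, hand-set weights."""
    spec = ModelSpec(n_features=2, n_continuous=1, hidden_widths=(1,))
    params = ModelParams(
        weights=[np.array([[0.5, -1.0]]), np.array([[2.0], [-1.0]])],
        biases=[np.array([0.25]), np.array([0.1, -0.2])],
    )
    return spec, params


class TestForward:
    def test_zero_params_give_zero_and_half(self):
        spec = ModelSpec(n_features=4, n_continuous=2, hidden_widths=(3,))
        params = ModelParams(
            weights=[np.zeros((3, 4)), np.zeros((4, 3))],
            biases=[np.zeros(3), np.zeros(4)],
        )
        y = forward(np.array([1.0, -2.0, 0.5, 0.0]), params, spec)
        np.testing.assert_allclose(y[:2], 0.0)
        np.testing.assert_allclose(y[2:], 0.5)

    def test_hand_traced_two_feature_net(self):
        """Scalar trace of affine -> leaky rectifier -> affine -> (id, sigmoid)."""
        spec, params = tiny_net()
        x = np.array([0.3, -0.4])
        z1 = 0.5 * 0.3 + (-1.0) * (-0.4) + 0.25  # = 0.8, positive
        h1 = z1
        out_c = 2.0 * h1 + 0.1
        out_b = 1.0 / (1.0 + math.exp(-(-1.0 * h1 - 0.2)))
        y = forward(x, params, spec)
        assert y[0] == pytest.approx(out_c, rel=1e-12)
        assert y[1] == pytest.approx(out_b, rel=1e-12)
        # negative preactivation exercises the leaky slope
        x2 = np.array([-1.0, 0.5])
        z1n = 0.5 * (-1.0) + (-1.0) * 0.5 + 0.25  # = -0.75
        h1n = 0.01 * z1n
        y2 = forward(x2, params, spec)
        assert y2[0] == pytest.approx(2.0 * h1n + 0.1, rel=1e-12)

    def test_printed_phi_variant_maps_negatives_positive(self):
        spec, params = tiny_net()
        printed = ModelSpec(
            n_features=2, n_continuous=1, hidden_widths=(1,), printed_phi=True
        )
        x = np.array([-1.0, 0.5])  # hidden preactivation -0.75
        y = forward(x, params, printed)
        assert y[0] == pytest.approx(2.0 * (-0.01 * -0.75) + 0.1, rel=1e-12)

    def test_binary_outputs_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(0)
        spec = ModelSpec(n_features=6, n_continuous=3)
        for _ in range(5):
            params = init_params(spec, rng)
            for w in params.weights:
                w *= 50.0  # push sigmoid toward saturation
            y = forward(rng.normal(size=(10, 6)), params, spec)
            assert ((y[:, 3:] > 0) & (y[:, 3:] < 1)).all()


class TestJointLoss:
    def test_perfect_continuous_reconstruction_zero(self):
        spec = ModelSpec(n_features=3, n_continuous=3)
        t = np.array([[1.0, -2.0, 0.5]])
        assert joint_loss(t, t, np.ones((1, 3), bool), spec) == 0.0

    def test_single_binary_half_prediction_is_log2(self):
        spec = ModelSpec(n_features=1, n_continuous=0)
        loss = joint_loss(
            np.array([[0.5]]), np.array([[1.0]]), np.ones((1, 1), bool), spec
        )
        assert loss == pytest.approx(math.log(2.0), rel=1e-12)

    def test_toy_matrix_matches_cellwise_hand_sum(self):
        """3x4 mixed matrix with 2 masked cells vs an explicit loop."""
        spec = ModelSpec(n_features=4, n_continuous=2)
        rng = np.random.default_rng(3)
        y = np.column_stack([rng.normal(size=(3, 2)), rng.uniform(0.1, 0.9, (3, 2))])
        t = np.column_stack(
            [rng.normal(size=(3, 2)), rng.integers(0, 2, (3, 2)).astype(float)]
        )
        m = np.ones((3, 4), dtype=bool)
        m[0, 1] = m[2, 3] = False
        expected = 0.0
        for i in range(3):
            for j in range(4):
                if not m[i, j]:
                    continue
                if j < 2:
                    expected += (y[i, j] - t[i, j]) ** 2
                else:
                    expected += -(
                        t[i, j] * math.log(y[i, j])
                        + (1 - t[i, j]) * math.log(1 - y[i, j])
                    )
        assert joint_loss(y, t, m, spec) == pytest.approx(expected, rel=1e-12)

    def test_rejects_invalid_binary_values(self):
        spec = ModelSpec(n_features=2, n_continuous=1)
        m = np.ones((1, 2), bool)
        with pytest.raises(ValueError, match="strictly"):
            joint_loss(np.array([[0.0, 1.5]]), np.array([[0.0, 1.0]]), m, spec)
        with pytest.raises(ValueError, match="0 or 1"):
            joint_loss(np.array([[0.0, 0.5]]), np.array([[0.0, 0.7]]), m, spec)


class TestGradients:
    def test_analytic_gradients_match_finite_differences(self):
        """Central finite differences on a small subnet, 1e-4 relative."""
        spec = ModelSpec(n_features=3, n_continuous=2, hidden_widths=(2,))
        rng = np.random.default_rng(5)
        params = init_params(spec, rng)
        x = rng.normal(size=(4, 3))
        t = np.column_stack(
            [rng.normal(size=(4, 2)), rng.integers(0, 2, 4).astype(float)]
        )
        m = rng.random((4, 3)) > 0.2
        _, gw, gb = loss_and_grads(params, spec, x, t, m)
        eps = 1e-6
        checked = 0
        for arrs, grads in ((params.weights, gw), (params.biases, gb)):
            for arr, g in zip(arrs, grads):
                flat = arr.ravel()
                for idx in range(0, flat.size, max(1, flat.size // 4)):
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp, _, _ = loss_and_grads(params, spec, x, t, m)
                    flat[idx] = orig - eps
                    lm, _, _ = loss_and_grads(params, spec, x, t, m)
                    flat[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert g.ravel()[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)
                    checked += 1
        assert checked >= 5


class TestFit:
    def test_zero_epochs_returns_initialized_params_empty_log(self, small_matrix):
        res = fit(small_matrix, TrainConfig(max_epochs=0, seed=1))
        assert res.log.n_epochs == 0
        assert res.log.best_epoch is None
        res.params.check_finite()

    def test_default_config_mirrors_reference_settings(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 0.1
        assert cfg.rho == 0.8
        assert cfg.batch_size == 2048
        assert cfg.max_epochs == 500

    def test_training_reduces_validation_loss(self):
        ds = generate(SyntheticConfig(n_individuals=800, seed=2))
        cfg = TrainConfig(
            max_epochs=60, batch_size=128, learning_rate=0.3, seed=3,
            scheduler_patience=30,
        )
        res = fit(ds.data, cfg)
        assert res.log.val_loss[-1] < res.log.val_loss[0]
        assert res.log.best_val_loss == min(res.log.val_loss)

    def test_checkpoint_contract_reproduces_best_val_loss(self):
        ds = generate(SyntheticConfig(n_individuals=600, seed=4))
        cfg = TrainConfig(max_epochs=30, batch_size=128, seed=5)
        res = fit(ds.data, cfg)
        x_val, t_val, m_val = res.validation_bundle
        reval = joint_loss(forward(x_val, res.params, res.spec), t_val, m_val, res.spec)
        assert reval == pytest.approx(res.log.best_val_loss, rel=1e-10)

    def test_same_seed_identical_training(self):
        data = make_matrix(n=300, seed=6)
        cfg = TrainConfig(max_epochs=15, batch_size=64, seed=7)
        a = fit(data, cfg)
        b = fit(data, cfg)
        assert a.log.val_loss == b.log.val_loss
        for wa, wb in zip(a.params.weights, b.params.weights):
            np.testing.assert_array_equal(wa, wb)


class TestImpute:
    def test_observed_cells_pass_through_exactly(self):
        data = make_matrix(n=200, seed=8)
        res = fit(data, TrainConfig(max_epochs=10, batch_size=64, seed=9))
        completed = impute(data, res.params, res.spec, res.stats)
        np.testing.assert_array_equal(
            completed[data.mask], data.values[data.mask]
        )
        assert np.isfinite(completed).all()
        # binary fills are probabilities
        assert ((completed[:, 6:] >= 0) & (completed[:, 6:] <= 1)).all()

    def test_imputation_composition_on_hand_set_net(self):
        spec, params = tiny_net()
        from phenocomplete import MaskedPhenotypeMatrix, NormalizationStats, PhenotypeSchema

        schema = PhenotypeSchema(("x", "b"), ("continuous", "binary"))
        data = MaskedPhenotypeMatrix(
            ids=("A",),
            values=np.array([[3.0, np.nan]]),
            mask=np.array([[True, False]]),
            schema=schema,
        )
        stats = NormalizationStats(
            names=("x", "b"), mean=np.array([1.0, np.nan]), sd=np.array([2.0, np.nan])
        )
        # encoder input: x z-scored to 1.0, missing binary zero-filled
        z1 = 0.5 * 1.0 + 0.25
        out_b = 1.0 / (1.0 + math.exp(-(-1.0 * z1 - 0.2)))
        completed = impute(data, params, spec, stats)
        assert completed[0, 0] == 3.0  # observed passthrough
        assert completed[0, 1] == pytest.approx(out_b, rel=1e-12)

    def test_fully_missing_row_equals_net_of_zero_vector(self):
        spec, params = tiny_net()
        from phenocomplete import MaskedPhenotypeMatrix, NormalizationStats, PhenotypeSchema

        schema = PhenotypeSchema(("x", "b"), ("continuous", "binary"))
        data = MaskedPhenotypeMatrix(
            ids=("A",),
            values=np.array([[np.nan, np.nan]]),
            mask=np.zeros((1, 2), bool),
            schema=schema,
        )
        stats = NormalizationStats(
            names=("x", "b"), mean=np.array([1.0, np.nan]), sd=np.array([2.0, np.nan])
        )
        y0 = forward(np.zeros(2), params, spec)
        completed = impute(data, params, spec, stats)
        assert completed[0, 0] == pytest.approx(y0[0] * 2.0 + 1.0, rel=1e-12)
        assert completed[0, 1] == pytest.approx(y0[1], rel=1e-12)


class TestCheckpointIO:
    def test_save_load_roundtrip(self, tmp_path):
        data = make_matrix(n=150, seed=10)
        res = fit(data, TrainConfig(max_epochs=5, batch_size=64, seed=11))
        path = tmp_path / "model.ckpt.npz"
        save_checkpoint(path, res)
        params, spec, stats = load_checkpoint(path)
        for wa, wb in zip(params.weights, res.params.weights):
            np.testing.assert_array_equal(wa, wb)
        assert spec == res.spec
        completed_a = impute(data, res.params, res.spec, res.stats)
        completed_b = impute(data, params, spec, stats)
        np.testing.assert_array_equal(completed_a, completed_b)
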