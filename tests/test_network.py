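"""Loss terms against hand computations and a normal-equations oracle;
architecture geometry; training-loop contracts."""

import numpy as np
import pandas as pd
import pytest

from collidernet.autograd import Tensor
from collidernet.experiments import simulate_matched
from collidernet.imaging import generate_synthetic_pool
from collidernet.network import (
    Adam,
    ArchitectureSpec,
    ColliderCNN,
    DegenerateBatchError,
    LossBreakdown,
    TrainConfig,
    evaluate_losses,
    loss_reg,
    loss_x,
    loss_y,
    total_loss,
    train,
)


def ols_oracle(a_rest, x):
    """Textbook normal-equations least squares with intercept."""
    X = np.column_stack([np.ones(len(x)), a_rest])
    beta = np.linalg.solve(X.T @ X, X.T @ x)
    return X @ beta


class TestLossY:
    def test_zero_at_perfect_prediction(self, rng):
        y = rng.normal(size=8)
        assert float(loss_y(y, y).data) == 0.0

    def test_hand_computed(self):
        # residuals (1, 3) -> (1 + 9) / 2 = 5
        assert float(loss_y(np.array([1.0, 3.0]), np.zeros(2)).data) == 5.0

    def test_translation_invariance(self, rng):
        yh, y = rng.normal(size=6), rng.normal(size=6)
        a = float(loss_y(yh, y).data)
        b = float(loss_y(yh + 2.5, y + 2.5).data)
        assert a == pytest.approx(b)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            loss_y(np.array([]), np.array([]))


class TestLossX:
    def test_zero_and_offset(self, rng):
        x = rng.normal(size=10)
        assert float(loss_x(x, x).data) == 0.0
        assert float(loss_x(x + 2.0, x).data) == pytest.approx(4.0)

    def test_permutation_invariance(self, rng):
        a, x = rng.normal(size=9), rng.normal(size=9)
        perm = rng.permutation(9)
        assert float(loss_x(a, x).data) == pytest.approx(
            float(loss_x(a[perm], x[perm]).data)
        )


class TestLossReg:
    def test_constant_activations_hinge_at_zero(self, rng):
        a = np.ones((20, 3)) * 4.2
        x = rng.normal(size=20)
        assert float(loss_reg(a, x).data) == pytest.approx(0.0, abs=1e-9)

    def test_perfect_column_gives_batch_variance(self, rng):
        x = rng.normal(size=30)
        a = np.column_stack([x, rng.normal(size=30)])
        # OLS hits x exactly -> penalty equals population variance of x
        assert float(loss_reg(a, x).data) == pytest.approx(x.var(), rel=1e-6)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(10):
            m = 40
            a = rng.normal(size=(m, 5))
            x = rng.normal(size=m) + a[:, 0] * rng.normal()
            ours = float(loss_reg(a, x, ridge=0.0).data)
            xhat = ols_oracle(a, x)
            expected = max(0.0, ((x - x.mean()) ** 2).mean() - ((x - xhat) ** 2).mean())
            assert ours == pytest.approx(expected, abs=1e-8)

    def test_independent_activations_small_overfit_gain(self, rng):
        m = 400
        a = rng.normal(size=(m, 5))
        x = rng.normal(size=m)
        val = float(loss_reg(a, x).data)
        # the in-sample gain of OLS on 5 junk regressors is ~ (p/m) * var
        assert 0.0 <= val < 4 * 5 / m * x.var() + 0.05

    def test_affine_reparameterization_invariance(self, rng):
        a = rng.normal(size=(35, 4))
        x = rng.normal(size=35) + 0.5 * a[:, 1]
        base = float(loss_reg(a, x, ridge=0.0).data)
        a2 = a.copy()
        a2[:, 2] = 3.0 * a2[:, 2] - 7.0  # OLS absorbs scale and shift
        assert float(loss_reg(a2, x, ridge=0.0).data) == pytest.approx(base, abs=1e-8)

    def test_replacing_column_with_collider_never_decreases(self, rng):
        a = rng.normal(size=(30, 4))
        x = rng.normal(size=30)
        base = float(loss_reg(a, x, ridge=0.0).data)
        a2 = a.copy()
        a2[:, 0] = x
        assert float(loss_reg(a2, x, ridge=0.0).data) >= base - 1e-10

    def test_degenerate_batch_rejected(self, rng):
        with pytest.raises(DegenerateBatchError):
            loss_reg(rng.normal(size=(5, 5)), rng.normal(size=5))

    def test_stop_gradient_variant_same_value(self, rng):
        a = rng.normal(size=(25, 3))
        x = rng.normal(size=25)
        diff = loss_reg(Tensor(a, requires_grad=True), x, differentiable=True)
        stop = loss_reg(Tensor(a, requires_grad=True), x, differentiable=False)
        assert float(diff.data) == pytest.approx(float(stop.data), abs=1e-12)


class TestTotalLoss:
    def test_exact_sum(self):
        parts = LossBreakdown(1.0, 2.0, 0.5)
        assert total_loss(parts) == 3.5
        assert LossBreakdown(0.0).L_total == 0.0

    def test_biased_mode_is_outcome_only(self):
        parts = LossBreakdown(L_y=1.7)  # L_x = L_reg = 0 when not computed
        assert total_loss(parts) == pytest.approx(1.7)

    def test_nonfinite_raises(self):
        from collidernet.network import TrainingDivergence

        with pytest.raises(TrainingDivergence):
            total_loss(LossBreakdown(np.nan, 0.0, 0.0))


class TestArchitecture:
    def test_geometry_and_parameter_count(self):
        net = ColliderCNN(seed=0)
        a = net.arch
        assert a.flatten_dim == 16 * 3 * 3
        # conv stack: 1->16 then 16->16 x4; fcs 144-144-144-12; acts 12->6; head
        expected = (
            (16 * 1 * 9 + 16)
            + 4 * (16 * 16 * 9 + 16)
            + (144 * 144 + 144) * 2
            + (144 * 12 + 12)
            + (12 * 6 + 6)
            + (6 + 1 + 1)
        )
        assert net.parameter_count() == expected

    def test_forward_shapes(self, rng):
        net = ColliderCNN(seed=0)
        y_hat, acts = net.forward(rng.normal(size=(3, 51, 51)), np.array([0, 1, 0]))
        assert y_hat.data.shape == (3,)
        assert acts.data.shape == (3, 6)

    def test_head_affine_identities(self, rng):
        net = ColliderCNN(seed=0)
        # zero the activation layer -> a = 0 -> y_hat = b0 + w_t * t
        net.params["act_w"].data[:] = 0.0
        net.params["act_b"].data[:] = 0.0
        net.params["b0"].data = np.asarray(0.7)
        net.params["w_t"].data = np.asarray(-0.3)
        imgs = rng.normal(size=(2, 51, 51))
        y_hat, acts = net.forward(imgs, np.array([0, 1]))
        np.testing.assert_allclose(acts.data, 0.0)
        np.testing.assert_allclose(y_hat.data, [0.7, 0.4])

    def test_treatment_flip_changes_prediction_by_beta_t(self, rng):
        net = ColliderCNN(seed=1)
        net.params["w_t"].data = np.asarray(0.8)
        img = rng.normal(size=(1, 51, 51))
        y0, _ = net.forward(img, np.array([0]))
        y1, _ = net.forward(img, np.array([1]))
        assert float((y1.data - y0.data)[0]) == pytest.approx(0.8, abs=1e-12)

    def test_min_activations_enforced(self):
        with pytest.raises(ValueError):
            ArchitectureSpec(n_activations=1)

    def test_shape_mismatch_rejected(self, rng):
        net = ColliderCNN(seed=0)
        with pytest.raises(ValueError):
            net.forward(rng.normal(size=(2, 51, 51)), np.array([1.0]))

    def test_checkpoint_roundtrip(self, tmp_path, rng):
        net = ColliderCNN(seed=5)
        net.trained = True
        net.save(tmp_path / "ckpt.npz")
        other = ColliderCNN.load(tmp_path / "ckpt.npz")
        img = rng.normal(size=(1, 51, 51))
        a = net.forward(img, np.zeros(1))[0].data
        b = other.forward(img, np.zeros(1))[0].data
        np.testing.assert_array_equal(a, b)


class TestAdam:
    def test_descends_quadratic(self):
        p = {"w": Tensor(np.array([5.0, -3.0]), requires_grad=True)}
        opt = Adam(p, lr=0.1)
        for _ in range(200):
            opt.zero_grad()
            loss = (p["w"] ** 2).sum()
            loss.backward()
            opt.step()
        np.testing.assert_allclose(p["w"].data, 0.0, atol=1e-2)


@pytest.fixture(scope="module")
def tiny_study():
    pool = generate_synthetic_pool(150, size_range_mm2=(20.0, 700.0), seed=13)
    return simulate_matched(120, 60, pool, seed=13)


class TestTraining:
    def test_training_log_and_determinism(self, tiny_study):
        cfg = TrainConfig(mode="causal", max_epochs=2, batch_size=40)
        logs = []
        for _ in range(2):
            net = ColliderCNN(seed=3)
            logs.append(
                train(net, tiny_study.matched_train, tiny_study.matched_val, cfg, seed=4)
            )
        pd.testing.assert_frame_equal(logs[0], logs[1])
        assert set(logs[0].columns) == {"epoch", "split", "L_y", "L_x", "L_reg", "L_total"}
        assert set(logs[0]["split"]) == {"train", "validation"}

    def test_biased_mode_has_no_collider_losses(self, tiny_study):
        cfg = TrainConfig(mode="biased", max_epochs=1)
        net = ColliderCNN(seed=3)
        log = train(net, tiny_study.matched_train, tiny_study.matched_val, cfg, seed=4)
        assert (log["L_x"] == 0).all()
        assert (log["L_reg"] == 0).all()

    def test_ground_truth_mode_learns_heterogeneity(self, tiny_study):
        # predicting z from the image must beat the mean predictor
        cfg = TrainConfig(mode="ground_truth", ground_truth_target="z", max_epochs=15)
        net = ColliderCNN(seed=3)
        train(net, tiny_study.matched_train, tiny_study.matched_val, cfg, seed=4)
        val = evaluate_losses(net, tiny_study.matched_val, cfg)
        var_z = tiny_study.matched_val.table["z"].var()
        assert val.L_y < var_z

    def test_attenuation_of_noisy_measurement(self, rng):
        # adding N(0, sqrt(mse)) noise to x gives R2 = var/(var+mse)
        x = rng.normal(size=20000)
        mse = 0.25
        x_noisy = x + rng.normal(0, np.sqrt(mse), size=x.size)
        r2 = np.corrcoef(x, x_noisy)[0, 1] ** 2
        assert r2 == pytest.approx(x.var() / (x.var() + mse), abs=0.02)
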