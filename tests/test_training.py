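"""Rate loss, surrogate gradient, STBP backward pass, and the training loop."""

import numpy as np
import pytest

from lsmkit import (
    NeuronParams,
    TrainConfig,
    rate_loss,
    stbp_readout_gradients,
    surrogate_grad,
    train_readout,
)
from lsmkit.reservoir import LSMModel, build_model
from lsmkit.training import one_hot


class TestRateLoss:
    def test_perfect_rate_coding_gives_zero_loss(self):
        spikes = np.zeros((1, 4, 3))
        spikes[0, :, 1] = 1.0  # correct class fires every step
        labels = np.array([[0.0, 1.0, 0.0]])
        assert rate_loss(spikes, labels).value == 0.0

    def test_two_term_arithmetic(self):
        # S=1, C=2, T=2, y=(1,0), rates (0.5, 0.5) -> ||(0.5, -0.5)||^2 = 0.5
        spikes = np.array([[[1.0, 0.0], [0.0, 1.0]]])
        labels = np.array([[1.0, 0.0]])
        assert rate_loss(spikes, labels).value == pytest.approx(0.5)

    def test_sample_permutation_invariance(self, rng):
        spikes = rng.integers(0, 2, (6, 5, 3)).astype(float)
        labels = one_hot(rng.integers(0, 3, 6), 3)
        perm = rng.permutation(6)
        assert rate_loss(spikes, labels).value == pytest.approx(
            rate_loss(spikes[perm], labels[perm]).value
        )

    def test_value_is_mean_of_per_sample(self, rng):
        spikes = rng.integers(0, 2, (4, 5, 2)).astype(float)
        labels = one_hot(rng.integers(0, 2, 4), 2)
        rl = rate_loss(spikes, labels)
        assert rl.value == pytest.approx(rl.per_sample.mean())
        assert rl.value >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            rate_loss(np.zeros((2, 3, 4)), np.zeros((3, 4)))


class TestSurrogate:
    def test_window_center_and_edges(self):
        assert surrogate_grad(np.array([0.3]), 0.3, 0.5)[0] == pytest.approx(2.0)
        assert surrogate_grad(np.array([0.3 + 0.5]), 0.3, 0.5)[0] == 0.0
        assert surrogate_grad(np.array([-10.0]), 0.3, 0.5)[0] == 0.0

    @pytest.mark.parametrize("a", [0.1, 1.0, 3.0])
    def test_unit_area(self, a):
        u = np.linspace(-10, 10, 200001)
        area = np.trapezoid(surrogate_grad(u, 0.3, a), u)
        assert area == pytest.approx(1.0, rel=2e-2)

    def test_nonpositive_width_rejected(self):
        with pytest.raises(ValueError):
            surrogate_grad(np.zeros(1), 0.3, 0.0)


def unrolled_gradient_oracle(hidden, labels, model, a):
    """Forward-mode chain-rule oracle for dL/dW_ho, written with scalar loops.

    Unrolls the readout recursion sample by sample, accumulating du/dW and
    dtheta/dW explicitly (reset factor constant, rectangular surrogate),
    independently of the trainer's reverse-mode implementation.
    """
    S, T, M = hidden.shape
    C = model.W_ho.shape[0]
    p = model.params
    d, g, th = p.decay, p.gain, p.u_th
    grad = np.zeros((C, M))
    for s in range(S):
        for c in range(C):
            for m in range(M):
                # forward pass with sensitivity of u[k] and theta[k] to W[c, m]
                u = np.zeros(C)
                du = np.zeros(C)  # du[j]/dW[c,m]; only j == c is nonzero
                theta_sum = np.zeros(C)
                dtheta_sum = 0.0
                for k in range(T):
                    theta = (u >= th).astype(float)
                    surr = 1.0 / a if abs(u[c] - th) < a / 2 else 0.0
                    dtheta_c = surr * du[c]
                    drive = (model.W_ho @ hidden[s, k - 1]) if k >= 1 else np.zeros(C)
                    ddrive = hidden[s, k - 1, m] if k >= 1 else 0.0
                    du_new = du[c] * d * (1.0 - theta[c]) + g * ddrive
                    u = u * d * (1.0 - theta) + g * drive
                    du = np.zeros(C)
                    du[c] = du_new
                    theta_sum += theta
                    dtheta_sum += dtheta_c
                rate_c = theta_sum[c] / T
                # dL_s/dW[c,m] = -2 (y_c - rate_c) * d(rate_c)/dW[c,m]
                grad[c, m] += -2.0 * (labels[s, c] - rate_c) * dtheta_sum / T
    return grad / S


class TestGradients:
    def test_silent_hidden_raster_gives_zero_gradient(self, tiny_model):
        hidden = np.zeros((2, 4, 5))
        labels = one_hot(np.array([0, 1]), 3)
        g = stbp_readout_gradients(hidden, labels, tiny_model, TrainConfig())
        assert (g == 0).all()

    @pytest.mark.parametrize("T,M,C,seed", [(2, 2, 1, 0), (3, 3, 2, 1), (3, 2, 2, 2)])
    def test_matches_hand_unrolled_chain_rule(self, T, M, C, seed):
        rng = np.random.default_rng(seed)
        params = NeuronParams(gain=1.0)
        W_ho = rng.uniform(-1, 1, (C, M))
        model = LSMModel(
            W_ih=np.zeros((M, 1)), W_hh=np.zeros((M, M)), W_ho=W_ho, params=params
        )
        hidden = rng.integers(0, 2, (4, T, M)).astype(float)
        labels = one_hot(rng.integers(0, C, 4), C)
        cfg = TrainConfig(surrogate_width=1.0)
        got = stbp_readout_gradients(hidden, labels, model, cfg)
        want = unrolled_gradient_oracle(hidden, labels, model, cfg.surrogate_width)
        assert np.abs(got - want).max() <= 1e-10 * max(1.0, np.abs(want).max())

    def test_gradient_linear_in_label_residual(self, tiny_model, rng):
        # the loss is quadratic: doubling the residual (y - r) doubles the
        # gradient; realized by y -> 2y - r with the rate r held fixed
        hidden = rng.integers(0, 2, (3, 6, 5)).astype(float)
        cfg = TrainConfig()
        from lsmkit.reservoir import readout_rollout

        theta_o, _ = readout_rollout(hidden, tiny_model.W_ho, tiny_model.params)
        rates = theta_o.mean(axis=1)
        y = one_hot(np.array([0, 1, 2]), 3)
        g1 = stbp_readout_gradients(hidden, y, tiny_model, cfg)
        g2 = stbp_readout_gradients(hidden, 2 * y - rates, tiny_model, cfg)
        np.testing.assert_allclose(g2, 2 * g1, atol=1e-12)


class TestTrainReadout:
    def _toy_dataset(self, rng, S=24, T=10, N=8):
        X = rng.integers(0, 2, (S, T, N)).astype(float)
        y = rng.integers(0, 2, S)
        return X, y

    def test_zero_epochs_is_identity(self, rng):
        X, y = self._toy_dataset(rng)
        model = build_model(8, 6, 2, seed=0)
        trained, history = train_readout(X, y, model, TrainConfig(epochs=0))
        assert history.size == 0
        assert np.array_equal(trained.W_ho, model.W_ho)

    def test_reservoir_weights_bitwise_frozen(self, rng):
        X, y = self._toy_dataset(rng)
        model = build_model(8, 6, 2, params=NeuronParams(gain=5.0), seed=0)
        W_ih_before = model.W_ih.copy()
        W_hh_before = model.W_hh.copy()
        trained, _ = train_readout(X, y, model, TrainConfig(epochs=3, seed=1))
        assert np.array_equal(trained.W_ih, W_ih_before)
        assert np.array_equal(trained.W_hh, W_hh_before)
        assert np.array_equal(model.W_ih, W_ih_before)  # input model untouched
        assert not np.array_equal(trained.W_ho, model.W_ho)

    def test_training_reduces_loss_on_separable_task(self, rng):
        # two classes driving disjoint input channels hard
        S, T, N = 40, 12, 16
        X = np.zeros((S, T, N))
        y = np.repeat([0, 1], S // 2)
        X[: S // 2, :, : N // 2] = rng.integers(0, 2, (S // 2, T, N // 2))
        X[S // 2 :, :, N // 2 :] = rng.integers(0, 2, (S // 2, T, N // 2))
        model = build_model(N, 32, 2, params=NeuronParams(gain=8.0), seed=4)
        _, history = train_readout(X, y, model, TrainConfig(epochs=10, seed=2))
        assert history[-1] < history[0]

    def test_seeded_determinism(self, rng):
        X, y = self._toy_dataset(rng)
        model = build_model(8, 6, 2, params=NeuronParams(gain=5.0), seed=0)
        cfg = TrainConfig(epochs=4, seed=7)
        t1, h1 = train_readout(X, y, model, cfg)
        t2, h2 = train_readout(X, y, model, cfg)
        assert np.array_equal(t1.W_ho, t2.W_ho)
        assert np.array_equal(h1, h2)

    def test_adam_optimizer_runs(self, rng):
        X, y = self._toy_dataset(rng)
        model = build_model(8, 6, 2, params=NeuronParams(gain=5.0), seed=0)
        _, history = train_readout(
            X, y, model, TrainConfig(epochs=3, optimizer="adam", learning_rate=0.001)
        )
        assert history.shape == (3,)

    def test_empty_dataset_rejected(self):
        model = build_model(4, 3, 2, seed=0)
        with pytest.raises(ValueError):
            train_readout(np.zeros((0, 5, 4)), np.zeros(0), model, TrainConfig())

    @pytest.mark.parametrize(
        "kwargs",
        [dict(learning_rate=0.0), dict(batch_size=0), dict(optimizer="lbfgs")],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TrainConfig(**kwargs)
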