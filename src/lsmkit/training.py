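"""STBP training of the readout layer on a spike-rate loss.

Only the hidden-to-readout matrix ``W_ho`` is trained; the liquid is frozen,
so hidden spike rasters are constants of the optimization and are computed
once per dataset.  The loss over S samples and a time window of T steps is
the mean squared distance between the one-hot label and the mean readout
spike vector,

    L = (1/S) * sum_s || y_s - (1/T) * sum_t theta_{s,t} ||^2 ,

which is minimized when the correct-class readout neuron fires every step
and the others stay silent (rate coding).

Backpropagation through time unrolls the readout membrane recursion
``u[k] = u[k-1] * d * (1 - theta[k]) + gain * (W_ho @ h[k-1])`` and replaces
the derivative of the spike step function by a rectangular surrogate window
of width ``a`` centred on the threshold.  Two standard STBP conventions are
used: the reset factor ``(1 - theta)`` is treated as a constant during
differentiation, and gradients do not flow into the (frozen) liquid rollout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import stack_rasters
from .reservoir import LSMModel, hidden_rollout, readout_rollout

__all__ = [
    "TrainConfig",
    "RateLoss",
    "rate_loss",
    "surrogate_grad",
    "stbp_readout_gradients",
    "train_readout",
]


@dataclass(frozen=True)
class TrainConfig:
    """Hyper-parameters of the readout fit.

    ``surrogate_width`` is the width ``a`` (in threshold units) of the
    rectangular pseudo-derivative.  All fields are configurable; the packaged
    synthetic study uses Adam at lr 1e-3, which is robust across liquid
    sizes because it normalizes the per-parameter gradient scale (raw SGD
    steps grow with the liquid's firing activity, and rates much above ~0.01
    push readout membranes out of the surrogate window, after which
    gradients vanish and the fit stalls).
    """

    learning_rate: float = 0.005
    epochs: int = 20
    batch_size: int = 64
    surrogate_width: float = 1.0
    seed: int = 0
    optimizer: str = "sgd"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.surrogate_width <= 0:
            raise ValueError("surrogate_width must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class RateLoss:
    """Value and per-sample decomposition of the spike-rate loss."""

    value: float
    per_sample: np.ndarray


def _as_batch(readout_spikes) -> np.ndarray:
    if isinstance(readout_spikes, np.ndarray):
        arr = readout_spikes.astype(float)
        if arr.ndim != 3:
            raise ValueError(f"expected (S, T, C) spikes, got shape {arr.shape}")
        return arr
    return stack_rasters(list(readout_spikes))


def rate_loss(readout_spikes, labels: np.ndarray) -> RateLoss:
    """Mean squared error between one-hot labels and mean readout spike rates.

    ``readout_spikes`` is an (S, T, C) array or a list of T x C rasters;
    ``labels`` is an (S, C) one-hot matrix.
    """
    spikes = _as_batch(readout_spikes)
    labels = np.asarray(labels, dtype=float)
    S, T, C = spikes.shape
    if labels.shape != (S, C):
        raise ValueError(
            f"labels shape {labels.shape} does not match spikes batch ({S}, {C})"
        )
    rates = spikes.mean(axis=1)
    per_sample = ((labels - rates) ** 2).sum(axis=1)
    return RateLoss(value=float(per_sample.mean()), per_sample=per_sample)


def surrogate_grad(u: np.ndarray, u_th: float, a: float) -> np.ndarray:
    """Rectangular pseudo-derivative of the spike function.

    ``(1/a) * 1{|u - u_th| < a/2}``: a unit-area window of width ``a`` centred
    on the threshold.
    """
    if a <= 0:
        raise ValueError("surrogate width must be positive")
    u = np.asarray(u, dtype=float)
    return (np.abs(u - u_th) < a / 2).astype(float) / a


def _readout_backward(
    hidden: np.ndarray,
    theta_o: np.ndarray,
    u_o: np.ndarray,
    labels: np.ndarray,
    model: LSMModel,
    a: float,
) -> np.ndarray:
    """BPTT through the readout recursion; returns dL/dW_ho of shape (C, M)."""
    S, T, M = hidden.shape
    p = model.params
    d, g, th = p.decay, p.gain, p.u_th
    rates = theta_o.mean(axis=1)  # (S, C)
    # dL_s/dtheta[k] is the same for every k under the rate loss
    err = -(2.0 / T) * (labels - rates)  # (S, C)
    grad = np.zeros_like(model.W_ho)
    delta = np.zeros_like(err)  # dL/du[k], reset factor held constant
    for k in range(T - 1, -1, -1):
        if k < T - 1:
            delta = err * surrogate_grad(u_o[:, k], th, a) + delta * d * (
                1.0 - theta_o[:, k + 1]
            )
        # u[k] depends on W_ho directly through gain * W_ho @ h[k-1]
        if k >= 1:
            grad += g * (delta.T @ hidden[:, k - 1])
    return grad / S


def stbp_readout_gradients(
    batch_hidden: np.ndarray,
    labels: np.ndarray,
    model: LSMModel,
    config: TrainConfig,
) -> np.ndarray:
    """Gradient of the rate loss w.r.t. ``W_ho`` for a batch of hidden rasters.

    ``batch_hidden`` is (S, T, M) hidden spikes from the frozen liquid;
    ``labels`` is (S, C) one-hot.  No gradient exists for ``W_ih``/``W_hh``.
    """
    hidden = _as_batch(batch_hidden)
    labels = np.asarray(labels, dtype=float)
    theta_o, u_o = readout_rollout(
        hidden, model.W_ho, model.params, record_membrane=True
    )
    return _readout_backward(
        hidden, theta_o, u_o, labels, model, config.surrogate_width
    )


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """Integer class labels -> (S, C) one-hot matrix."""
    labels = np.asarray(labels)
    if labels.ndim == 2:
        return labels.astype(float)
    out = np.zeros((labels.size, n_classes))
    out[np.arange(labels.size), labels.astype(int)] = 1.0
    return out


def train_readout(
    inputs: np.ndarray,
    labels: np.ndarray,
    model: LSMModel,
    config: TrainConfig | None = None,
) -> tuple[LSMModel, np.ndarray]:
    """Fit the readout weights by mini-batch STBP.

    Parameters
    ----------
    inputs : (S, T, N) array or list of SpikeRaster
        Input rasters of the training set.
    labels : (S,) integer classes or (S, C) one-hot matrix.
    model : LSMModel
        Starting point; returned model differs only in ``W_ho``.
    config : TrainConfig

    Returns
    -------
    trained : LSMModel
        ``W_ih``/``W_hh`` are bitwise identical to the input model's.
    history : (epochs,) array
        Full-dataset loss evaluated after each epoch.
    """
    config = config or TrainConfig()
    inputs = _as_batch(inputs)
    if inputs.shape[0] == 0:
        raise ValueError("empty training set")
    Y = one_hot(labels, model.n_classes)
    if Y.shape != (inputs.shape[0], model.n_classes):
        raise ValueError(
            f"labels shape {Y.shape} inconsistent with {inputs.shape[0]} samples, "
            f"{model.n_classes} classes"
        )

    # the liquid is frozen: hidden rasters are computed once
    hidden, _ = hidden_rollout(inputs, model)

    trained = model.copy()
    if config.epochs == 0:
        return trained, np.empty(0)

    rng = np.random.default_rng(config.seed)
    S = hidden.shape[0]
    a = config.surrogate_width
    # Adam state (allocated for W_ho only; the reservoir has no optimizer state)
    m_t = np.zeros_like(trained.W_ho)
    v_t = np.zeros_like(trained.W_ho)
    step = 0
    history = np.empty(config.epochs)
    for epoch in range(config.epochs):
        order = rng.permutation(S)
        for start in range(0, S, config.batch_size):
            idx = order[start : start + config.batch_size]
            h_b, y_b = hidden[idx], Y[idx]
            theta_o, u_o = readout_rollout(
                h_b, trained.W_ho, trained.params, record_membrane=True
            )
            grad = _readout_backward(h_b, theta_o, u_o, y_b, trained, a)
            step += 1
            if config.optimizer == "sgd":
                trained.W_ho -= config.learning_rate * grad
            else:  # adam
                beta1, beta2, eps = 0.9, 0.999, 1e-8
                m_t = beta1 * m_t + (1 - beta1) * grad
                v_t = beta2 * v_t + (1 - beta2) * grad**2
                m_hat = m_t / (1 - beta1**step)
                v_hat = v_t / (1 - beta2**step)
                trained.W_ho -= config.learning_rate * m_hat / (np.sqrt(v_hat) + eps)
        theta_o, _ = readout_rollout(hidden, trained.W_ho, trained.params)
        history[epoch] = rate_loss(theta_o, Y).value
    return trained, history
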