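"""Frozen Elman spiking reservoir: construction and forward simulation.

The liquid is a recurrently connected layer of M LIF neurons driven by N
input channels (input fully connected, hidden all-to-all recurrent including
self-connections).  Both weight matrices are drawn i.i.d. uniform on
[-1/N, 1/N] and stay frozen forever; only the hidden-to-readout matrix is
trainable.  The readout layer has the same membrane dynamics but no lateral
connectivity and never feeds back into the liquid.

Timing convention (one-step synaptic delay, equal to the simulation
resolution): a spike emitted at step ``k-1`` contributes to the synaptic
current applied at step ``k``, and the spike emitted at step ``k`` is decided
by the membrane potential after step ``k-1``.  Consequently the input at the
first step can never elicit a first-step spike, and truncating the input
after step ``k`` leaves all spikes up to step ``k`` unchanged.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .lif import NeuronParams
from .raster import SpikeRaster

__all__ = [
    "LSMModel",
    "RolloutRecord",
    "init_weights",
    "init_readout",
    "build_model",
    "synaptic_current",
    "hidden_rollout",
    "readout_rollout",
    "run_reservoir",
    "run_reservoir_batch",
]


@dataclass
class LSMModel:
    """Frozen reservoir weights plus the trainable readout.

    ``W_ih`` is (M, N) input-to-hidden, ``W_hh`` is (M, M) hidden-to-hidden,
    ``W_ho`` is (C, M) hidden-to-readout.  ``W_ih``/``W_hh`` are never touched
    by training; ``W_ho`` is the only trainable parameter set and there are no
    bias terms anywhere.
    """

    W_ih: np.ndarray
    W_hh: np.ndarray
    W_ho: np.ndarray
    params: NeuronParams
    seed: int = 0

    def __post_init__(self) -> None:
        self.W_ih = np.asarray(self.W_ih, dtype=float)
        self.W_hh = np.asarray(self.W_hh, dtype=float)
        self.W_ho = np.asarray(self.W_ho, dtype=float)
        M, N = self.W_ih.shape
        if self.W_hh.shape != (M, M):
            raise ValueError(
                f"W_hh must be ({M}, {M}) to match W_ih, got {self.W_hh.shape}"
            )
        if self.W_ho.shape[1] != M:
            raise ValueError(
                f"W_ho must have {M} columns, got shape {self.W_ho.shape}"
            )

    @property
    def n_input(self) -> int:
        return self.W_ih.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W_ih.shape[0]

    @property
    def n_classes(self) -> int:
        return self.W_ho.shape[0]

    def copy(self) -> "LSMModel":
        return LSMModel(
            self.W_ih.copy(), self.W_hh.copy(), self.W_ho.copy(), self.params, self.seed
        )

    def save(self, path: str | Path) -> None:
        """Write the model to a single ``.npz`` archive (bit-exact round trip)."""
        np.savez(
            path,
            W_ih=self.W_ih,
            W_hh=self.W_hh,
            W_ho=self.W_ho,
            seed=np.int64(self.seed),
            params_json=np.frombuffer(
                json.dumps(self.params.to_dict()).encode(), dtype=np.uint8
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "LSMModel":
        with np.load(path) as z:
            params = NeuronParams.from_dict(
                json.loads(bytes(z["params_json"]).decode())
            )
            return cls(z["W_ih"], z["W_hh"], z["W_ho"], params, int(z["seed"]))


@dataclass
class RolloutRecord:
    """Everything a forward pass produces for one sample."""

    hidden_spikes: SpikeRaster
    readout_spikes: SpikeRaster
    readout_counts: np.ndarray
    hidden_membrane: np.ndarray | None = None
    readout_membrane: np.ndarray | None = None


def init_weights(N: int, M: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw the frozen reservoir matrices, i.i.d. uniform on [-1/N, 1/N].

    Returns ``(W_ih, W_hh)`` of shapes (M, N) and (M, M); deterministic for a
    given seed.  Self-connections in ``W_hh`` are allowed (all-to-all).
    """
    if N < 1 or M < 1:
        raise ValueError(f"N and M must be positive, got N={N}, M={M}")
    rng = np.random.default_rng(seed)
    bound = 1.0 / N
    W_ih = rng.uniform(-bound, bound, size=(M, N))
    W_hh = rng.uniform(-bound, bound, size=(M, M))
    return W_ih, W_hh


def init_readout(M: int, C: int, seed: int) -> np.ndarray:
    """Initial readout matrix, uniform on [-1/M, 1/M] by analogy with the liquid."""
    if M < 1 or C < 1:
        raise ValueError(f"M and C must be positive, got M={M}, C={C}")
    rng = np.random.default_rng(seed)
    bound = 1.0 / M
    return rng.uniform(-bound, bound, size=(C, M))


def build_model(
    n_input: int,
    n_hidden: int,
    n_classes: int,
    params: NeuronParams | None = None,
    seed: int = 0,
) -> LSMModel:
    """Construct a fresh LSM with seeded random weights."""
    params = params or NeuronParams()
    W_ih, W_hh = init_weights(n_input, n_hidden, seed)
    # distinct stream for the readout so reservoir draws do not depend on C
    W_ho = init_readout(n_hidden, n_classes, seed + 1)
    return LSMModel(W_ih, W_hh, W_ho, params, seed)


def synaptic_current(
    theta_in: np.ndarray,
    theta_hid: np.ndarray,
    W_ih: np.ndarray,
    W_hh: np.ndarray,
) -> np.ndarray:
    """Total synaptic drive ``W_ih @ theta_in + W_hh @ theta_hid``.

    ``theta_in``/``theta_hid`` are the spike vectors of the previous step
    (one-step synaptic delay); batched inputs of shape (S, N)/(S, M) give a
    batched (S, M) current.
    """
    theta_in = np.asarray(theta_in, dtype=float)
    theta_hid = np.asarray(theta_hid, dtype=float)
    if theta_in.shape[-1] != W_ih.shape[1]:
        raise ValueError(
            f"input spikes have {theta_in.shape[-1]} channels, W_ih expects {W_ih.shape[1]}"
        )
    if theta_hid.shape[-1] != W_hh.shape[1]:
        raise ValueError(
            f"hidden spikes have {theta_hid.shape[-1]} channels, W_hh expects {W_hh.shape[1]}"
        )
    return theta_in @ W_ih.T + theta_hid @ W_hh.T


def hidden_rollout(
    inputs: np.ndarray,
    model: LSMModel,
    record_membrane: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Simulate the liquid on a batch of input rasters.

    Parameters
    ----------
    inputs : (S, T, N) array
        Binary input spikes per sample, step and channel.
    model : LSMModel
    record_membrane : bool
        Also return the (S, T, M) membrane trace.

    Returns
    -------
    hidden_spikes : (S, T, M) float array of {0, 1}
    hidden_membrane : (S, T, M) array or None
    """
    inputs = np.asarray(inputs, dtype=float)
    if inputs.ndim != 3:
        raise ValueError(f"inputs must be (S, T, N), got shape {inputs.shape}")
    S, T, N = inputs.shape
    if N != model.n_input:
        raise ValueError(f"input has {N} channels, model expects {model.n_input}")
    p = model.params
    d, g, th = p.decay, p.gain, p.u_th
    u_rest, u_reset = p.u_rest, p.u_reset

    u = np.full((S, model.n_hidden), u_rest, dtype=float)
    s_prev = np.zeros((S, model.n_hidden))  # hidden spikes at step k-1
    x_prev = np.zeros((S, N))  # input spikes at step k-1
    spikes = np.empty((S, T, model.n_hidden))
    membrane = np.empty((S, T, model.n_hidden)) if record_membrane else None

    for k in range(T):
        theta = (u >= th).astype(float)
        I = x_prev @ model.W_ih.T + s_prev @ model.W_hh.T
        u = u_rest + np.where(theta != 0.0, u_reset - u_rest, (u - u_rest) * d) + g * I
        spikes[:, k] = theta
        if record_membrane:
            membrane[:, k] = u
        s_prev = theta
        x_prev = inputs[:, k]
    return spikes, membrane


def readout_rollout(
    hidden_spikes: np.ndarray,
    W_ho: np.ndarray,
    params: NeuronParams,
    record_membrane: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Simulate the readout layer on (batched) hidden spike rasters.

    Readout neurons share the hidden dynamics but have no lateral
    connections; hidden spikes at step ``k-1`` drive the readout at step
    ``k``.  Returns ``(readout_spikes, membrane)`` with shapes (S, T, C).
    """
    h = np.asarray(hidden_spikes, dtype=float)
    if h.ndim != 3:
        raise ValueError(f"hidden spikes must be (S, T, M), got {h.shape}")
    S, T, M = h.shape
    if W_ho.shape[1] != M:
        raise ValueError(f"W_ho expects {W_ho.shape[1]} hidden channels, got {M}")
    C = W_ho.shape[0]
    d, g, th = params.decay, params.gain, params.u_th
    u_rest, u_reset = params.u_rest, params.u_reset

    u = np.full((S, C), u_rest, dtype=float)
    spikes = np.empty((S, T, C))
    membrane = np.empty((S, T, C)) if record_membrane else None
    for k in range(T):
        theta = (u >= th).astype(float)
        drive = h[:, k - 1] @ W_ho.T if k >= 1 else np.zeros((S, C))
        u = u_rest + np.where(theta != 0.0, u_reset - u_rest, (u - u_rest) * d) + g * drive
        spikes[:, k] = theta
        if record_membrane:
            membrane[:, k] = u
    return spikes, membrane


def run_reservoir_batch(
    inputs: np.ndarray,
    model: LSMModel,
    record_membrane: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray | None, np.ndarray | None]:
    """Full liquid + readout rollout on an (S, T, N) batch.

    Returns ``(hidden_spikes, readout_spikes, readout_counts, hidden_membrane,
    readout_membrane)``; counts are per-sample column sums of the readout
    raster.
    """
    h, hm = hidden_rollout(inputs, model, record_membrane)
    o, om = readout_rollout(h, model.W_ho, model.params, record_membrane)
    counts = o.sum(axis=1)
    return h, o, counts, hm, om


def run_reservoir(
    input_raster: SpikeRaster,
    model: LSMModel,
    record_membrane: bool = False,
) -> RolloutRecord:
    """Simulate one input raster through liquid and readout.

    A pure function of ``(input_raster, model)``: repeated calls return
    identical records.
    """
    inputs = input_raster.data[None].astype(float)
    h, o, counts, hm, om = run_reservoir_batch(inputs, model, record_membrane)
    dt = input_raster.dt
    return RolloutRecord(
        hidden_spikes=SpikeRaster(h[0], dt),
        readout_spikes=SpikeRaster(o[0], dt),
        readout_counts=counts[0].astype(np.int64),
        hidden_membrane=hm[0] if hm is not None else None,
        readout_membrane=om[0] if om is not None else None,
    )
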