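"""Discrete-time leaky integrate-and-fire (LIF) neuron primitives.

The membrane potential of a current-based LIF neuron decays exponentially
toward its resting value with time constant ``tau_m`` and is perturbed by the
synaptic input current.  On a fixed simulation grid of step ``dt`` the update
is the factored form

    u[k] = u[k-1] * d * (1 - theta[k]) + gain * I[k],      d = exp(-dt/tau_m)

where ``theta[k] = 1`` iff ``u[k-1] >= u_th``.  The ``(1 - theta)`` factor
embeds the reset: the decayed carry-over is zeroed on the step at which the
neuron fires, and integration restarts from the reset potential.  With
``u_rest = u_reset = 0`` (the defaults) this is exactly the classic piecewise
"reset-then-integrate" update.

``gain`` is the potential produced per unit synaptic current per step,
i.e. ``dt / c_m`` for a membrane capacitance ``c_m``; in normalized units it
defaults to 1 and any physical scale is absorbed into the synaptic weights.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

__all__ = [
    "NeuronParams",
    "MembraneState",
    "decay_factor",
    "tau_from_decay",
    "spike_indicator",
    "membrane_step",
    "free_decay_trace",
]


@dataclass(frozen=True)
class NeuronParams:
    """LIF constants shared by hidden and readout neurons.

    Parameters
    ----------
    u_rest : float
        Resting potential (mV).  The fixed point of the free decay.
    u_reset : float
        Post-spike reset potential (mV).
    u_th : float
        Firing threshold (mV); the comparison is inclusive (``u >= u_th``).
    tau_m : float
        Membrane time constant (ms).  The default 9.4912 ms together with
        ``dt = 1`` ms gives a per-step decay of 0.9.
    dt : float
        Simulation resolution (ms).
    gain : float
        Potential increment per unit input current per step (``dt / c_m``);
        1.0 in normalized units.
    """

    u_rest: float = 0.0
    u_reset: float = 0.0
    u_th: float = 0.3
    tau_m: float = 9.4912
    dt: float = 1.0
    gain: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0:
            raise ValueError(f"tau_m must be positive, got {self.tau_m}")
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.u_th <= self.u_rest:
            raise ValueError(
                f"u_th ({self.u_th}) must exceed u_rest ({self.u_rest})"
            )

    @property
    def decay(self) -> float:
        """Per-step membrane decay ``d = exp(-dt/tau_m)``, strictly in (0, 1)."""
        return decay_factor(self.tau_m, self.dt)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronParams":
        return cls(**d)


@dataclass
class MembraneState:
    """Snapshot of a neuron population: potentials and current spike flags."""

    u: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if not np.isin(self.theta, (0.0, 1.0)).all():
            raise ValueError("spike indicators must be binary")


def decay_factor(tau_m: float, dt: float) -> float:
    """Per-step decay ``exp(-dt/tau_m)`` for time constant ``tau_m`` and step ``dt`` (ms)."""
    if tau_m <= 0:
        raise ValueError(f"tau_m must be positive, got {tau_m}")
    if dt < 0:
        raise ValueError(f"dt must be nonnegative, got {dt}")
    return math.exp(-dt / tau_m)


def tau_from_decay(d: float, dt: float) -> float:
    """Membrane time constant ``-dt / ln(d)`` recovering a given per-step decay.

    Inverse of :func:`decay_factor`; e.g. a decay of 0.9 at ``dt = 1`` ms
    corresponds to ``tau_m = 9.4912`` ms.
    """
    if not 0.0 < d < 1.0:
        raise ValueError(f"decay must lie strictly in (0, 1), got {d}")
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    return -dt / math.log(d)


def spike_indicator(u_prev: np.ndarray, u_th: float) -> np.ndarray:
    """Binary spike flags: 1 where the previous-step potential reached threshold.

    The comparison is inclusive (``u_prev >= u_th``).
    """
    return (np.asarray(u_prev, dtype=float) >= u_th).astype(float)


def membrane_step(
    u_prev: np.ndarray,
    I: np.ndarray,
    theta: np.ndarray,
    params: NeuronParams,
) -> np.ndarray:
    """One membrane update with the reset embedded in the decay term.

    ``u = u_rest + [theta ? (u_reset - u_rest) : (u_prev - u_rest) * d] + gain * I``

    which for ``u_rest = u_reset = 0`` reduces bitwise to the factored form
    ``u_prev * d * (1 - theta) + gain * I``.  ``theta`` must be the spike
    indicator computed from ``u_prev``.
    """
    u_prev = np.asarray(u_prev, dtype=float)
    I = np.asarray(I, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if not (u_prev.shape == I.shape == theta.shape):
        raise ValueError(
            f"shape mismatch: u_prev {u_prev.shape}, I {I.shape}, theta {theta.shape}"
        )
    d = params.decay
    carried = np.where(
        theta != 0.0, params.u_reset - params.u_rest, (u_prev - params.u_rest) * d
    )
    return params.u_rest + carried + params.gain * I


def free_decay_trace(u0: float, n_steps: int, params: NeuronParams) -> np.ndarray:
    """Sub-threshold free decay ``u0 * d**k`` for ``k = 0..n_steps``.

    Computed by sequential multiplication so the trace is bit-identical to an
    iterated :func:`membrane_step` with zero input (same floating-point
    evaluation order).  Assumes no spike occurs, i.e. ``u0 < u_th``.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be nonnegative")
    d = params.decay
    rest = params.u_rest
    trace = np.empty(n_steps + 1, dtype=float)
    u = float(u0)
    trace[0] = u
    for k in range(1, n_steps + 1):
        u = rest + (u - rest) * d
        trace[k] = u
    return trace
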