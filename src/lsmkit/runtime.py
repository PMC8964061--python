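"""Inference engines and the spike-count classification rule.

Batch mode resets all membrane state between samples (the training-time
convention of independent samples).  Streaming mode emulates sequential
real-time inference: state persists across samples, each sample is presented
for a stimulus window followed by a relaxation window, and a rhythmic
inhibitory pulse — modeling a single inhibitory neuron with one-to-all
connectivity to the liquid, firing once per period — quenches reverberating
reservoir activity between samples.  Classification counts readout spikes
only inside each sample's stimulus window; the predicted class is the
readout neuron with the highest count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import stack_rasters
from .reservoir import LSMModel, run_reservoir_batch

__all__ = [
    "StreamingSchedule",
    "Prediction",
    "StreamingRecord",
    "classify_counts",
    "infer_batch",
    "infer_streaming",
]


@dataclass(frozen=True)
class StreamingSchedule:
    """Timing of sequential inference.

    Each sample occupies one period of ``stim_ms + relax_ms``; at step
    ``inh_step`` of the period (default: the first step after the stimulus
    ends) a current of ``inh_weight`` (nonpositive) is injected into every
    hidden neuron simultaneously — the scheduled equivalent of the rhythmic
    inhibitory neuron's spike.  The pulse targets the liquid only; readout
    membranes decay naturally.
    """

    stim_ms: float = 25.0
    relax_ms: float = 25.0
    inh_weight: float = -10.0
    inh_step: int | None = None

    def __post_init__(self) -> None:
        if self.stim_ms <= 0:
            raise ValueError("stim_ms must be positive")
        if self.relax_ms < 0:
            raise ValueError("relax_ms must be nonnegative")
        if self.inh_weight > 0:
            raise ValueError("inh_weight must be nonpositive (inhibitory)")

    def steps(self, dt: float) -> tuple[int, int, int]:
        """(stimulus steps, period steps, inhibition step) on a grid of ``dt`` ms."""
        stim = int(round(self.stim_ms / dt))
        period = stim + int(round(self.relax_ms / dt))
        inh = self.inh_step if self.inh_step is not None else stim
        return stim, period, inh


@dataclass
class Prediction:
    """Spike-count classification outcome for one sample."""

    counts: np.ndarray
    label: int
    tie: bool = False
    silent: bool = False


@dataclass
class StreamingRecord:
    """Diagnostics of a streaming run (per sample)."""

    predictions: list[Prediction]
    stim_hidden_counts: np.ndarray  # total hidden spikes inside each stimulus window
    relax_hidden_counts: np.ndarray  # total hidden spikes inside each relaxation window


def classify_counts(counts: np.ndarray) -> Prediction:
    """Argmax over readout spike counts, ties broken toward the lowest index.

    Flags ``tie`` when the maximum is attained more than once and ``silent``
    when every count is zero (in which case class 0 is reported and flagged).
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        raise ValueError("empty count vector")
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    label = int(np.argmax(counts))  # np.argmax returns the first maximum
    mx = counts[label]
    return Prediction(
        counts=counts.copy(),
        label=label,
        tie=int((counts == mx).sum()) > 1,
        silent=bool((counts == 0).all()),
    )


def infer_batch(samples, model: LSMModel) -> list[Prediction]:
    """Classify each sample independently, state zeroed before each one.

    ``samples`` is a list of T x N :class:`SpikeRaster` (or an (S, T, N)
    array); counts are taken over the full raster duration.
    """
    if isinstance(samples, np.ndarray):
        batch = samples.astype(float)
    else:
        batch = stack_rasters(list(samples))
    _, _, counts, _, _ = run_reservoir_batch(batch, model)
    return [classify_counts(c) for c in counts]


def infer_streaming(
    samples,
    model: LSMModel,
    schedule: StreamingSchedule | None = None,
    return_record: bool = False,
):
    """Sequential inference with persistent state and rhythmic inhibition.

    Each sample raster must span exactly ``stim_ms/dt`` steps; it is followed
    by ``relax_ms`` of zero input during which the inhibitory pulse fires.
    Membrane state carries over from one sample to the next (total simulated
    time is ``n_samples * (stim_ms + relax_ms)``).  Returns a list of
    :class:`Prediction`; with ``return_record=True`` returns a
    :class:`StreamingRecord` with per-window hidden spike counts as well.
    """
    schedule = schedule or StreamingSchedule()
    if isinstance(samples, np.ndarray):
        batch = samples.astype(float)
    else:
        batch = stack_rasters(list(samples))
    S, T, N = batch.shape
    if N != model.n_input:
        raise ValueError(f"samples have {N} channels, model expects {model.n_input}")
    p = model.params
    stim_steps, period_steps, inh_step = schedule.steps(p.dt)
    if T != stim_steps:
        raise ValueError(
            f"sample rasters span {T} steps but the stimulus window is "
            f"{stim_steps} steps ({schedule.stim_ms} ms at dt={p.dt})"
        )
    d, g, th = p.decay, p.gain, p.u_th
    u_rest, u_reset = p.u_rest, p.u_reset
    M, C = model.n_hidden, model.n_classes

    # state kept as (1, ·) rows so the matmul shapes (and hence the
    # floating-point summation order) match the batch engine exactly
    u_h = np.full((1, M), u_rest)
    u_o = np.full((1, C), u_rest)
    s_h_prev = np.zeros((1, M))
    x_prev = np.zeros((1, N))

    predictions: list[Prediction] = []
    stim_hidden = np.zeros(S)
    relax_hidden = np.zeros(S)
    for s in range(S):
        counts = np.zeros(C)
        for k in range(period_steps):
            x = batch[s, k : k + 1] if k < stim_steps else np.zeros((1, N))
            theta_h = (u_h >= th).astype(float)
            theta_o = (u_o >= th).astype(float)
            I_h = x_prev @ model.W_ih.T + s_h_prev @ model.W_hh.T
            if k == inh_step:
                I_h = I_h + schedule.inh_weight
            I_o = s_h_prev @ model.W_ho.T
            u_h = u_rest + np.where(theta_h != 0.0, u_reset - u_rest, (u_h - u_rest) * d) + g * I_h
            u_o = u_rest + np.where(theta_o != 0.0, u_reset - u_rest, (u_o - u_rest) * d) + g * I_o
            if k < stim_steps:
                counts += theta_o[0]
                stim_hidden[s] += theta_h.sum()
            else:
                relax_hidden[s] += theta_h.sum()
            s_h_prev = theta_h
            x_prev = x
        predictions.append(classify_counts(counts))
    if return_record:
        return StreamingRecord(predictions, stim_hidden, relax_hidden)
    return predictions
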