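"""Spike rasters: dense binary (timestep x channel) matrices.

The raster is the lingua franca between event binning, reservoir simulation
and readout training: row ``k`` holds the spikes emitted at simulation step
``k``, one column per channel (input pixel-polarity, hidden neuron, or
readout neuron).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeRaster", "stack_rasters"]


@dataclass
class SpikeRaster:
    """A T x K binary spike matrix with a fixed time step.

    Attributes
    ----------
    data : np.ndarray
        (n_steps, n_channels) array with entries in {0, 1}.
    dt : float
        Duration of one row in milliseconds.
    """

    data: np.ndarray
    dt: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster must be 2-D, got shape {self.data.shape}")
        if self.data.shape[0] < 1:
            raise ValueError("raster needs at least one timestep")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.data.size and not np.isin(self.data, (0, 1)).all():
            raise ValueError("raster entries must be binary")
        self.data = self.data.astype(np.uint8, copy=False)

    @property
    def n_steps(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_ms(self) -> float:
        return self.n_steps * self.dt

    def counts(self) -> np.ndarray:
        """Per-channel spike counts (column sums)."""
        return self.data.sum(axis=0).astype(np.int64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeRaster):
            return NotImplemented
        return self.dt == other.dt and np.array_equal(self.data, other.data)


def stack_rasters(rasters: list[SpikeRaster]) -> np.ndarray:
    """Stack equally shaped rasters into a float (S, T, K) batch array."""
    if not rasters:
        raise ValueError("empty raster list")
    dt0, shape0 = rasters[0].dt, rasters[0].data.shape
    for r in rasters:
        if r.data.shape != shape0 or r.dt != dt0:
            raise ValueError("rasters must share shape and dt to be stacked")
    return np.stack([r.data for r in rasters]).astype(float)
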