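"""Uniform b-bit quantization of the frozen reservoir weights.

Weights are rounded onto the lattice ``step * Z`` with
``step = s * 2**(1-b)``, where ``s`` is a scale fitted to the weight
distribution (by default its maximum absolute value).  On ``[-s, s]`` this
yields at most ``2**b + 1`` distinct levels (zero is always a level) and a
worst-case error of ``step / 2``.  Because the liquid never trains, the
quantization is training-agnostic: quantizing before or after readout
training gives identical reservoir weights.  The trained readout matrix is
never quantized.

For ``b = 1`` the lattice is ``{-s, 0, s}``; a ``sign`` mode implementing a
strict two-level binarization ``s * sign(w)`` is provided as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .reservoir import LSMModel

__all__ = ["QuantScheme", "fit_scale", "quantize_weights", "quantized_model"]


@dataclass(frozen=True)
class QuantScheme:
    """A fitted uniform quantizer: bit width, scale and derived step."""

    bits: int
    scale: float

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ValueError(f"bits must be >= 1, got {self.bits}")
        if self.scale < 0:
            raise ValueError("scale must be nonnegative")

    @property
    def step(self) -> float:
        """Lattice spacing ``s * 2**(1-b)`` (0 when the scale is degenerate)."""
        return self.scale * 2.0 ** (1 - self.bits)

    @property
    def degenerate(self) -> bool:
        return self.scale == 0.0


def fit_scale(W: np.ndarray, percentile: float | None = None) -> float:
    """Normalization scale from the weight distribution.

    Default is ``max |w|``; pass ``percentile`` (e.g. 99.5) to use that
    percentile of ``|w|`` instead.  An all-zero matrix yields the degenerate
    scale 0 (quantization becomes the zero map) with a warning.
    """
    W = np.asarray(W, dtype=float)
    if W.size == 0:
        raise ValueError("cannot fit a scale to an empty matrix")
    mag = np.abs(W)
    s = float(np.max(mag) if percentile is None else np.percentile(mag, percentile))
    if s == 0.0:
        warnings.warn(
            "all-zero weight matrix: degenerate scale 0, quantization maps to zero",
            stacklevel=2,
        )
    return s


def quantize_weights(
    W: np.ndarray, b: int, s: float, mode: str = "uniform"
) -> np.ndarray:
    """Round weights onto the b-bit lattice with scale ``s``.

    ``mode='uniform'`` (default): ``w_q = step * round(w / step)`` with
    ``step = s * 2**(1-b)`` and ties-to-even rounding; values outside
    ``[-s, s]`` are lattice-rounded without clipping.  ``mode='sign'``
    (``b = 1`` only): ``w_q = s * sign(w)``.
    """
    if b < 1:
        raise ValueError(f"bits must be >= 1, got {b}")
    if s < 0:
        raise ValueError("scale must be nonnegative")
    W = np.asarray(W, dtype=float)
    if mode == "sign":
        if b != 1:
            raise ValueError("sign mode is defined for b = 1 only")
        return s * np.sign(W)
    if mode != "uniform":
        raise ValueError(f"unknown quantization mode {mode!r}")
    if s == 0.0:
        return np.zeros_like(W)
    step = s * 2.0 ** (1 - b)
    # np.round rounds half to even, giving deterministic bit-exact lattices
    return step * np.round(W / step)


def quantized_model(model: LSMModel, b: int, mode: str = "uniform") -> LSMModel:
    """Quantize the frozen matrices of a model; readout and neuron parameters untouched.

    ``W_ih`` and ``W_hh`` each get their own fitted scale (their distributions
    differ); ``W_ho`` is returned bitwise unchanged.
    """
    s_ih = fit_scale(model.W_ih)
    s_hh = fit_scale(model.W_hh)
    return LSMModel(
        W_ih=quantize_weights(model.W_ih, b, s_ih, mode),
        W_hh=quantize_weights(model.W_hh, b, s_hh, mode),
        W_ho=model.W_ho.copy(),
        params=model.params,
        seed=model.seed,
    )


def quantization_report(model: LSMModel, b: int, mode: str = "uniform") -> str:
    """Human-readable per-matrix summary: scale, step, levels, max error."""
    lines = [f"uniform {b}-bit quantization (mode={mode})"]
    for name, W in (("W_ih", model.W_ih), ("W_hh", model.W_hh)):
        s = fit_scale(W)
        Wq = quantize_weights(W, b, s, mode)
        scheme = QuantScheme(b, s)
        lines.append(
            f"  {name}: scale={s:.6g} step={scheme.step:.6g} "
            f"levels={np.unique(Wq).size} max_err={np.max(np.abs(W - Wq)):.6g}"
        )
    lines.append("  W_ho: not quantized")
    return "\n".join(lines)
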