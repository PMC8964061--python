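"""Config-driven end-to-end pipeline: data -> rasters -> train -> evaluate.

These are the plumbing functions shared by the CLI, the acceptance script
and the test suite.  The time mapping from event streams to rasters follows
the ``binning`` section: ``compress`` bins the whole stream duration into
``frames`` bins (every event is used, one frame per simulation step);
``truncate`` bins only the first ``frames * dt`` ms at native resolution and
drops the rest.
"""

from __future__ import annotations

import numpy as np

from .config import ExperimentConfig
from .events import EventStream, bin_to_raster, synth_generate
from .reservoir import LSMModel, build_model
from .runtime import infer_batch, infer_streaming
from .training import train_readout

__all__ = [
    "rasterize_streams",
    "make_synthetic_rasters",
    "train_pipeline",
    "evaluate",
    "accuracy",
]


def rasterize_streams(
    samples: list[tuple[EventStream, int]],
    frames: int,
    time_mode: str = "compress",
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bin labeled event streams into an (S, T, 2HW) batch plus label vector."""
    rasters, labels = [], []
    for stream, label in samples:
        if time_mode == "compress":
            window = max(stream.duration_us / 1000.0, dt)
        elif time_mode == "truncate":
            window = frames * dt
        else:
            raise ValueError(f"unknown time_mode {time_mode!r}")
        raster, _ = bin_to_raster(stream, frames, window, dt=dt)
        rasters.append(raster.data)
        labels.append(label)
    return np.stack(rasters).astype(float), np.asarray(labels, dtype=np.int64)


def make_synthetic_rasters(
    cfg: ExperimentConfig, seed_offset: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Generate the train and test splits of the synthetic study as rasters.

    The test split uses an independent seed stream (``synth.seed + 1 +
    seed_offset``) so train and test realizations never overlap.
    Returns ``(train_X, train_y, test_X, test_y)``.
    """
    from dataclasses import replace

    train_cfg = replace(cfg.synth, seed=cfg.synth.seed + seed_offset)
    test_cfg = replace(
        cfg.synth,
        samples_per_class=cfg.test_per_class,
        seed=cfg.synth.seed + 1 + seed_offset,
    )
    train = synth_generate(train_cfg)
    test = synth_generate(test_cfg)
    Xtr, ytr = rasterize_streams(train, cfg.frames, cfg.time_mode, cfg.neuron.dt)
    Xte, yte = rasterize_streams(test, cfg.frames, cfg.time_mode, cfg.neuron.dt)
    return Xtr, ytr, Xte, yte


def train_pipeline(
    cfg: ExperimentConfig,
    train_X: np.ndarray,
    train_y: np.ndarray,
    hidden_size: int | None = None,
) -> tuple[LSMModel, np.ndarray]:
    """Build a model per the config and fit its readout; returns (model, loss history)."""
    M = hidden_size or cfg.hidden_size
    n_input = train_X.shape[2]
    n_classes = int(train_y.max()) + 1 if train_y.ndim == 1 else train_y.shape[1]
    model = build_model(n_input, M, n_classes, cfg.neuron, seed=cfg.weight_seed)
    return train_readout(train_X, train_y, model, cfg.train)


def evaluate(
    model: LSMModel,
    X: np.ndarray,
    y: np.ndarray,
    mode: str = "batch",
    schedule=None,
) -> tuple[float, list]:
    """Accuracy and per-sample predictions under batch or streaming inference."""
    if mode == "batch":
        preds = infer_batch(X, model)
    elif mode == "streaming":
        preds = infer_streaming(X, model, schedule)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return accuracy(preds, y), preds


def accuracy(preds: list, y: np.ndarray) -> float:
    """Fraction of predictions whose label matches ``y``."""
    y = np.asarray(y)
    hits = sum(int(p.label == int(t)) for p, t in zip(preds, y, strict=True))
    return hits / len(y)
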