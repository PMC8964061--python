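"""Address-event-representation I/O, frame binning, and synthetic event data.

The on-disk dialect is the 5-byte N-MNIST record:

    byte 0: x address            byte 1: y address
    byte 2: bit 7 = polarity, bits 6..0 = timestamp bits 22..16
    byte 3: timestamp bits 15..8 byte 4: timestamp bits 7..0

Timestamps are microseconds and must fit in 23 bits (~8.4 s).  Polarity 1
is an ON (brightness increase) event, 0 is OFF.

Binning maps a stream onto a T x (2*H*W) spike raster: time bin ``k`` covers
the half-open interval ``[k*window/T, (k+1)*window/T)`` and the flattened
channel index is ``p*H*W + y*W + x`` (polarity-major, row-major).  A bin
entry is 1 iff at least one event fell into it; a count-preserving mode
exists for diagnostics.

The synthetic generator is a DVS-like stand-in for saccade recordings: each
class is a bar (or dot, for diagonal trajectories) sweeping a small pixel
grid along a class-specific direction.  Pixels entering the stimulus emit a
Poisson burst of ON events, pixels it leaves emit OFF events, timestamps are
jittered, and uniform background noise is added on both polarities.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .raster import SpikeRaster

__all__ = [
    "Event",
    "EventStream",
    "SyntheticConfig",
    "read_aer",
    "write_aer",
    "bin_to_raster",
    "synth_generate",
    "write_dataset",
    "read_dataset",
]

MAX_TIMESTAMP = (1 << 23) - 1  # 23-bit µs timestamps in the 5-byte dialect


@dataclass(frozen=True)
class Event:
    """A single DVS event: pixel address, timestamp (µs) and polarity."""

    x: int
    y: int
    t: int
    p: int


@dataclass
class EventStream:
    """A time-ordered event stream on a fixed pixel grid.

    ``x``, ``y``, ``t``, ``p`` are parallel int64 arrays; ``t`` is in
    microseconds and nondecreasing; ``p`` is 0 (OFF) or 1 (ON).
    """

    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    p: np.ndarray
    width: int = 34
    height: int = 34
    duration_us: int | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.int64)
        self.y = np.asarray(self.y, dtype=np.int64)
        self.t = np.asarray(self.t, dtype=np.int64)
        self.p = np.asarray(self.p, dtype=np.int64)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.p) == n):
            raise ValueError("event field arrays must have equal length")
        if n:
            if (self.x < 0).any() or (self.x >= self.width).any():
                raise ValueError("x coordinates out of bounds")
            if (self.y < 0).any() or (self.y >= self.height).any():
                raise ValueError("y coordinates out of bounds")
            if (self.t < 0).any():
                raise ValueError("timestamps must be nonnegative")
            if (np.diff(self.t) < 0).any():
                raise ValueError("timestamps must be nondecreasing")
            if not np.isin(self.p, (0, 1)).all():
                raise ValueError("polarity must be 0 or 1")
        if self.duration_us is None:
            self.duration_us = int(self.t[-1]) + 1 if n else 0

    def __len__(self) -> int:
        return len(self.t)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventStream):
            return NotImplemented
        return (
            (self.width, self.height) == (other.width, other.height)
            and np.array_equal(self.x, other.x)
            and np.array_equal(self.y, other.y)
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.p, other.p)
        )


def read_aer(data: bytes, width: int = 34, height: int = 34) -> EventStream:
    """Decode a 5-byte-per-event AER byte string into an :class:`EventStream`."""
    if len(data) % 5 != 0:
        raise ValueError(
            f"truncated AER record: {len(data)} bytes is not a multiple of 5 "
            f"(partial record starts at byte offset {len(data) - len(data) % 5})"
        )
    raw = np.frombuffer(data, dtype=np.uint8).reshape(-1, 5).astype(np.int64)
    x = raw[:, 0]
    y = raw[:, 1]
    p = raw[:, 2] >> 7
    t = ((raw[:, 2] & 0x7F) << 16) | (raw[:, 3] << 8) | raw[:, 4]
    return EventStream(x, y, t, p, width=width, height=height)


def write_aer(stream: EventStream) -> bytes:
    """Encode an :class:`EventStream` to the 5-byte dialect (inverse of :func:`read_aer`)."""
    if len(stream) and (stream.t > MAX_TIMESTAMP).any():
        raise ValueError(f"timestamps exceed the 23-bit limit ({MAX_TIMESTAMP} µs)")
    raw = np.empty((len(stream), 5), dtype=np.uint8)
    raw[:, 0] = stream.x
    raw[:, 1] = stream.y
    raw[:, 2] = (stream.p << 7) | ((stream.t >> 16) & 0x7F)
    raw[:, 3] = (stream.t >> 8) & 0xFF
    raw[:, 4] = stream.t & 0xFF
    return raw.tobytes()


def bin_to_raster(
    stream: EventStream,
    T: int,
    window_ms: float,
    dt: float = 1.0,
) -> tuple[SpikeRaster, int]:
    """Bin an event stream into a binarized T x (2*H*W) spike raster.

    Bin ``k`` covers ``[k * window/T, (k+1) * window/T)`` (half-open);
    channel index is ``p*H*W + y*W + x``.  An entry is 1 iff at least one
    event fell into the cell (one spike per timestep per channel); the
    count-preserving diagnostic variant is :func:`bin_event_counts`.

    Returns
    -------
    raster : SpikeRaster
        The binarized raster, with ``raster.dt = dt``.
    dropped : int
        Number of events at or beyond the window.
    """
    counts, dropped = bin_event_counts(stream, T, window_ms)
    return SpikeRaster((counts > 0).astype(np.uint8), dt), dropped


def bin_event_counts(
    stream: EventStream, T: int, window_ms: float
) -> tuple[np.ndarray, int]:
    """Count-preserving binning: (T, 2*H*W) int array of events per cell, plus drops."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if window_ms <= 0:
        raise ValueError("window must be positive")
    H, W = stream.height, stream.width
    counts = np.zeros((T, 2 * H * W), dtype=np.int64)
    window_us = window_ms * 1000.0
    if len(stream) == 0:
        return counts, 0
    bins = np.floor(stream.t / (window_us / T)).astype(np.int64)
    keep = bins < T
    dropped = int((~keep).sum())
    ch = stream.p[keep] * H * W + stream.y[keep] * W + stream.x[keep]
    np.add.at(counts, (bins[keep], ch), 1)
    return counts, dropped


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic labeled event data.

    Rates are per millisecond; ``base_rate`` is the expected number of events
    a pixel emits when the stimulus edge enters (ON) or leaves (OFF) it,
    ``noise_rate`` the background rate per pixel per polarity.  ``jitter_ms``
    is the s.d. of Gaussian timestamp jitter.  Class ``c`` uses trajectory
    ``c mod 8``: bars sweeping E, W, S, N, then dots along the four diagonals.
    """

    n_classes: int = 4
    grid: tuple[int, int] = (16, 16)  # (height, width)
    duration_ms: int = 300
    base_rate: float = 2.0
    noise_rate: float = 0.001
    jitter_ms: float = 1.0
    samples_per_class: int = 100
    seed: int = 0
    bar_width: int = 2

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.base_rate < 0 or self.noise_rate < 0:
            raise ValueError("rates must be nonnegative")
        if self.duration_ms < 1:
            raise ValueError("duration must be >= 1 ms")

    @property
    def n_channels(self) -> int:
        H, W = self.grid
        return 2 * H * W

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid"] = list(self.grid)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticConfig":
        d = dict(d)
        d["grid"] = tuple(d["grid"])
        return cls(**d)


def _coverage_mask(cls_idx: int, frac: float, H: int, W: int, bar_w: int) -> np.ndarray:
    """Boolean (H, W) mask of pixels covered by the class stimulus at progress ``frac``."""
    traj = cls_idx % 8
    mask = np.zeros((H, W), dtype=bool)
    if traj < 4:  # sweeping bar: E, W, S, N
        if traj in (0, 1):  # vertical bar moving along x
            span = W + bar_w
            lead = frac * span - bar_w
            a, b = int(np.ceil(lead)), int(np.ceil(lead)) + bar_w
            if traj == 1:
                a, b = W - b, W - a
            a, b = max(a, 0), min(b, W)
            if a < b:
                mask[:, a:b] = True
        else:  # horizontal bar moving along y
            span = H + bar_w
            lead = frac * span - bar_w
            a, b = int(np.ceil(lead)), int(np.ceil(lead)) + bar_w
            if traj == 3:
                a, b = H - b, H - a
            a, b = max(a, 0), min(b, H)
            if a < b:
                mask[a:b, :] = True
    else:  # dot of radius bar_w on a diagonal: SE, NW, NE, SW
        cx = frac * (W - 1)
        cy = frac * (H - 1)
        if traj == 5:
            cx, cy = W - 1 - cx, H - 1 - cy
        elif traj == 6:
            cy = H - 1 - cy
        elif traj == 7:
            cx = W - 1 - cx
        yy, xx = np.mgrid[0:H, 0:W]
        mask = (xx - cx) ** 2 + (yy - cy) ** 2 <= bar_w**2
    return mask


def _one_stream(
    cls_idx: int, config: SyntheticConfig, rng: np.random.Generator
) -> EventStream:
    H, W = config.grid
    D = config.duration_ms
    xs, ys, ts, ps = [], [], [], []

    prev = np.zeros((H, W), dtype=bool)
    for m in range(D + 1):
        mask = _coverage_mask(cls_idx, m / D, H, W, config.bar_width)
        for pol, trans in ((1, mask & ~prev), (0, prev & ~mask)):
            ty, tx = np.nonzero(trans)
            if ty.size == 0:
                continue
            n_ev = rng.poisson(config.base_rate, size=ty.size)
            rep = np.repeat(np.arange(ty.size), n_ev)
            if rep.size == 0:
                continue
            t0 = m * 1000.0 + rng.normal(0.0, config.jitter_ms * 1000.0, rep.size)
            xs.append(tx[rep])
            ys.append(ty[rep])
            ts.append(t0)
            ps.append(np.full(rep.size, pol))
        prev = mask

    n_noise = rng.poisson(config.noise_rate * D * H * W * 2)
    if n_noise:
        xs.append(rng.integers(0, W, n_noise))
        ys.append(rng.integers(0, H, n_noise))
        ts.append(rng.uniform(0, D * 1000.0, n_noise))
        ps.append(rng.integers(0, 2, n_noise))

    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        t = np.clip(np.concatenate(ts), 0, D * 1000 - 1).astype(np.int64)
        p = np.concatenate(ps)
        order = np.argsort(t, kind="stable")
        x, y, t, p = x[order], y[order], t[order], p[order]
    else:
        x = y = t = p = np.empty(0, dtype=np.int64)
    return EventStream(x, y, t, p, width=W, height=H, duration_us=D * 1000)


def synth_generate(config: SyntheticConfig) -> list[tuple[EventStream, int]]:
    """Generate the labeled synthetic dataset: ``samples_per_class`` streams per class.

    Deterministic for a given config (one child RNG per sample, spawned from
    ``config.seed``).  Returns ``[(stream, label), ...]`` ordered by class
    then sample index.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_classes * config.samples_per_class)
    out: list[tuple[EventStream, int]] = []
    i = 0
    for cls_idx in range(config.n_classes):
        for _ in range(config.samples_per_class):
            rng = np.random.default_rng(children[i])
            out.append((_one_stream(cls_idx, config, rng), cls_idx))
            i += 1
    return out


def write_dataset(
    root: str | Path, samples: list[tuple[EventStream, int]]
) -> None:
    """Write labeled streams as ``<root>/<label>/<index>.bin`` AER files."""
    root = Path(root)
    counters: dict[int, int] = {}
    for stream, label in samples:
        idx = counters.get(label, 0)
        counters[label] = idx + 1
        d = root / str(label)
        d.mkdir(parents=True, exist_ok=True)
        (d / f"{idx:05d}.bin").write_bytes(write_aer(stream))


def read_dataset(
    root: str | Path, width: int = 34, height: int = 34
) -> list[tuple[EventStream, int]]:
    """Read a ``<root>/<label>/<sample>.bin`` directory back into labeled streams."""
    root = Path(root)
    out: list[tuple[EventStream, int]] = []
    for label_dir in sorted(root.iterdir(), key=lambda p: int(p.name)):
        label = int(label_dir.name)
        for f in sorted(label_dir.glob("*.bin")):
            out.append((read_aer(f.read_bytes(), width, height), label))
    return out
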