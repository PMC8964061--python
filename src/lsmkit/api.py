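"""Model/Results interface for fitting an LSM classifier.

``LSMClassifier`` holds the data and architecture, ``fit()`` trains the
readout by STBP and returns an ``LSMResults`` carrying the trained model,
the loss history and evaluation/plotting helpers — the same shape of API as
a statsmodels model: construct, fit, inspect the results object.

Example
-------
>>> clf = LSMClassifier(train_X, train_y, hidden_size=128, seed=0)
>>> res = clf.fit(epochs=10)
>>> res.predict(test_X)          # predicted class labels
>>> print(res.summary())
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .lif import NeuronParams
from .quantize import quantized_model
from .raster import stack_rasters
from .reservoir import LSMModel, build_model
from .runtime import StreamingSchedule, infer_batch, infer_streaming
from .training import TrainConfig, one_hot, rate_loss, train_readout
from .reservoir import readout_rollout, hidden_rollout

__all__ = ["LSMClassifier", "LSMResults"]


class LSMClassifier:
    """A liquid state machine classifier bound to a training set.

    Parameters
    ----------
    train_X : (S, T, N) array or list of SpikeRaster
        Binary input spike rasters.
    train_y : (S,) integer class labels.
    hidden_size : int
        Number of liquid neurons M.
    neuron : NeuronParams, optional
        LIF constants (shared by liquid and readout).
    seed : int
        Seed of the frozen random weights.
    """

    def __init__(
        self,
        train_X,
        train_y,
        hidden_size: int = 256,
        neuron: NeuronParams | None = None,
        seed: int = 0,
    ):
        self.train_X = (
            train_X.astype(float)
            if isinstance(train_X, np.ndarray)
            else stack_rasters(list(train_X))
        )
        self.train_y = np.asarray(train_y, dtype=np.int64)
        if self.train_X.shape[0] != self.train_y.shape[0]:
            raise ValueError("X and y sample counts differ")
        self.hidden_size = hidden_size
        self.neuron = neuron or NeuronParams()
        self.seed = seed
        self.n_classes = int(self.train_y.max()) + 1
        self.model = build_model(
            self.train_X.shape[2], hidden_size, self.n_classes, self.neuron, seed
        )

    def fit(self, config: TrainConfig | None = None, **kwargs) -> "LSMResults":
        """Train the readout weights; keyword args override TrainConfig fields."""
        config = config or TrainConfig()
        if kwargs:
            config = replace(config, **kwargs)
        trained, history = train_readout(self.train_X, self.train_y, self.model, config)
        return LSMResults(self, trained, history, config)


class LSMResults:
    """Fit results: the trained model plus diagnostics and evaluation helpers."""

    def __init__(
        self,
        classifier: LSMClassifier,
        model: LSMModel,
        loss_history: np.ndarray,
        config: TrainConfig,
    ):
        self.classifier = classifier
        self.model = model
        self.loss_history = loss_history
        self.config = config

    # -- inference ---------------------------------------------------------
    def predict(self, X, mode: str = "batch", schedule: StreamingSchedule | None = None):
        """Predicted class labels for a batch of rasters."""
        preds = self.predictions(X, mode, schedule)
        return np.array([p.label for p in preds], dtype=np.int64)

    def predictions(self, X, mode: str = "batch", schedule: StreamingSchedule | None = None):
        """Full :class:`Prediction` objects (counts, tie/silent flags)."""
        if mode == "batch":
            return infer_batch(X, self.model)
        if mode == "streaming":
            return infer_streaming(X, self.model, schedule)
        raise ValueError(f"unknown mode {mode!r}")

    def score(self, X, y, mode: str = "batch", schedule=None) -> float:
        """Classification accuracy on (X, y)."""
        y = np.asarray(y)
        return float((self.predict(X, mode, schedule) == y).mean())

    def quantized(self, bits: int, mode: str = "uniform") -> "LSMResults":
        """Results object whose reservoir weights are quantized to ``bits`` bits."""
        return LSMResults(
            self.classifier, quantized_model(self.model, bits, mode),
            self.loss_history, self.config,
        )

    # -- diagnostics -------------------------------------------------------
    @property
    def final_loss(self) -> float:
        return float(self.loss_history[-1]) if len(self.loss_history) else float("nan")

    def train_loss(self) -> float:
        """Rate loss of the trained readout on the training set."""
        hidden, _ = hidden_rollout(self.classifier.train_X, self.model)
        theta_o, _ = readout_rollout(hidden, self.model.W_ho, self.model.params)
        Y = one_hot(self.classifier.train_y, self.model.n_classes)
        return rate_loss(theta_o, Y).value

    def summary(self) -> str:
        """Plain-text fit summary in the spirit of a statsmodels results table."""
        m = self.model
        lines = [
            "LSM classifier fit (STBP readout training)",
            "=" * 46,
            f"{'input channels':<28}{m.n_input:>18}",
            f"{'liquid size M':<28}{m.n_hidden:>18}",
            f"{'classes C':<28}{m.n_classes:>18}",
            f"{'trainable parameters':<28}{m.W_ho.size:>18}",
            f"{'frozen parameters':<28}{m.W_ih.size + m.W_hh.size:>18}",
            f"{'membrane decay d':<28}{m.params.decay:>18.6f}",
            f"{'threshold u_th':<28}{m.params.u_th:>18.4g}",
            f"{'gain (dt/c_m)':<28}{m.params.gain:>18.4g}",
            f"{'optimizer':<28}{self.config.optimizer:>18}",
            f"{'learning rate':<28}{self.config.learning_rate:>18.4g}",
            f"{'epochs':<28}{len(self.loss_history):>18}",
            f"{'final rate loss':<28}{self.final_loss:>18.6f}",
            "=" * 46,
        ]
        return "\n".join(lines)

    # -- plotting ----------------------------------------------------------
    def plot_loss(self, ax=None):
        """Loss-history curve (one point per epoch)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.loss_history) + 1), self.loss_history, marker="o")
        ax.set_xlabel("epoch")
        ax.set_ylabel("spike-rate loss")
        ax.set_title("STBP readout training")
        return ax

    def plot_rollout(self, raster, ax=None):
        """Raster plot of liquid and readout spikes for one input sample."""
        import matplotlib.pyplot as plt

        from .reservoir import run_reservoir
        from .raster import SpikeRaster

        if isinstance(raster, np.ndarray):
            raster = SpikeRaster(raster, self.model.params.dt)
        rec = run_reservoir(raster, self.model)
        if ax is None:
            _, ax = plt.subplots()
        for name, spikes, offset, color in (
            ("liquid", rec.hidden_spikes.data, 0, "k"),
            ("readout", rec.readout_spikes.data, rec.hidden_spikes.n_channels + 2, "r"),
        ):
            t, ch = np.nonzero(spikes)
            ax.scatter(t, ch + offset, s=4, marker="|", color=color, label=name)
        ax.set_xlabel("timestep")
        ax.set_ylabel("neuron")
        ax.legend(loc="upper right")
        return ax
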