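"""The CNN–LSTM confirmation classifier.

Architecture (input: one 80-sample, 4-s magnitude window, Z-score normalized
with statistics frozen from the training pool):

    Conv1D(32, kernel 3, ReLU) → BatchNorm →
    Conv1D(64, kernel 3, ReLU) → BatchNorm → MaxPool(2) →
    LSTM(32, return sequences) → Dropout(0.2) →
    LSTM(32)                   → Dropout(0.2) →
    Dense(1, sigmoid)

The convolutional stage extracts local shape features (the free-fall dip and
impact spike); the recurrent stage models their temporal ordering; the sigmoid
head emits the fall probability. Training minimizes binary cross-entropy with
Adam (default learning rate 1e-3) for 70 epochs at batch size 32 and records
per-epoch train/validation loss and accuracy. All randomness (weight init,
shuffling, dropout) derives from the config seed, so runs are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import nn
from .errors import ConfigurationError, InvalidInputError
from .signals import NormStats, zscore_apply, zscore_fit
from .sisfall import Pattern


@dataclass(frozen=True)
class ClassifierConfig:
    conv_filters: Tuple[int, int] = (32, 64)
    kernel_size: int = 3
    pool_size: int = 2
    lstm_units: Tuple[int, int] = (32, 32)
    dropout: float = 0.20
    epochs: int = 70
    batch_size: int = 32
    learning_rate: float = 1e-3
    input_length: int = 80
    input_channels: int = 1
    decision_threshold: float = 0.5
    pool_after_each_conv: bool = False
    seed: int = 42

    def __post_init__(self):
        if any(
            v < 1
            for v in (*self.conv_filters, self.kernel_size, self.pool_size,
                      *self.lstm_units, self.epochs, self.batch_size,
                      self.input_length, self.input_channels)
        ):
            raise ConfigurationError("all architecture counts must be positive")
        if not 0 <= self.dropout < 1:
            raise ConfigurationError("dropout must lie in [0, 1)")
        if not 0 < self.decision_threshold < 1:
            raise ConfigurationError("decision_threshold must lie in (0, 1)")


def build_model(config: ClassifierConfig, rng: Optional[np.random.Generator] = None) -> nn.Sequential:
    """Construct the untrained network for a given configuration.

    Weight initialization uses the config seed, so two builds with the same
    config have identical parameters.
    """
    rng = rng or np.random.default_rng(config.seed)
    dropout_rng = np.random.default_rng(config.seed + 1)
    f1, f2 = config.conv_filters
    k = config.kernel_size
    layers: List[nn.Layer] = [
        nn.Conv1D(config.input_channels, f1, k, rng),
        nn.ReLU(),
        nn.BatchNorm(f1),
    ]
    if config.pool_after_each_conv:
        layers.append(nn.MaxPool1D(config.pool_size))
    layers += [
        nn.Conv1D(f1, f2, k, rng),
        nn.ReLU(),
        nn.BatchNorm(f2),
        nn.MaxPool1D(config.pool_size),
    ]
    u1, u2 = config.lstm_units
    layers += [
        nn.LSTM(f2, u1, rng, return_sequences=True),
        nn.Dropout(config.dropout, dropout_rng),
        nn.LSTM(u1, u2, rng, return_sequences=False),
        nn.Dropout(config.dropout, dropout_rng),
        nn.Dense(u2, 1, rng),
    ]
    return nn.Sequential(layers)


@dataclass
class TrainedModel:
    """A fitted classifier bundled with its config and normalization stats."""

    network: nn.Sequential
    config: ClassifierConfig
    norm_stats: NormStats
    history: Dict[str, List[float]] = field(default_factory=dict)

    def predict(self, window, pre_normalized: bool = False) -> float:
        """Fall probability in (0, 1) for one 80-sample magnitude window."""
        arr = np.asarray(window, dtype=float).ravel()
        if arr.size != self.config.input_length:
            raise InvalidInputError(
                f"window must have {self.config.input_length} samples, got {arr.size}"
            )
        if not pre_normalized:
            arr = zscore_apply(arr, self.norm_stats)
        x = arr.reshape(1, -1, self.config.input_channels)
        logit = self.network.forward(x, training=False)
        return float(nn.sigmoid(logit)[0, 0])

    def predict_batch(self, windows, pre_normalized: bool = False) -> np.ndarray:
        arr = np.asarray(windows, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != self.config.input_length:
            raise InvalidInputError(
                f"windows must be (n, {self.config.input_length}), got {arr.shape}"
            )
        if not pre_normalized:
            arr = zscore_apply(arr, self.norm_stats)
        x = arr[:, :, None]
        logits = self.network.forward(x, training=False)
        return nn.sigmoid(logits).ravel()

    def save(self, path: Union[str, Path]) -> None:
        """Single-archive checkpoint: config + weights + normalization stats."""
        meta = {
            "config": asdict(self.config),
            "norm_stats": {"mu": self.norm_stats.mu, "sigma": self.norm_stats.sigma},
            "history": self.history,
        }
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **self.network.get_weights(),
        )

    @classmethod
    def load(cls, path: Union[str, Path]) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            weights = {k: data[k] for k in data.files if k != "__meta__"}
        cfg = meta["config"]
        for key in ("conv_filters", "lstm_units"):
            cfg[key] = tuple(cfg[key])
        config = ClassifierConfig(**cfg)
        network = build_model(config)
        network.set_weights(weights)
        stats = NormStats(**meta["norm_stats"])
        return cls(network=network, config=config, norm_stats=stats, history=meta["history"])


def _patterns_to_arrays(patterns: Sequence[Pattern]) -> Tuple[np.ndarray, np.ndarray]:
    X = np.stack([p.values for p in patterns])
    y = np.array([p.label for p in patterns], dtype=float)
    return X, y


def train(
    train_patterns: Sequence[Pattern],
    val_patterns: Sequence[Pattern],
    config: Optional[ClassifierConfig] = None,
    norm_stats: Optional[NormStats] = None,
    verbose: bool = False,
) -> TrainedModel:
    """Fit the CNN–LSTM on raw (un-normalized) magnitude patterns.

    Z-score statistics are computed from the training pool only (unless passed
    in) and applied to every split; validation subjects therefore never leak
    into the normalization. Returns the fitted model with per-epoch history.
    """
    config = config or ClassifierConfig()
    if not train_patterns:
        raise InvalidInputError("training split is empty")
    if not val_patterns:
        raise InvalidInputError("validation split is empty")
    X_train, y_train = _patterns_to_arrays(train_patterns)
    X_val, y_val = _patterns_to_arrays(val_patterns)
    if norm_stats is None:
        norm_stats = zscore_fit(X_train)
    Xn_train = zscore_apply(X_train, norm_stats)[:, :, None]
    Xn_val = zscore_apply(X_val, norm_stats)[:, :, None]

    network = build_model(config)
    optimizer = nn.Adam(network, learning_rate=config.learning_rate)
    shuffle_rng = np.random.default_rng(config.seed + 2)
    history: Dict[str, List[float]] = {
        "loss": [], "accuracy": [], "val_loss": [], "val_accuracy": []
    }
    n = Xn_train.shape[0]
    for epoch in range(config.epochs):
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        epoch_correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = Xn_train[idx], y_train[idx]
            logits = network.forward(xb, training=True)
            epoch_loss += nn.bce_with_logits(logits, yb) * len(idx)
            probs = nn.sigmoid(logits).ravel()
            epoch_correct += int(np.sum((probs >= config.decision_threshold) == (yb == 1)))
            network.backward(nn.bce_with_logits_grad(logits, yb))
            optimizer.step()
        val_logits = network.forward(Xn_val, training=False)
        val_probs = nn.sigmoid(val_logits).ravel()
        history["loss"].append(epoch_loss / n)
        history["accuracy"].append(epoch_correct / n)
        history["val_loss"].append(nn.bce_with_logits(val_logits, y_val))
        history["val_accuracy"].append(
            float(np.mean((val_probs >= config.decision_threshold) == (y_val == 1)))
        )
        if verbose:
            print(
                f"epoch {epoch + 1:3d}/{config.epochs}  "
                f"loss {history['loss'][-1]:.4f}  acc {history['accuracy'][-1]:.4f}  "
                f"val_loss {history['val_loss'][-1]:.4f}  "
                f"val_acc {history['val_accuracy'][-1]:.4f}"
            )
    return TrainedModel(network=network, config=config, norm_stats=norm_stats, history=history)


def classify(probability: float, decision_threshold: float = 0.5) -> int:
    """Map a fall probability to a hard label: 1 (fall) iff p ≥ threshold."""
    if not 0 <= probability <= 1:
        raise InvalidInputError("probability must lie in [0, 1]")
    return int(probability >= decision_threshold)
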