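"""EEG emotion-classification backbones and their sklearn-style estimators.

Four architectures of comparable capacity over differential-entropy
inputs:

* ``cnn`` — two 3x3 convolutions (32 then 64 filters, (2,1) max-pool and
  dropout 0.2 after each) over the 62x5 channel-band grid of a single
  window, then a dense layer to 3 classes.
* ``gnn`` — one graph convolution (5 -> 8 features per electrode) over
  the montage proximity graph, ReLU, dropout 0.2, dense to 3.
* ``gnn_lstm`` — the graph layer per window, flattened 496-d window
  embeddings fed to a bidirectional LSTM (32 hidden units per
  direction), concatenated final states, dropout, dense to 3.
* ``gnn_transformer`` — the graph layer per window (SiLU, dropout,
  layer-norm), 496-d tokens plus a learnable positional embedding, one
  transformer encoder layer (4 heads, feed-forward 992, dropout 0.3),
  mean pooling over the sequence, dropout, dense to 3.

``cnn`` and ``gnn`` classify single windows; the recurrent/attention
variants classify sequences of ``W`` consecutive windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from ._autograd import Tensor
from .montage import SEED_62_CHANNELS, build_adjacency

__all__ = [
    "ModelConfig", "ARCHITECTURES", "EmotionBackboneClassifier",
    "CNNBackbone", "GNNBackbone", "GNNLSTMBackbone", "GNNTransformerBackbone",
    "train_model", "TrainingLog",
]

ARCHITECTURES = ("cnn", "gnn", "gnn_lstm", "gnn_transformer")

#: Tuned defaults per architecture: (epochs, learning rate, optimizer,
#: weight decay, dropout).
_ARCH_DEFAULTS = {
    "cnn": (30, 1e-3, "sgd", 0.0, 0.2),
    "gnn": (50, 1e-2, "sgd", 0.0, 0.2),
    "gnn_lstm": (80, 1e-3, "adamw", 0.1, 0.3),
    "gnn_transformer": (80, 1e-3, "adamw", 0.1, 0.3),
}


@dataclass
class ModelConfig:
    architecture: str = "gnn_transformer"
    epochs: int = 80
    learning_rate: float = 1e-3
    weight_decay: float = 0.1
    optimizer: str = "adamw"
    batch_size: int = 32
    dropout: float = 0.3
    sequence_length: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}; "
                             f"choose from {ARCHITECTURES}")
        if self.optimizer not in ("sgd", "adamw"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")

    @classmethod
    def for_architecture(cls, architecture: str, **overrides) -> "ModelConfig":
        if architecture not in _ARCH_DEFAULTS:
            raise ValueError(f"unknown architecture {architecture!r}")
        epochs, lr, opt, wd, drop = _ARCH_DEFAULTS[architecture]
        base = dict(architecture=architecture, epochs=epochs, learning_rate=lr,
                    optimizer=opt, weight_decay=wd, dropout=drop)
        base.update(overrides)
        return cls(**base)


class CNNBackbone(nn.Module):
    def __init__(self, rng: np.random.Generator, dropout: float = 0.2,
                 n_channels: int = 62, n_bands: int = 5, n_classes: int = 3):
        self.conv1 = nn.Conv2d(1, 32, rng)
        self.conv2 = nn.Conv2d(32, 64, rng)
        self.drop1 = nn.Dropout(dropout, rng)
        self.drop2 = nn.Dropout(dropout, rng)
        h = (n_channels - 2) // 2      # after conv1 (valid) + pool
        w = n_bands - 2
        h2 = (h - 2) // 2              # after conv2 + pool
        w2 = w - 2
        self.fc = nn.Linear(64 * h2 * max(w2, 1), n_classes, rng)
        self._flat = 64 * h2 * max(w2, 1)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, 1, 62, 5)
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"CNN expects (B, 1, channels, bands); got {x.shape}")
        h = self.drop1(nn.max_pool_h2(self.conv1(x).relu()))
        h = self.drop2(nn.max_pool_h2(self.conv2(h).relu()))
        B = h.shape[0]
        return self.fc(h.reshape(B, self._flat))


class GNNBackbone(nn.Module):
    def __init__(self, adjacency: np.ndarray, rng: np.random.Generator,
                 dropout: float = 0.2, n_classes: int = 3,
                 in_features: int = 5, graph_features: int = 8):
        self.gc = nn.GraphConv(in_features, graph_features, adjacency, rng)
        self.drop = nn.Dropout(dropout, rng)
        n_nodes = adjacency.shape[0]
        self.fc = nn.Linear(n_nodes * graph_features, n_classes, rng)
        self._flat = n_nodes * graph_features

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, 62, 5)
        if x.ndim != 3:
            raise ValueError(f"GNN expects (B, channels, bands); got {x.shape}")
        h = self.drop(self.gc(x).relu())
        return self.fc(h.reshape(x.shape[0], self._flat))


class GNNLSTMBackbone(nn.Module):
    def __init__(self, adjacency: np.ndarray, rng: np.random.Generator,
                 dropout: float = 0.3, n_classes: int = 3,
                 in_features: int = 5, graph_features: int = 8, hidden: int = 32):
        self.gc = nn.GraphConv(in_features, graph_features, adjacency, rng)
        self.drop_g = nn.Dropout(dropout, rng)
        n_nodes = adjacency.shape[0]
        self._token = n_nodes * graph_features
        self.lstm = nn.BiLSTM(self._token, hidden, rng)
        self.drop_out = nn.Dropout(dropout, rng)
        self.fc = nn.Linear(2 * hidden, n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, W, 62, 5)
        if x.ndim != 4:
            raise ValueError(f"GNN+LSTM expects (B, W, channels, bands); got {x.shape}")
        B, W = x.shape[0], x.shape[1]
        h = self.drop_g(self.gc(x).relu()).reshape(B, W, self._token)
        return self.fc(self.drop_out(self.lstm(h)))


class GNNTransformerBackbone(nn.Module):
    """Graph layer per window, transformer encoder over the window
    sequence, mean pooling; the pooled 496-d embedding is also exposed
    for the fusion head."""

    def __init__(self, adjacency: np.ndarray, rng: np.random.Generator,
                 dropout: float = 0.3, n_classes: int = 3, max_seq_len: int = 64,
                 in_features: int = 5, graph_features: int = 8, n_heads: int = 4):
        self.gc = nn.GraphConv(in_features, graph_features, adjacency, rng)
        self.drop_g = nn.Dropout(dropout, rng)
        self.norm_g = nn.LayerNorm(graph_features)
        n_nodes = adjacency.shape[0]
        d_model = n_nodes * graph_features     # 62*8 = 496
        self.d_model = d_model
        self.pos = Tensor(rng.normal(0.0, 0.02, size=(max_seq_len, d_model)),
                          requires_grad=True)
        self.encoder = nn.TransformerEncoderLayer(d_model, n_heads, 2 * d_model,
                                                  dropout, rng)
        self.drop_out = nn.Dropout(dropout, rng)
        self.fc = nn.Linear(d_model, n_classes, rng)

    def embed(self, x: Tensor) -> Tensor:
        """Pooled sequence embedding, shape (B, 496)."""
        if x.ndim != 4:
            raise ValueError(
                f"GNN+Transformer expects (B, W, channels, bands); got {x.shape}")
        B, W = x.shape[0], x.shape[1]
        if W > self.pos.shape[0]:
            raise ValueError(f"sequence length {W} exceeds positional table "
                             f"{self.pos.shape[0]}")
        h = self.norm_g(self.drop_g(self.gc(x).silu()))
        tokens = h.reshape(B, W, self.d_model) + self.pos[:W]
        encoded = self.encoder(tokens)
        return self.drop_out(encoded.mean(axis=1))

    def __call__(self, x: Tensor, return_embedding: bool = False) -> Tensor:
        pooled = self.embed(x)
        if return_embedding:
            return pooled
        return self.fc(pooled)


def build_backbone(config: ModelConfig, adjacency: np.ndarray,
                   rng: np.random.Generator) -> nn.Module:
    arch = config.architecture
    if arch == "cnn":
        return CNNBackbone(rng, dropout=config.dropout)
    if arch == "gnn":
        return GNNBackbone(adjacency, rng, dropout=config.dropout)
    if arch == "gnn_lstm":
        return GNNLSTMBackbone(adjacency, rng, dropout=config.dropout)
    return GNNTransformerBackbone(adjacency, rng, dropout=config.dropout,
                                  max_seq_len=max(config.sequence_length, 16))


@dataclass
class TrainingLog:
    epochs: list[int]
    loss: list[float]
    train_accuracy: list[float]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame({"epoch": self.epochs, "loss": self.loss,
                             "train_acc": self.train_accuracy})


def _prepare_input(arch: str, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float32)
    if arch == "cnn":
        if X.ndim == 3:
            X = X[:, None, :, :]
        if X.ndim != 4 or X.shape[1] != 1:
            raise ValueError(f"cnn input must be (n, 62, 5); got {X.shape}")
    elif arch == "gnn":
        if X.ndim != 3:
            raise ValueError(f"gnn input must be (n, 62, 5); got {X.shape}")
    else:
        if X.ndim != 4:
            raise ValueError(f"{arch} input must be (n, W, 62, 5); got {X.shape}")
    return X


def train_model(model: nn.Module, X: np.ndarray, y: np.ndarray,
                config: ModelConfig, rng: np.random.Generator,
                forward=None) -> TrainingLog:
    """Mini-batch training for a fixed number of epochs (no early
    stopping); returns the per-epoch loss / training-accuracy trace."""
    if len(X) == 0:
        raise ValueError("empty training set")
    y = np.asarray(y, dtype=int)
    params = model.parameters()
    if config.optimizer == "sgd":
        opt = nn.SGD(params, lr=config.learning_rate,
                     weight_decay=config.weight_decay)
    else:
        opt = nn.AdamW(params, lr=config.learning_rate,
                       weight_decay=config.weight_decay)
    fwd = forward if forward is not None else model
    log = TrainingLog([], [], [])
    n = len(X)
    model.train()
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        correct = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = fwd(Tensor(X[idx]))
            loss = nn.cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}")
            model.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data) * len(idx)
            correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
        log.epochs.append(epoch + 1)
        log.loss.append(epoch_loss / n)
        log.train_accuracy.append(correct / n)
    model.eval()
    return log


class EmotionBackboneClassifier(ClassifierMixin, BaseEstimator):
    """Sklearn-style wrapper around the EEG-only backbones.

    Parameters default to the per-architecture tuned values when left
    as ``None``. ``X`` is (n, 62, 5) windows for ``cnn``/``gnn`` and
    (n, W, 62, 5) window sequences otherwise; features are expected to
    be per-session z-scored differential entropies.
    """

    def __init__(self, architecture: str = "gnn_transformer", epochs: int | None = None,
                 learning_rate: float | None = None, weight_decay: float | None = None,
                 optimizer: str | None = None, batch_size: int = 32,
                 dropout: float | None = None, adjacency_threshold_mm: float = 60.0,
                 channel_names: tuple = SEED_62_CHANNELS, seed: int = 0):
        self.architecture = architecture
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.dropout = dropout
        self.adjacency_threshold_mm = adjacency_threshold_mm
        self.channel_names = channel_names
        self.seed = seed

    def _config(self, seq_len: int) -> ModelConfig:
        overrides = {k: v for k, v in dict(
            epochs=self.epochs, learning_rate=self.learning_rate,
            weight_decay=self.weight_decay, optimizer=self.optimizer,
            dropout=self.dropout).items() if v is not None}
        overrides["batch_size"] = self.batch_size
        overrides["sequence_length"] = seq_len
        overrides["seed"] = self.seed
        return ModelConfig.for_architecture(self.architecture, **overrides)

    def fit(self, X, y):
        X = _prepare_input(self.architecture, X)
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        seq_len = X.shape[1] if X.ndim == 4 and self.architecture != "cnn" else 1
        config = self._config(seq_len)
        rng = np.random.default_rng(self.seed)
        self.adjacency_ = build_adjacency(self.channel_names,
                                          self.adjacency_threshold_mm)
        self.model_ = build_backbone(config, self.adjacency_, rng)
        self.config_ = config
        self.history_ = train_model(self.model_, X, y_idx, config, rng)
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = _prepare_input(self.architecture, X)
        self.model_.eval()
        return self.model_(Tensor(X)).data.astype(float)

    def predict_proba(self, X) -> np.ndarray:
        logits = self.decision_function(X)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X) -> np.ndarray:
        return self.classes_[self.decision_function(X).argmax(axis=1)]

    def _build_info(self) -> dict:
        check_is_fitted(self, "model_")
        return {"sequence_length": self.config_.sequence_length}

    def _rebuild_for_checkpoint(self, build: dict) -> None:
        """Reconstruct the (untrained) architecture so checkpoint weights
        can be loaded into it."""
        config = self._config(int(build["sequence_length"]))
        rng = np.random.default_rng(self.seed)
        self.adjacency_ = build_adjacency(self.channel_names,
                                          self.adjacency_threshold_mm)
        self.model_ = build_backbone(config, self.adjacency_, rng)
        self.config_ = config

    def embed(self, X) -> np.ndarray:
        """Pooled embeddings (gnn_transformer only)."""
        check_is_fitted(self, "model_")
        if self.architecture != "gnn_transformer":
            raise ValueError("embeddings are defined for the gnn_transformer backbone")
        X = _prepare_input(self.architecture, X)
        self.model_.eval()
        return self.model_(Tensor(X), return_embedding=True).data.astype(float)
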