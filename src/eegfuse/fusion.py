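"""Attention-based fusion of EEG embeddings with demographic covariates.

The extended classifier projects the transformer's pooled 496-d EEG
embedding to 16 units (O1) and the standardized 4-d demographic vector
to 16 units (O2, weight matrix L without bias). A shared learnable
16-vector A gates the two modalities per dimension:

    w1_j = exp(A_j O1_j) / (exp(A_j O1_j) + exp(A_j O2_j)),  w2 = 1 - w1
    Ofusion = w1 * O1 + w2 * O2

i.e. a two-way softmax per fused dimension, computed in its numerically
stable sigmoid form. A plain concatenation head (O1 ++ O2 -> linear) is
provided as the internal baseline fusion variant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import nn
from ._autograd import Tensor, concatenate
from .models import (GNNTransformerBackbone, ModelConfig, TrainingLog,
                     _prepare_input)
from .montage import SEED_62_CHANNELS, build_adjacency

__all__ = [
    "attention_fuse", "concat_fuse", "FusionTrace",
    "ExtendedFusionModel", "FusedEmotionClassifier",
]


def attention_fuse(o1: np.ndarray, o2: np.ndarray, a: np.ndarray):
    """Per-dimension attention fusion of two equally sized embeddings.

    Returns ``(ofusion, omega1, omega2)`` with ``omega1 + omega2 == 1``
    exactly (omega2 is computed as the complement). Accepts vectors or
    batches (..., d).
    """
    o1 = np.asarray(o1, dtype=float)
    o2 = np.asarray(o2, dtype=float)
    a = np.asarray(a, dtype=float)
    for name, arr in (("O1", o1), ("O2", o2), ("A", a)):
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{name} contains non-finite values")
    # two-way softmax == sigmoid of the logit difference (stable)
    delta = a * (o1 - o2)
    omega1 = np.where(delta >= 0,
                      1.0 / (1.0 + np.exp(-delta)),
                      np.exp(delta) / (1.0 + np.exp(delta)))
    omega2 = 1.0 - omega1
    return omega1 * o1 + omega2 * o2, omega1, omega2


def concat_fuse(o1: np.ndarray, o2: np.ndarray) -> np.ndarray:
    """Concatenation baseline: stack the two embeddings (..., 2d)."""
    return np.concatenate([np.asarray(o1, dtype=float),
                           np.asarray(o2, dtype=float)], axis=-1)


@dataclass
class FusionTrace:
    """Per-sample attention weights captured on a test fold, plus the
    demographic expansion matrix of the trained model."""

    omega1: np.ndarray           # (n, 16)
    omega2: np.ndarray           # (n, 16)
    L: np.ndarray                # (demo_dim, 16) demographic projection
    subject_ids: np.ndarray      # (n,)
    true_labels: np.ndarray      # (n,) ints
    predicted_labels: np.ndarray  # (n,) ints
    demo_columns: tuple[str, ...] = ("age", "sex", "nationality_1", "nationality_2")


class ExtendedFusionModel(nn.Module):
    """GNN+Transformer EEG branch fused with a demographic branch."""

    def __init__(self, adjacency: np.ndarray, rng: np.random.Generator,
                 dropout: float = 0.3, demo_dim: int = 4, fusion_dim: int = 16,
                 n_classes: int = 3, max_seq_len: int = 64,
                 fusion_mode: str = "attention", demo_bias: bool = False):
        self.backbone = GNNTransformerBackbone(adjacency, rng, dropout=dropout,
                                               max_seq_len=max_seq_len)
        self.eeg_proj = nn.Linear(self.backbone.d_model, fusion_dim, rng)
        self.demo_proj = nn.Linear(demo_dim, fusion_dim, rng, bias=demo_bias)
        self.attention = Tensor(rng.normal(0.0, 0.5, size=(fusion_dim,)),
                                requires_grad=True)
        if fusion_mode == "attention":
            self.classifier = nn.Linear(fusion_dim, n_classes, rng)
        elif fusion_mode == "concat":
            self.classifier = nn.Linear(2 * fusion_dim, n_classes, rng)
        else:
            raise ValueError(f"unknown fusion_mode {fusion_mode!r}")
        self.fusion_mode = fusion_mode
        self.fusion_dim = fusion_dim
        self.demo_dim = demo_dim

    @property
    def L(self) -> np.ndarray:
        """Demographic expansion matrix, rows = original variables."""
        return self.demo_proj.weight.data.astype(float).copy()

    def _fuse(self, o1: Tensor, o2: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        delta = self.attention * (o1 - o2)
        omega1 = delta.sigmoid()
        omega2 = 1.0 - omega1
        return omega1 * o1 + omega2 * o2, omega1, omega2

    def forward(self, x: Tensor, demo: Tensor, force_omega1: float | None = None):
        """Logits plus the per-sample fusion weights.

        ``force_omega1`` overrides the learned gate with a constant (a
        test harness hook for fusion-degeneracy checks).
        """
        o1 = self.eeg_proj(self.backbone.embed(x))
        o2 = self.demo_proj(demo)
        if self.fusion_mode == "concat":
            fused = concatenate([o1, o2], axis=-1)
            omega1 = Tensor(np.full(o1.shape, 0.5, dtype=np.float32))
            omega2 = omega1
        elif force_omega1 is not None:
            omega1 = Tensor(np.full(o1.shape, force_omega1, dtype=np.float32))
            omega2 = Tensor(np.full(o1.shape, 1.0 - force_omega1, dtype=np.float32))
            fused = omega1 * o1 + omega2 * o2
        else:
            fused, omega1, omega2 = self._fuse(o1, o2)
        return self.classifier(fused), omega1, omega2

    def __call__(self, x: Tensor, demo: Tensor) -> Tensor:
        return self.forward(x, demo)[0]


class FusedEmotionClassifier(ClassifierMixin, BaseEstimator):
    """Extended classifier: EEG sequences plus demographic covariates.

    ``fit(X, y, demo=...)`` takes X of shape (n, W, 62, 5) and ``demo``
    of shape (n, demo_dim) — encoded, standardized demographic rows
    aligned with the samples. Training defaults follow the
    gnn_transformer recipe (AdamW, 80 epochs, lr 1e-3, wd 0.1).
    """

    def __init__(self, epochs: int = 80, learning_rate: float = 1e-3,
                 weight_decay: float = 0.1, optimizer: str = "adamw",
                 batch_size: int = 32, dropout: float = 0.3,
                 fusion_mode: str = "attention", demo_bias: bool = False,
                 adjacency_threshold_mm: float = 60.0,
                 channel_names: tuple = SEED_62_CHANNELS, seed: int = 0):
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.optimizer = optimizer
        self.batch_size = batch_size
        self.dropout = dropout
        self.fusion_mode = fusion_mode
        self.demo_bias = demo_bias
        self.adjacency_threshold_mm = adjacency_threshold_mm
        self.channel_names = channel_names
        self.seed = seed

    def fit(self, X, y, demo=None):
        if demo is None:
            raise ValueError("the extended classifier requires demo=(n, d) encoded "
                             "demographic rows")
        X = _prepare_input("gnn_transformer", X)
        demo = np.asarray(demo, dtype=np.float32)
        if demo.ndim != 2 or len(demo) != len(X):
            raise ValueError(f"demo must be (n_samples, d); got {demo.shape}")
        y = np.asarray(y)
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        config = ModelConfig.for_architecture(
            "gnn_transformer", epochs=self.epochs, learning_rate=self.learning_rate,
            weight_decay=self.weight_decay, optimizer=self.optimizer,
            dropout=self.dropout, batch_size=self.batch_size,
            sequence_length=X.shape[1], seed=self.seed)
        rng = np.random.default_rng(self.seed)
        self.adjacency_ = build_adjacency(self.channel_names,
                                          self.adjacency_threshold_mm)
        self.model_ = ExtendedFusionModel(
            self.adjacency_, rng, dropout=self.dropout, demo_dim=demo.shape[1],
            max_seq_len=max(X.shape[1], 16), fusion_mode=self.fusion_mode,
            demo_bias=self.demo_bias)
        self.history_ = self._train(X, y_idx, demo, config, rng)
        self.config_ = config
        return self

    def _train(self, X, y, demo, config: ModelConfig,
               rng: np.random.Generator) -> TrainingLog:
        params = self.model_.parameters()
        if config.optimizer == "sgd":
            opt = nn.SGD(params, lr=config.learning_rate,
                         weight_decay=config.weight_decay)
        else:
            opt = nn.AdamW(params, lr=config.learning_rate,
                           weight_decay=config.weight_decay)
        log = TrainingLog([], [], [])
        n = len(X)
        self.model_.train()
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            correct = 0
            for start in range(0, n, config.batch_size):
                idx = order[start:start + config.batch_size]
                logits = self.model_(Tensor(X[idx]), Tensor(demo[idx]))
                loss = nn.cross_entropy(logits, y[idx])
                if not np.isfinite(loss.data):
                    raise RuntimeError(f"non-finite loss at epoch {epoch}")
                self.model_.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data) * len(idx)
                correct += int((logits.data.argmax(axis=1) == y[idx]).sum())
            log.epochs.append(epoch + 1)
            log.loss.append(epoch_loss / n)
            log.train_accuracy.append(correct / n)
        self.model_.eval()
        return log

    def _build_info(self) -> dict:
        check_is_fitted(self, "model_")
        return {"demo_dim": self.model_.demo_dim,
                "max_seq_len": int(self.model_.backbone.pos.shape[0])}

    def _rebuild_for_checkpoint(self, build: dict) -> None:
        rng = np.random.default_rng(self.seed)
        self.adjacency_ = build_adjacency(self.channel_names,
                                          self.adjacency_threshold_mm)
        self.model_ = ExtendedFusionModel(
            self.adjacency_, rng, dropout=self.dropout,
            demo_dim=int(build["demo_dim"]),
            max_seq_len=int(build["max_seq_len"]),
            fusion_mode=self.fusion_mode, demo_bias=self.demo_bias)
        self.model_.eval()

    def _forward_eval(self, X, demo):
        check_is_fitted(self, "model_")
        X = _prepare_input("gnn_transformer", X)
        demo = np.asarray(demo, dtype=np.float32)
        self.model_.eval()
        return self.model_.forward(Tensor(X), Tensor(demo))

    def decision_function(self, X, demo) -> np.ndarray:
        return self._forward_eval(X, demo)[0].data.astype(float)

    def predict_proba(self, X, demo) -> np.ndarray:
        logits = self.decision_function(X, demo)
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X, demo) -> np.ndarray:
        return self.classes_[self.decision_function(X, demo).argmax(axis=1)]

    def fusion_trace(self, X, demo, y_true=None,
                     subject_ids=None) -> FusionTrace:
        """Capture per-sample attention weights (evaluation mode)."""
        logits, omega1, omega2 = self._forward_eval(X, demo)
        pred = logits.data.argmax(axis=1)
        n = len(pred)
        w1 = omega1.data.astype(float)
        return FusionTrace(
            omega1=w1,
            # recompute the complement in float64 so the exact-sum
            # invariant holds on the recorded trace
            omega2=1.0 - w1,
            L=self.model_.L,
            subject_ids=(np.asarray(subject_ids) if subject_ids is not None
                         else np.array(["?"] * n)),
            true_labels=(np.asarray(y_true, dtype=int) if y_true is not None
                         else np.full(n, -1)),
            predicted_labels=pred.astype(int),
        )
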