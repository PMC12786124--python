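"""Neural building blocks: layers, a transformer encoder, and optimizers.

Everything is deterministic given the generator passed at construction;
dropout draws from that generator only in training mode, so evaluation
is exactly reproducible.
"""

from __future__ import annotations

import math

import numpy as np

from ._autograd import Tensor, concatenate

__all__ = [
    "Module", "Linear", "Dropout", "LayerNorm", "GraphConv", "Conv2d",
    "BiLSTM", "TransformerEncoderLayer", "max_pool_h2", "cross_entropy",
    "SGD", "AdamW",
]


class Module:
    """Base class with parameter traversal and train/eval switching."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()
        for value in self.__dict__.values():
            found: list = []
            if isinstance(value, Tensor) and value.requires_grad:
                found = [value]
            elif isinstance(value, Module):
                found = value.parameters()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        found.extend(item.parameters())
                    elif isinstance(item, Tensor) and item.requires_grad:
                        found.append(item)
            for p in found:
                if id(p) not in seen:
                    seen.add(id(p))
                    params.append(p)
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for value in self.__dict__.values():
            if isinstance(value, Module):
                mods.extend(value.modules())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=np.float32)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()


def _uniform(rng: np.random.Generator, shape, bound: float) -> Tensor:
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 bias: bool = True):
        k = 1.0 / math.sqrt(in_features)
        self.weight = _uniform(rng, (in_features, out_features), k)
        self.bias = _uniform(rng, (out_features,), k) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.weight
        if self.bias is not None:
            out = out + self.bias
        return out


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p = float(p)
        self.rng = rng
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape, dtype=np.float32) < keep
                ).astype(np.float32)
        mask /= keep
        return x * Tensor(mask)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class GraphConv(Module):
    """First-order graph convolution H' = A_hat H W + b.

    ``adjacency`` is the fixed, symmetrically normalized 62x62 matrix;
    node features are aggregated over spatial neighbours before the
    per-node linear map.
    """

    def __init__(self, in_features: int, out_features: int,
                 adjacency: np.ndarray, rng: np.random.Generator):
        self.adjacency = Tensor(np.asarray(adjacency, dtype=np.float32))
        k = 1.0 / math.sqrt(in_features)
        self.weight = _uniform(rng, (in_features, out_features), k)
        self.bias = _uniform(rng, (out_features,), k)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (..., nodes, in_features)
        return self.adjacency @ x @ self.weight + self.bias


class Conv2d(Module):
    """3x3 (by default) valid convolution, stride 1, NCHW layout."""

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel_size: int = 3):
        self.kernel_size = kernel_size
        fan_in = in_channels * kernel_size * kernel_size
        k = 1.0 / math.sqrt(fan_in)
        # one (C_in, C_out) matrix per kernel offset
        self.weight = _uniform(rng, (kernel_size, kernel_size, in_channels, out_channels), k)
        self.bias = _uniform(rng, (out_channels,), k)
        self.in_channels = in_channels
        self.out_channels = out_channels

    def __call__(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        ks = self.kernel_size
        Ho, Wo = H - ks + 1, W - ks + 1
        if Ho < 1 or Wo < 1:
            raise ValueError(f"input {H}x{W} smaller than {ks}x{ks} kernel")
        out = None
        for di in range(ks):
            for dj in range(ks):
                patch = x[:, :, di:di + Ho, dj:dj + Wo]            # (B,C,Ho,Wo)
                flat = patch.reshape(B, C, Ho * Wo).transpose(0, 2, 1)  # (B,HoWo,C)
                term = flat @ self.weight[di, dj]                   # (B,HoWo,O)
                out = term if out is None else out + term
        out = out + self.bias
        return out.transpose(0, 2, 1).reshape(B, self.out_channels, Ho, Wo)


def max_pool_h2(x: Tensor) -> Tensor:
    """(2,1) max pooling over the height axis of an NCHW tensor; odd rows drop."""
    H = x.shape[2]
    Ho = H // 2
    a = x[:, :, 0:2 * Ho:2, :]
    b = x[:, :, 1:2 * Ho:2, :]
    return a.maximum(b)


class BiLSTM(Module):
    """Bidirectional single-layer LSTM; returns concatenated final states."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator):
        self.hidden_size = hidden_size
        k = 1.0 / math.sqrt(hidden_size)
        self.w_x_f = _uniform(rng, (input_size, 4 * hidden_size), k)
        self.w_h_f = _uniform(rng, (hidden_size, 4 * hidden_size), k)
        self.b_f = _uniform(rng, (4 * hidden_size,), k)
        self.w_x_b = _uniform(rng, (input_size, 4 * hidden_size), k)
        self.w_h_b = _uniform(rng, (hidden_size, 4 * hidden_size), k)
        self.b_b = _uniform(rng, (4 * hidden_size,), k)

    def _run(self, xs: list[Tensor], w_x, w_h, b) -> Tensor:
        H = self.hidden_size
        B = xs[0].shape[0]
        h = Tensor(np.zeros((B, H)))
        c = Tensor(np.zeros((B, H)))
        for x in xs:
            z = x @ w_x + h @ w_h + b
            i = z[:, 0 * H:1 * H].sigmoid()
            f = z[:, 1 * H:2 * H].sigmoid()
            g = z[:, 2 * H:3 * H].tanh()
            o = z[:, 3 * H:4 * H].sigmoid()
            c = f * c + i * g
            h = o * c.tanh()
        return h

    def __call__(self, x: Tensor) -> Tensor:
        # x: (B, T, F) -> (B, 2*hidden)
        T = x.shape[1]
        steps = [x[:, t, :] for t in range(T)]
        h_fwd = self._run(steps, self.w_x_f, self.w_h_f, self.b_f)
        h_bwd = self._run(steps[::-1], self.w_x_b, self.w_h_b, self.b_b)
        return concatenate([h_fwd, h_bwd], axis=-1)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: self-attention + position-wise feed-forward."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, dropout: float,
                 rng: np.random.Generator):
        if d_model % n_heads:
            raise ValueError(f"d_model {d_model} not divisible by {n_heads} heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)
        self.ff1 = Linear(d_model, d_ff, rng)
        self.ff2 = Linear(d_ff, d_model, rng)
        self.norm1 = LayerNorm(d_model)
        self.norm2 = LayerNorm(d_model)
        self.drop_attn = Dropout(dropout, rng)
        self.drop1 = Dropout(dropout, rng)
        self.drop2 = Dropout(dropout, rng)

    def _split_heads(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.d_head).transpose(0, 2, 1, 3)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        q = self._split_heads(self.wq(x))
        k = self._split_heads(self.wk(x))
        v = self._split_heads(self.wv(x))
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.d_head))
        attn = self.drop_attn(scores.softmax(axis=-1))
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(B, T, D)
        x = self.norm1(x + self.drop1(self.wo(ctx)))
        ff = self.ff2(self.ff1(x).relu())
        return self.norm2(x + self.drop2(ff))


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy for integer class targets."""
    B, C = logits.shape
    onehot = np.zeros((B, C), dtype=np.float32)
    onehot[np.arange(B), np.asarray(targets, dtype=int)] = 1.0
    return -(Tensor(onehot) * logits.log_softmax(axis=-1)).sum() * (1.0 / B)


class SGD:
    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay

    def step(self) -> None:
        for p in self.params:
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            p.data -= self.lr * g


class AdamW:
    """Adam with decoupled weight decay."""

    def __init__(self, params: list[Tensor], lr: float, weight_decay: float = 0.0,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.weight_decay = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self._buf = [np.empty_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1**self.t
        bc2 = 1.0 - self.b2**self.t
        scale = self.lr / bc1
        for p, m, v, buf in zip(self.params, self.m, self.v, self._buf):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            np.multiply(g, 1.0 - self.b1, out=buf)
            m += buf
            v *= self.b2
            np.multiply(g, g, out=buf)
            buf *= 1.0 - self.b2
            v += buf
            if self.weight_decay:
                p.data *= 1.0 - self.lr * self.weight_decay
            np.multiply(v, 1.0 / bc2, out=buf)
            np.sqrt(buf, out=buf)
            buf += self.eps
            np.divide(m, buf, out=buf)
            buf *= scale
            p.data -= buf
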