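"""Network building blocks: linear, bidirectional LSTM, attention, layer norm.

Parameter initialisation follows the usual Glorot-uniform convention and is
driven by an explicit ``numpy.random.Generator`` so that every model in the
package is reproducible from a single integer seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class with recursive parameter discovery and a training flag."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        seen: set[int] = set()

        def walk(obj):
            if isinstance(obj, Tensor):
                if obj.requires_grad and id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    walk(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    walk(v)

        walk(self)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> None:
        self._set_mode(True)

    def eval(self) -> None:
        self._set_mode(False)

    def _set_mode(self, flag: bool) -> None:
        self.training = flag
        for v in vars(self).values():
            if isinstance(v, Module):
                v._set_mode(flag)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item._set_mode(flag)

    def state_dict(self) -> dict[str, np.ndarray]:
        return {f"p{i}": p.data for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"state has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}: {arr.shape} vs {p.data.shape}")
            p.data = arr

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape=None) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    shape = shape if shape is not None else (fan_in, fan_out)
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        self.w = glorot(rng, in_dim, out_dim)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.matmul(x, self.w) + self.b


class LSTM(Module):
    """Single-direction LSTM over (batch, time, features) input."""

    def __init__(self, in_dim: int, hidden: int, rng: np.random.Generator, reverse: bool = False):
        super().__init__()
        self.hidden = hidden
        self.reverse = reverse
        self.wx = glorot(rng, in_dim, 4 * hidden, (in_dim, 4 * hidden))
        self.wh = glorot(rng, hidden, 4 * hidden, (hidden, 4 * hidden))
        b = np.zeros(4 * hidden)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias trick
        self.b = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.lstm(x, self.wx, self.wh, self.b, reverse=self.reverse)


class BiLSTM(Module):
    """Bidirectional LSTM; output is the concatenation of both directions."""

    def __init__(self, in_dim: int, hidden_per_dir: int, rng: np.random.Generator):
        super().__init__()
        self.fwd = LSTM(in_dim, hidden_per_dir, rng, reverse=False)
        self.bwd = LSTM(in_dim, hidden_per_dir, rng, reverse=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.concat([self.fwd(x), self.bwd(x)], axis=-1)


class Dropout(Module):
    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def __call__(self, x: Tensor) -> Tensor:
        if not self.training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = self.rng.random(x.data.shape) < keep
        return x * (mask.astype(np.float64) / keep)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        inv = (var + self.eps) ** -0.5
        return centered * inv * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads:
            raise ValueError(f"d_model={d_model} not divisible by n_heads={n_heads}")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.wq = Linear(d_model, d_model, rng)
        self.wk = Linear(d_model, d_model, rng)
        self.wv = Linear(d_model, d_model, rng)
        self.wo = Linear(d_model, d_model, rng)

    def _split(self, x: Tensor, B: int, T: int) -> Tensor:
        # (B, T, D) -> (B, heads, T, d_head)
        return x.reshape(B, T, self.n_heads, self.d_head).swapaxes(1, 2)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        q = self._split(self.wq(x), B, T)
        k = self._split(self.wk(x), B, T)
        v = self._split(self.wv(x), B, T)
        scores = ad.matmul(q, k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.d_head))
        attn = ad.softmax(scores, axis=-1)
        ctx = ad.matmul(attn, v)  # (B, heads, T, d_head)
        merged = ctx.swapaxes(1, 2).reshape(B, T, D)
        return self.wo(merged)


class TransformerEncoderLayer(Module):
    """Pre-norm encoder block: LN -> MHSA -> residual, LN -> MLP -> residual."""

    def __init__(self, d_model: int, n_heads: int, d_ff: int, rng: np.random.Generator,
                 dropout: float = 0.0):
        super().__init__()
        self.ln1 = LayerNorm(d_model)
        self.attn = MultiHeadSelfAttention(d_model, n_heads, rng)
        self.ln2 = LayerNorm(d_model)
        self.fc1 = Linear(d_model, d_ff, rng)
        self.fc2 = Linear(d_ff, d_model, rng)
        self.drop = Dropout(dropout, rng)

    def __call__(self, x: Tensor) -> Tensor:
        x = x + self.drop(self.attn(self.ln1(x)))
        h = ad.relu(self.fc1(self.ln2(x)))
        return x + self.drop(self.fc2(h))


def sinusoidal_positions(n_positions: int, d_model: int) -> np.ndarray:
    """Classic fixed sine/cosine positional encoding table."""
    pos = np.arange(n_positions)[:, None]
    i = np.arange(d_model)[None, :]
    angle = pos / np.power(10000.0, (2 * (i // 2)) / d_model)
    table = np.where(i % 2 == 0, np.sin(angle), np.cos(angle))
    return table  # (n_positions, d_model)
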