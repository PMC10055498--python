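"""Neural-network building blocks on top of the autodiff engine.

Weight initialisation follows the symmetric uniform fan-in scheme
(U(-1/sqrt(fan_in), 1/sqrt(fan_in))) for linear layers; positional
embeddings use small Gaussians; heads get zero bias.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .icosphere import WindowMap

__all__ = ["Module", "Linear", "LayerNorm", "Dropout", "FeedForward", "WindowAttention", "LocalMHSABlock"]


class Module:
    """Parameter container with recursive, deterministically ordered traversal."""

    def named_parameters(self, prefix: str = ""):
        def walk(name: str, val):
            if isinstance(val, Tensor) and val.requires_grad:
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(f"{name}.")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    yield from walk(f"{name}.{i}", item)

        for key, val in vars(self).items():
            yield from walk(f"{prefix}{key}", val)

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        missing = set(params) ^ set(state)
        if missing:
            raise ValueError(f"state dict mismatch: {sorted(missing)}")
        for k, p in params.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, zero_bias: bool = False):
        bound = 1.0 / np.sqrt(d_in)
        self.weight = Tensor(rng.uniform(-bound, bound, size=(d_in, d_out)), requires_grad=True)
        b = np.zeros(d_out) if zero_bias else rng.uniform(-bound, bound, size=d_out)
        self.bias = Tensor(b, requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.eps) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None, training: bool) -> Tensor:
        if not training or self.p == 0.0:
            return x
        if rng is None:
            raise ValueError("dropout in training mode needs an rng")
        mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class FeedForward(Module):
    """Two-layer MLP with GELU, the transformer FFN."""

    def __init__(self, dim: int, mlp_ratio: float, rng: np.random.Generator):
        hidden = int(round(dim * mlp_ratio))
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class WindowAttention(Module):
    """Multi-head self-attention restricted to non-overlapping sequence windows.

    With ``shift > 0`` the sequence is cyclically rolled by ``-shift``
    positions before windowing and rolled back after, so a fraction of each
    window's patches comes from adjacent windows (shifted-window attention).
    On a closed sphere there is no sequence border, so no attention mask is
    applied to rolled-over tokens.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads = heads
        self.q = Linear(dim, dim, rng)
        self.k = Linear(dim, dim, rng)
        self.v = Linear(dim, dim, rng)
        self.proj = Linear(dim, dim, rng)

    def __call__(
        self,
        x: Tensor,
        wmap: WindowMap,
        shift: int = 0,
        attn_sink: list | None = None,
    ) -> Tensor:
        B, L, d = x.shape
        if L != wmap.seq_len:
            raise ValueError(f"sequence length {L} != window map length {wmap.seq_len}")
        nw, w, h = wmap.n_windows, wmap.window_size, self.heads
        dh = d // h
        if shift:
            x = x.roll(-shift, axis=1)

        def split(t: Tensor) -> Tensor:
            # (B, L, d) -> (B, nw, h, w, dh)
            return t.reshape(B, nw, w, h, dh).transpose(0, 1, 3, 2, 4)

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose(0, 1, 2, 4, 3)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(-1)  # (B, nw, h, w, w)
        if attn_sink is not None:
            attn_sink.append(attn.data.copy())
        out = (attn @ v).transpose(0, 1, 3, 2, 4).reshape(B, L, d)
        out = self.proj(out)
        if shift:
            out = out.roll(shift, axis=1)
        return out


class LocalMHSABlock(Module):
    """One local-MHSA block: W-MHSA, FFN, SW-MHSA, FFN, each pre-norm + residual.

    The shifted sub-step reuses the same window map after a cyclic roll by
    the map's shift; with shift 0 (or a global window) it computes exactly
    the windowed sub-step's function.
    """

    def __init__(self, dim: int, heads: int, mlp_ratio: float, rng: np.random.Generator):
        self.norm1 = LayerNorm(dim)
        self.attn_w = WindowAttention(dim, heads, rng)
        self.norm2 = LayerNorm(dim)
        self.ffn1 = FeedForward(dim, mlp_ratio, rng)
        self.norm3 = LayerNorm(dim)
        self.attn_sw = WindowAttention(dim, heads, rng)
        self.norm4 = LayerNorm(dim)
        self.ffn2 = FeedForward(dim, mlp_ratio, rng)

    def __call__(self, x: Tensor, wmap: WindowMap, attn_sink: list | None = None) -> Tensor:
        x = x + self.attn_w(self.norm1(x), wmap, shift=0, attn_sink=attn_sink)
        x = x + self.ffn1(self.norm2(x))
        x = x + self.attn_sw(self.norm3(x), wmap, shift=wmap.shift, attn_sink=attn_sink)
        x = x + self.ffn2(self.norm4(x))
        return x
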