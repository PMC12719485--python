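"""Neural-network building blocks on the autodiff engine.

Layers mirror the BEiT-family transformer encoder: patch embedding,
pre-norm residual blocks with layer-scale, attention with a learned
decomposed relative-position bias (queries/values biased, keys not),
and an AdamW optimizer with decoupled weight decay.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


def kaiming_normal(rng: np.random.Generator, fan_in: int, shape, dtype=np.float64) -> np.ndarray:
    """Kaiming (He) normal initialization: std = sqrt(2 / fan_in)."""
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Module:
    """Tiny module base: named parameter registry and train/eval mode."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def register(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def add_child(self, name: str, child: "Module") -> "Module":
        self._children[name] = child
        return child

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + name, t) for name, t in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def n_parameters(self) -> int:
        """Count of trainable scalars."""
        return int(sum(t.data.size for t in self.parameters()))

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: t.data.copy() for name, t in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"state dict missing parameters: {sorted(missing)}")
        for name, t in own.items():
            arr = np.asarray(state[name])
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for {name}: {arr.shape} vs {t.data.shape}")
            t.data = arr.astype(t.data.dtype)

    def zero_grad(self) -> None:
        for t in self.parameters():
            t.zero_grad()


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 bias: bool = True, init: str = "kaiming", dtype=np.float64):
        super().__init__()
        if init == "kaiming":
            w = kaiming_normal(rng, d_in, (d_in, d_out), dtype)
        elif init == "zeros":
            w = np.zeros((d_in, d_out), dtype)
        elif init == "empty":
            w = np.empty((d_in, d_out), dtype)
        else:  # small uniform, torch-style fallback
            bound = 1.0 / np.sqrt(d_in)
            w = rng.uniform(-bound, bound, (d_in, d_out)).astype(dtype)
        self.weight = self.register("weight", w)
        self.bias = self.register("bias", np.zeros(d_out, dtype)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, dim: int, dtype=np.float64, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = self.register("gamma", np.ones(dim, dtype))
        self.beta = self.register("beta", np.zeros(dim, dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.gamma, self.beta, self.eps)


def relative_position_index(grid: int) -> np.ndarray:
    """BEiT-style relative-position index for a grid of patch tokens + CLS.

    Table rows: (2g-1)^2 token-token offsets plus 3 special entries
    (cls->token, token->cls, cls->cls).  Returns an (N, N) int index with
    N = grid*grid + 1.
    """
    coords = np.stack(np.meshgrid(np.arange(grid), np.arange(grid), indexing="ij"))
    flat = coords.reshape(2, -1)  # (2, g*g)
    rel = flat[:, :, None] - flat[:, None, :]  # (2, T, T)
    rel = rel.transpose(1, 2, 0) + (grid - 1)  # shift to >= 0
    token_idx = rel[:, :, 0] * (2 * grid - 1) + rel[:, :, 1]
    n_token = grid * grid
    n_rel = (2 * grid - 1) ** 2
    idx = np.zeros((n_token + 1, n_token + 1), dtype=np.int64)
    idx[1:, 1:] = token_idx
    idx[0, 1:] = n_rel  # cls -> token
    idx[1:, 0] = n_rel + 1  # token -> cls
    idx[0, 0] = n_rel + 2  # cls -> cls
    return idx


class EncoderSelfAttention(Module):
    """Encoder-block attention: q/v-biased projections, per-head relative bias."""

    def __init__(self, dim: int, heads: int, grid: int, rng: np.random.Generator,
                 init: str = "kaiming", dtype=np.float64):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.d_head = dim, heads, dim // heads
        self.scale = 1.0 / np.sqrt(self.d_head)
        self.q = self.add_child("q", Linear(dim, dim, rng, bias=True, init=init, dtype=dtype))
        self.k = self.add_child("k", Linear(dim, dim, rng, bias=False, init=init, dtype=dtype))
        self.v = self.add_child("v", Linear(dim, dim, rng, bias=True, init=init, dtype=dtype))
        self.proj = self.add_child("proj", Linear(dim, dim, rng, bias=True, init=init, dtype=dtype))
        n_rel = (2 * grid - 1) ** 2 + 3
        self.rel_bias_table = self.register(
            "rel_bias_table", np.zeros((n_rel, heads), dtype))
        self._rel_index = relative_position_index(grid)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        h, dh = self.heads, self.d_head

        def split(t: Tensor) -> Tensor:  # (B,T,dim) -> (B,h,T,dh)
            return t.reshape((B, T, h, dh)).transpose((0, 2, 1, 3))

        q, k, v = split(self.q(x)), split(self.k(x)), split(self.v(x))
        scores = (q @ k.transpose((0, 1, 3, 2))) * self.scale
        flat_idx = self._rel_index[:T, :T].reshape(-1)
        bias = ad.take(self.rel_bias_table, flat_idx, axis=0)  # (T*T, h)
        bias = bias.reshape((T, T, h)).transpose((2, 0, 1))  # (h,T,T)
        attn = ad.softmax(scores + bias, axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape((B, T, self.dim))
        return self.proj(out)


class Mlp(Module):
    def __init__(self, dim: int, hidden: int, rng, init="kaiming", dtype=np.float64):
        super().__init__()
        self.fc1 = self.add_child("fc1", Linear(dim, hidden, rng, init=init, dtype=dtype))
        self.fc2 = self.add_child("fc2", Linear(hidden, dim, rng, init=init, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(ad.gelu(self.fc1(x)))


class EncoderBlock(Module):
    """Pre-norm residual block with layer-scale and stochastic depth."""

    def __init__(self, dim: int, heads: int, mlp_ratio: float, grid: int,
                 drop_path: float, rng, init="kaiming", dtype=np.float64,
                 layer_scale_init: float = 1e-4):
        super().__init__()
        self.drop_path = float(drop_path)
        self.norm1 = self.add_child("norm1", LayerNorm(dim, dtype))
        self.attn = self.add_child("attn", EncoderSelfAttention(dim, heads, grid, rng, init, dtype))
        self.gamma_1 = self.register("gamma_1", np.full(dim, layer_scale_init, dtype))
        self.norm2 = self.add_child("norm2", LayerNorm(dim, dtype))
        self.mlp = self.add_child("mlp", Mlp(dim, int(dim * mlp_ratio), rng, init, dtype))
        self.gamma_2 = self.register("gamma_2", np.full(dim, layer_scale_init, dtype))

    def _residual(self, x: Tensor, branch: Tensor, rng) -> Tensor:
        p = self.drop_path
        if rng is not None and p > 0.0:
            if rng.random() < p:  # whole-batch block drop
                return x
            return x + branch * (1.0 / (1.0 - p))
        return x + branch

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = self._residual(x, self.attn(self.norm1(x)) * self.gamma_1, rng)
        x = self._residual(x, self.mlp(self.norm2(x)) * self.gamma_2, rng)
        return x


class PatchEmbed(Module):
    """Non-overlapping patch projection (conv expressed as unfold + linear)."""

    def __init__(self, img_size: int, patch_size: int, dim: int, rng,
                 init="kaiming", dtype=np.float64, in_chans: int = 3):
        super().__init__()
        if img_size % patch_size:
            raise ValueError(f"img_size {img_size} not divisible by patch {patch_size}")
        self.patch_size = patch_size
        self.grid = img_size // patch_size
        self.n_patches = self.grid * self.grid
        d_in = in_chans * patch_size * patch_size
        self.proj = self.add_child("proj", Linear(d_in, dim, rng, init=init, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        """(B, 3, H, W) -> (B, n_patches, dim)."""
        B, C, H, W = x.shape
        p, g = self.patch_size, self.grid
        x = x.reshape((B, C, g, p, g, p))
        x = x.transpose((0, 2, 4, 1, 3, 5))  # (B, g, g, C, p, p)
        x = x.reshape((B, g * g, C * p * p))
        return self.proj(x)


class AdamW:
    """AdamW with decoupled weight decay (Loshchilov & Hutter semantics)."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * update

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
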