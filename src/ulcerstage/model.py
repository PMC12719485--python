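"""Backbone-agnostic staging classifier.

The encoder is a BEiT-family vision transformer (bidirectional attention,
q/v-biased projections, decomposed relative-position bias tables,
layer-scale residuals).  On top of it sit the three architectural pieces
specific to wound staging:

* **hierarchical fusion** — mean-pooled outputs of intermediate blocks
  (6, 9, 12 at full depth), each linearly projected to the model width and
  summed with the attention-refined CLS vector, so low-level tissue
  texture and high-level semantics feed the head together;
* **enhanced attention** — an extra 8-head self-attention module with an
  additive relative-position score bias ``softmax(QK^T/sqrt(d_k) + R_pos)V``
  applied to the final token sequence, whose CLS row becomes the feature;
* **staged head** — ``W3·Drop(LN(GELU(W2·Drop(LN(GELU(W1·x))))))`` with
  dims 768 -> 768 -> 384 -> 6, Kaiming-normal initialized.

The same wiring instantiates both the full-size configuration (used only
to count parameters; pretrained weights are a deployment concern) and a
miniature encoder for desk-scale training.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .nn import (
    AdamW,  # re-export for training  # noqa: F401
    EncoderBlock,
    LayerNorm,
    Linear,
    Module,
    PatchEmbed,
)

N_CLASSES = 6


@dataclass(frozen=True)
class BackboneSpec:
    """Encoder geometry.  Full model: depth 12, dim 768, heads 12, taps (6, 9, 12)."""

    depth: int = 12
    dim: int = 768
    heads: int = 12
    patch_size: int = 16
    img_size: int = 224
    mlp_ratio: float = 4.0
    tap_blocks: tuple[int, ...] = (6, 9, 12)
    pretrained_id: str = "random"

    def __post_init__(self):
        if self.dim % self.heads:
            raise ValueError(f"dim {self.dim} not divisible by heads {self.heads}")
        bad = [b for b in self.tap_blocks if not 1 <= b <= self.depth]
        if bad:
            raise ValueError(f"tap blocks {bad} outside 1..{self.depth}")


@dataclass(frozen=True)
class AttentionHeadConfig:
    """Enhanced-attention module: 8 heads at model width 768 (full scale)."""

    heads: int = 8
    dim: int = 768

    def __post_init__(self):
        if self.dim % self.heads:
            raise ValueError(f"dim {self.dim} not divisible by heads {self.heads}")


@dataclass(frozen=True)
class ClassifierHeadConfig:
    """Three weight matrices with GELU/LayerNorm/Dropout between them."""

    dims: tuple[int, int, int, int] = (768, 768, 384, 6)
    dropout: float = 0.3

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0,1), got {self.dropout}")


@dataclass(frozen=True)
class StochasticDepthSchedule:
    """Per-block residual drop probability, linear in depth from 0 to max_rate."""

    depth: int
    max_rate: float = 0.1

    def rates(self) -> list[float]:
        if self.depth == 1:
            return [0.0]
        return [self.max_rate * i / (self.depth - 1) for i in range(self.depth)]


def beit_base_spec() -> BackboneSpec:
    """The full-scale encoder configuration (BEiT-base-patch16-224 geometry)."""
    return BackboneSpec(pretrained_id="microsoft/beit-base-patch16-224-pt22k-ft22k")


def tiny_spec(img_size: int = 32, depth: int = 2, dim: int = 32, heads: int = 4,
              patch_size: int = 8, tap_blocks: tuple[int, ...] | None = None) -> BackboneSpec:
    """A miniature encoder with identical wiring, for desk-scale training."""
    taps = tap_blocks if tap_blocks is not None else tuple(range(1, depth + 1))
    return BackboneSpec(depth=depth, dim=dim, heads=heads, patch_size=patch_size,
                        img_size=img_size, tap_blocks=taps, pretrained_id="random")


# -- functional forms (oracle-testable, pure numpy) ------------------------

def enhanced_attention(q: np.ndarray, k: np.ndarray, v: np.ndarray,
                       heads: int = 1, r_pos: np.ndarray | None = None,
                       w_out: np.ndarray | None = None) -> np.ndarray:
    """Relative-position-biased scaled dot-product attention.

    ``softmax(QK^T / sqrt(d_k) + R_pos) V`` per head; heads are split from
    the last axis, concatenated back, and optionally output-projected.
    Accepts 2-D (tokens, dim) or batched (..., tokens, dim) arrays.
    """
    q, k, v = np.asarray(q, float), np.asarray(k, float), np.asarray(v, float)
    dim = q.shape[-1]
    if dim % heads:
        raise ValueError(f"dim {dim} not divisible by heads {heads}")
    d_k = dim // heads
    outs = []
    for h in range(heads):
        sl = slice(h * d_k, (h + 1) * d_k)
        scores = q[..., sl] @ np.swapaxes(k[..., sl], -1, -2) / np.sqrt(d_k)
        if r_pos is not None:
            scores = scores + r_pos
        scores = scores - scores.max(axis=-1, keepdims=True)
        w = np.exp(scores)
        w = w / w.sum(axis=-1, keepdims=True)
        outs.append(w @ v[..., sl])
    out = np.concatenate(outs, axis=-1)
    if w_out is not None:
        out = out @ w_out
    return out


def hierarchical_fuse(taps: list[np.ndarray], cls_vector: np.ndarray,
                      projections: list[np.ndarray],
                      biases: list[np.ndarray] | None = None) -> np.ndarray:
    """Mean-pool each tap over tokens, project, and sum with the CLS vector."""
    if len(taps) != len(projections):
        raise ValueError(f"{len(taps)} taps but {len(projections)} projections")
    fused = np.asarray(cls_vector, float).copy()
    for i, (tap, w) in enumerate(zip(taps, projections)):
        pooled = np.asarray(tap, float).mean(axis=-2)
        y = pooled @ w
        if biases is not None:
            y = y + biases[i]
        fused = fused + y
    return fused


# -- modules ---------------------------------------------------------------

class EnhancedAttention(Module):
    """The add-on attention module: four d x d projections (Q, K, V, output).

    ``r_pos`` is an additive score-bias buffer (zeros unless set); it is a
    buffer, not a trainable table, so the module's trainable size is exactly
    ``4 * d * (d + 1)``.
    """

    def __init__(self, cfg: AttentionHeadConfig, rng: np.random.Generator,
                 init: str = "kaiming", dtype=np.float64):
        super().__init__()
        self.cfg = cfg
        d = cfg.dim
        self.wq = self.add_child("wq", Linear(d, d, rng, init=init, dtype=dtype))
        self.wk = self.add_child("wk", Linear(d, d, rng, init=init, dtype=dtype))
        self.wv = self.add_child("wv", Linear(d, d, rng, init=init, dtype=dtype))
        self.wo = self.add_child("wo", Linear(d, d, rng, init=init, dtype=dtype))
        self.r_pos: np.ndarray | None = None  # (T, T) additive bias buffer
        self.scale = 1.0 / np.sqrt(d // cfg.heads)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, d = x.shape
        h = self.cfg.heads
        dh = d // h

        def split(t: Tensor) -> Tensor:
            return t.reshape((B, T, h, dh)).transpose((0, 2, 1, 3))

        q, k, v = split(self.wq(x)), split(self.wk(x)), split(self.wv(x))
        scores = (q @ k.transpose((0, 1, 3, 2))) * self.scale
        if self.r_pos is not None:
            scores = scores + Tensor(self.r_pos[:T, :T])
        attn = ad.softmax(scores, axis=-1)
        out = (attn @ v).transpose((0, 2, 1, 3)).reshape((B, T, d))
        return self.wo(out)


class ClassifierHead(Module):
    """``W3·Drop(LN(GELU(W2·Drop(LN(GELU(W1·x))))))`` with Kaiming init."""

    def __init__(self, cfg: ClassifierHeadConfig, rng: np.random.Generator,
                 init: str = "kaiming", dtype=np.float64):
        super().__init__()
        d0, d1, d2, d3 = cfg.dims
        self.dropout = cfg.dropout
        self.fc1 = self.add_child("fc1", Linear(d0, d1, rng, init=init, dtype=dtype))
        self.norm1 = self.add_child("norm1", LayerNorm(d1, dtype))
        self.fc2 = self.add_child("fc2", Linear(d1, d2, rng, init=init, dtype=dtype))
        self.norm2 = self.add_child("norm2", LayerNorm(d2, dtype))
        self.fc3 = self.add_child("fc3", Linear(d2, d3, rng, init=init, dtype=dtype))

    def __call__(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        x = ad.dropout(self.norm1(ad.gelu(self.fc1(x))), self.dropout, rng)
        x = ad.dropout(self.norm2(ad.gelu(self.fc2(x))), self.dropout, rng)
        return self.fc3(x)


class StagingNetwork(Module):
    """Encoder + (optional) enhanced attention + (optional) fusion + head."""

    def __init__(self, spec: BackboneSpec, n_classes: int = N_CLASSES,
                 use_enhanced_attention: bool = True,
                 use_hierarchical_fusion: bool = True,
                 attention_heads: int | None = None,
                 head_dropout: float = 0.3,
                 stochastic_depth: float = 0.1,
                 seed: int = 0, init: str = "kaiming", dtype=np.float64):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.dtype = dtype
        self.use_enhanced_attention = use_enhanced_attention
        self.use_hierarchical_fusion = use_hierarchical_fusion
        d = spec.dim
        self.patch_embed = self.add_child(
            "patch_embed", PatchEmbed(spec.img_size, spec.patch_size, d, rng, init, dtype))
        self.cls_token = self.register("cls_token", np.zeros((1, 1, d), dtype))
        grid = self.patch_embed.grid
        sd_rates = StochasticDepthSchedule(spec.depth, stochastic_depth).rates()
        self.blocks = [
            self.add_child(f"block{i}", EncoderBlock(
                d, spec.heads, spec.mlp_ratio, grid, sd_rates[i], rng, init, dtype))
            for i in range(spec.depth)
        ]
        self.norm = self.add_child("norm", LayerNorm(d, dtype))
        if use_enhanced_attention:
            heads = attention_heads if attention_heads is not None else (
                8 if d % 8 == 0 else spec.heads)
            self.enh_attn = self.add_child(
                "enh_attn", EnhancedAttention(AttentionHeadConfig(heads, d), rng, init, dtype))
        else:
            self.enh_attn = None
        if use_hierarchical_fusion:
            self.tap_projs = [
                self.add_child(f"tap_proj{b}", Linear(d, d, rng, init=init, dtype=dtype))
                for b in spec.tap_blocks
            ]
        else:
            self.tap_projs = []
        self.fc_norm = self.add_child("fc_norm", LayerNorm(d, dtype))
        self.head_cfg = ClassifierHeadConfig((d, d, max(d // 2, n_classes), n_classes),
                                             head_dropout)
        self.head = self.add_child("head", ClassifierHead(self.head_cfg, rng, init, dtype))

    def forward(self, x, train: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        """Images (B, 3, H, W) -> logits (B, n_classes)."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, self.dtype))
        drop_rng = rng if train else None
        tokens = self.patch_embed(x)
        B = tokens.shape[0]
        cls = self.cls_token + Tensor(np.zeros((B, 1, self.spec.dim), self.dtype))
        seq = ad.concat([cls, tokens], axis=1)
        taps: dict[int, Tensor] = {}
        for i, block in enumerate(self.blocks, start=1):
            seq = block(seq, drop_rng)
            if i in self.spec.tap_blocks:
                taps[i] = seq
        seq = self.norm(seq)
        if self.enh_attn is not None:
            refined = self.enh_attn(seq)
            cls_vec = refined[:, 0, :]
        else:
            cls_vec = seq[:, 0, :]
        if self.tap_projs:
            missing = [b for b in self.spec.tap_blocks if b not in taps]
            if missing:
                raise RuntimeError(f"missing tap outputs for blocks {missing}")
            fused = cls_vec
            for b, proj in zip(self.spec.tap_blocks, self.tap_projs):
                fused = fused + proj(taps[b].mean(axis=1))
        else:
            fused = cls_vec
        return self.head(self.fc_norm(fused), drop_rng)

    __call__ = forward

    def predict_proba(self, x, batch_size: int = 32) -> np.ndarray:
        """Eval-mode class probabilities, row-wise softmax of the logits."""
        x = np.asarray(x, self.dtype)
        out = []
        for lo in range(0, len(x), batch_size):
            logits = self.forward(x[lo:lo + batch_size], train=False).data
            shifted = logits - logits.max(axis=1, keepdims=True)
            e = np.exp(shifted)
            out.append(e / e.sum(axis=1, keepdims=True))
        return np.concatenate(out, axis=0)


def classifier_forward(features: np.ndarray, head: ClassifierHead,
                       mode: str = "eval",
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """Run the staged head on raw features; eval mode is deterministic."""
    feats = np.asarray(features, float)
    if feats.shape[-1] != head.fc1.weight.shape[0]:
        raise ValueError(
            f"feature length {feats.shape[-1]} != head input {head.fc1.weight.shape[0]}")
    use_rng = rng if mode == "train" else None
    if mode == "train" and rng is None:
        raise ValueError("train mode needs an rng for dropout")
    return head(Tensor(feats), use_rng).data


def build_network(spec: BackboneSpec, variant: str = "enhanced", *,
                  use_hierarchical_fusion: bool | None = None,
                  seed: int = 0, init: str = "kaiming",
                  dtype=np.float64, **kw) -> StagingNetwork:
    if variant not in ("standard", "enhanced"):
        raise ValueError(f"unknown variant {variant!r}")
    fusion = (variant == "enhanced") if use_hierarchical_fusion is None else use_hierarchical_fusion
    return StagingNetwork(spec, use_enhanced_attention=(variant == "enhanced"),
                          use_hierarchical_fusion=fusion, seed=seed, init=init,
                          dtype=dtype, **kw)


def count_parameters(variant: str = "standard", spec: BackboneSpec | None = None) -> int:
    """Trainable-scalar count of a variant.

    Hierarchical-fusion projections are a switchable add-on excluded from
    both counted variants, so enhanced - standard is exactly the enhanced
    attention module: ``4 * d * (d + 1)``.
    """
    spec = spec or beit_base_spec()
    net = build_network(spec, variant, use_hierarchical_fusion=False,
                        init="empty", dtype=np.float32)
    return net.n_parameters()


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(path, net: StagingNetwork, epoch: int, fold: int | None = None) -> None:
    """Persist weights + geometry + provenance as a compressed npz."""
    meta = dict(asdict(net.spec))
    meta["tap_blocks"] = list(meta["tap_blocks"])
    meta.update(epoch=epoch, fold=-1 if fold is None else fold,
                use_enhanced_attention=net.use_enhanced_attention,
                use_hierarchical_fusion=net.use_hierarchical_fusion)
    state = {f"param/{k}": v for k, v in net.state_dict().items()}
    np.savez(path, __meta__=np.array([json.dumps(meta)]), **state)


def load_checkpoint(path, net: StagingNetwork) -> dict:
    """Load weights into `net`; returns the checkpoint metadata dict."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"][0]))
        state = {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
    net.load_state_dict(state)
    return meta
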