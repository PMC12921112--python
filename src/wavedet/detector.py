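"""End-to-end two-stage deformable detection transformer.

Pipeline: a strided CNN backbone emits a four-scale feature pyramid
(strides 4/8/16/32); the projection stage unifies channels with 1x1
convolutions and applies the wavelet projection (WTP) to every scale; the
flattened multi-scale tokens pass through N deformable self-attention
encoder blocks; an encoder detection head scores every token against a
uniform anchor grid and the top-K most confident proposals seed K decoder
queries; M decoder blocks alternate dense self-attention, deformable
cross-attention into the encoder memory and an FFN, each emitting box
offsets applied in logit (inverse-sigmoid) space.  Box gradients follow the
look-forward-twice contract: the boxes a layer reports are built from the
previous layer's *undetached* refinement, while the box fed onward is
detached, so a layer's box loss reaches its own and the previous layer's
refinement parameters only.

Boxes are normalized (cx, cy, w, h), held as pre-sigmoid logits internally
and in (0, 1) after sigmoid everywhere they are reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat, no_grad
from .matching import LayerPredictions
from .nn import MLP, Linear, LayerNorm, Module, Parameter, conv2d
from .wavelet import WTPConfig, WaveletProjection

__all__ = [
    "ImageTensor",
    "FeaturePyramid",
    "ContentEncoding",
    "ModelConfig",
    "TinyBackbone",
    "extract_features",
    "sinusoidal_position_encoding",
    "inverse_sigmoid",
    "DeformableAttention",
    "WaveletDetector",
    "DetectionRecord",
    "perturb_parameters",
]

REFERENCE_STRIDES = (4, 8, 16, 32)
REFERENCE_CHANNELS = (256, 512, 1024, 2048)


@dataclass
class ImageTensor:
    """A 3-channel image (grayscale images are channel-replicated)."""

    data: np.ndarray           # (3, H, W), normalized
    original_size: tuple       # (H, W) in pixels

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or self.data.shape[0] != 3:
            raise ValueError(f"expected (3, H, W) image, got {self.data.shape}")


@dataclass
class FeaturePyramid:
    """Multi-scale backbone outputs F0..F3 with their stride/channel contract."""

    maps: list                 # four Tensors (N, C_i, H_i, W_i)
    strides: tuple = REFERENCE_STRIDES
    channels: tuple = REFERENCE_CHANNELS

    def __post_init__(self):
        if len(self.maps) != 4:
            raise ValueError("expected four pyramid levels")
        for m, c in zip(self.maps, self.channels):
            if m.shape[-3] != c:
                raise ValueError(
                    f"pyramid channel contract violated: got {m.shape[-3]}, "
                    f"expected {c}"
                )


@dataclass
class ContentEncoding:
    """Flattened multi-scale tokens plus their spatial bookkeeping."""

    tokens: Tensor             # (N, L, D)
    pos: np.ndarray            # (L, D) positional encoding
    level_index: np.ndarray    # (L,) pyramid level of each token
    positions: np.ndarray      # (L, 2) normalized (cx, cy) of each token
    shapes: list               # [(H_l, W_l)] per level


@dataclass
class DetectionRecord:
    """One final prediction in COCO results dialect."""

    image_id: int
    category_id: int
    bbox: list                 # [x, y, w, h] absolute pixels
    score: float

    def to_json(self) -> dict:
        return {"image_id": int(self.image_id),
                "category_id": int(self.category_id),
                "bbox": [float(v) for v in self.bbox],
                "score": float(self.score)}


@dataclass
class ModelConfig:
    num_classes: int = 9
    hidden_dim: int = 256
    heads: int = 8
    encoder_layers: int = 6
    decoder_layers: int = 6
    num_queries: int = 300
    deformable_points: int = 4
    ffn_hidden_dim: int = 1024
    backbone_channels: tuple = REFERENCE_CHANNELS
    backbone_stem: int = 32
    anchor_base_size: float = 0.05
    use_wtp: bool = True
    wtp: WTPConfig = field(default_factory=WTPConfig)
    score_threshold: float = 0.3

    def __post_init__(self):
        if self.hidden_dim % self.heads:
            raise ValueError("hidden_dim must be divisible by heads")


# ---------------------------------------------------------------------------
# Backbone
# ---------------------------------------------------------------------------

class _ConvBlock(Module):
    def __init__(self, cin, cout, stride, rng):
        super().__init__()
        k = 3
        bound = 1.0 / math.sqrt(cin * k * k)
        self.weight = Parameter(rng.uniform(-bound, bound, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout))
        self.stride = stride

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride,
                      padding=1).relu()


class TinyBackbone(Module):
    """A 4-stage strided CNN honouring the stride-(4, 8, 16, 32) contract.

    Stands in for the 50-layer residual reference backbone at desk scale;
    the channel tuple is configurable so tests can shrink it.
    """

    def __init__(self, channels: tuple = REFERENCE_CHANNELS,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.channels = tuple(channels)
        stem = max(8, channels[0] // 2)
        self.stem1 = _ConvBlock(3, stem, 2, rng)
        self.stem2 = _ConvBlock(stem, channels[0], 2, rng)
        self.stage1 = _ConvBlock(channels[0], channels[1], 2, rng)
        self.stage2 = _ConvBlock(channels[1], channels[2], 2, rng)
        self.stage3 = _ConvBlock(channels[2], channels[3], 2, rng)

    def forward(self, x: Tensor) -> FeaturePyramid:
        f0 = self.stem2(self.stem1(x))
        f1 = self.stage1(f0)
        f2 = self.stage2(f1)
        f3 = self.stage3(f2)
        return FeaturePyramid([f0, f1, f2, f3], channels=self.channels)


def extract_features(image, backbone: Module) -> FeaturePyramid:
    """Run the backbone on one image or a batch; enforces the size contract."""
    if isinstance(image, ImageTensor):
        x = Tensor(image.data[None])
    elif isinstance(image, Tensor):
        x = image if image.ndim == 4 else image.reshape(1, *image.shape)
    else:
        arr = np.asarray(image, dtype=np.float32)
        x = Tensor(arr[None] if arr.ndim == 3 else arr)
    h, w = x.shape[-2], x.shape[-1]
    if h < 32 or w < 32:
        raise ValueError(
            f"image {h}x{w} is smaller than the total backbone stride (32)"
        )
    return backbone(x)


# ---------------------------------------------------------------------------
# Positional encodings
# ---------------------------------------------------------------------------

def sinusoidal_position_encoding(coords, dim: int = 256,
                                 temperature: float = 20.0):
    """Interleaved sine-cosine encoding of coordinates in [0, 1].

    ``coords``: array or Tensor (..., n_coords); each coordinate receives
    dim // n_coords channels alternating sin/cos at geometric frequencies.
    Coordinate 0 maps to sin components 0 and cos components 1.
    """
    is_tensor = isinstance(coords, Tensor)
    nc = coords.shape[-1]
    if dim % (2 * nc):
        raise ValueError(f"dim {dim} not divisible by 2*{nc} coordinates")
    half = dim // (2 * nc)
    freqs = (temperature ** (np.arange(half) / half)).astype(np.float32) \
        * 2.0 * np.pi
    if is_tensor:
        scaled = coords.reshape(*coords.shape, 1) * Tensor(freqs)
        cos_part = (scaled + 0.5 * np.pi)
        # sin(x) and cos(x) = sin(x + pi/2); composed from tanh-free primitives
        out = concat([_sin(scaled), _sin(cos_part)], axis=-1)
        return out.reshape(*coords.shape[:-1], dim)
    arr = np.asarray(coords, dtype=np.float32)
    scaled = arr[..., None] * freqs
    out = np.concatenate([np.sin(scaled), np.cos(scaled)], axis=-1)
    return out.reshape(*arr.shape[:-1], dim).astype(np.float32)


def _sin(x: Tensor) -> Tensor:
    data = np.sin(x.data)
    cos = np.cos(x.data)

    def backward(g):
        x._accum(g * cos)

    return Tensor._make(data, (x,), backward)


def inverse_sigmoid(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    x = np.clip(np.asarray(x, dtype=np.float32), eps, 1.0 - eps)
    return np.log(x / (1.0 - x))


# ---------------------------------------------------------------------------
# Attention
# ---------------------------------------------------------------------------

class MultiheadAttention(Module):
    """Standard dense scaled-dot-product attention."""

    def __init__(self, dim: int, heads: int, rng):
        super().__init__()
        self.dim, self.heads, self.dh = dim, heads, dim // heads
        self.q_proj = Linear(dim, dim, rng)
        self.k_proj = Linear(dim, dim, rng)
        self.v_proj = Linear(dim, dim, rng)
        self.out_proj = Linear(dim, dim, rng)

    def forward(self, q: Tensor, k: Tensor, v: Tensor) -> Tensor:
        n, lq, _ = q.shape
        lk = k.shape[1]
        def split(x, l):
            return x.reshape(n, l, self.heads, self.dh).transpose(0, 2, 1, 3)
        qh = split(self.q_proj(q), lq)
        kh = split(self.k_proj(k), lk)
        vh = split(self.v_proj(v), lk)
        att = (qh @ kh.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.dh))
        att = att.softmax(axis=-1)
        out = (att @ vh).transpose(0, 2, 1, 3).reshape(n, lq, self.dim)
        return self.out_proj(out)


class DeformableAttention(Module):
    """Multi-scale deformable attention.

    For each query and head, predicts ``points`` sampling offsets and a
    softmax-normalized weight per (level, point); value maps are bilinearly
    sampled at reference + offset (offsets expressed in normalized units of
    each level's grid), with zero padding outside the map.
    """

    def __init__(self, dim: int, heads: int, levels: int, points: int, rng):
        super().__init__()
        self.dim, self.heads, self.levels, self.points = dim, heads, levels, points
        self.dh = dim // heads
        self.value_proj = Linear(dim, dim, rng)
        self.offset_proj = Linear(dim, heads * levels * points * 2, rng)
        # start with zero offsets: sampling begins exactly at the reference
        self.offset_proj.weight.data[:] = 0.0
        self.attn_proj = Linear(dim, heads * levels * points, rng)
        self.out_proj = Linear(dim, dim, rng)

    def forward(self, queries: Tensor, reference: np.ndarray,
                memory: Tensor, shapes: list) -> Tensor:
        """queries (N,Q,D); reference (N,Q,2) normalized (cx, cy);
        memory (N,L,D) flattened multi-scale value tokens; shapes [(H,W)]."""
        n, q, _ = queries.shape
        hd, lv, pt, dh = self.heads, self.levels, self.points, self.dh
        values = self.value_proj(memory).reshape(n, memory.shape[1], hd, dh)
        offsets = self.offset_proj(queries).reshape(n, q, hd, lv, pt, 2)
        attn = self.attn_proj(queries).reshape(n, q, hd, lv * pt) \
            .softmax(axis=-1).reshape(n, q, hd, lv, pt)
        ref = np.ascontiguousarray(np.asarray(reference, dtype=np.float32)) \
            .reshape(n, q, 1, 1, 1, 2)
        norms = np.array([[wid, hgt] for hgt, wid in shapes],
                         dtype=np.float32).reshape(1, 1, 1, lv, 1, 2)
        loc = Tensor(ref) + offsets / Tensor(norms)   # normalized per level
        out = _deform_sample(values, loc, attn, shapes)
        return self.out_proj(out.reshape(n, q, self.dim))


def _deform_sample(values: Tensor, loc: Tensor, attn: Tensor,
                   shapes: list) -> Tensor:
    """Fused multi-scale bilinear sampling + attention-weighted sum.

    values (N, L, heads, dh) flattened level-concatenated value maps;
    loc (N, Q, heads, levels, points, 2) normalized sampling locations;
    attn (N, Q, heads, levels, points) weights summing to 1 per query-head.
    Returns (N, Q, heads, dh).  Samples outside a map contribute zero.
    Implemented as one autograd primitive with a hand-written adjoint for
    values, locations and weights.
    """
    n, q, hd, lv, pt, _ = loc.shape
    ln = values.shape[1]
    dh = values.shape[-1]
    starts = np.cumsum([0] + [h * w for h, w in shapes])
    # flat row index into values viewed as (N*L*heads, dh)
    base = (np.arange(n).reshape(n, 1, 1, 1) * ln * hd
            + np.arange(hd).reshape(1, 1, hd, 1)).astype(np.int64)
    out_data = np.zeros((n, q, hd, dh), dtype=np.float32)
    ctx = []   # per level: (corners, sampled, fx, fy, hgt, wid)
    v2d = values.data.reshape(n * ln * hd, dh)
    for l, (hgt, wid) in enumerate(shapes):
        px = loc.data[:, :, :, l, :, 0] * wid - 0.5    # (N, Q, hd, pt)
        py = loc.data[:, :, :, l, :, 1] * hgt - 0.5
        x0 = np.floor(px).astype(np.int64)
        y0 = np.floor(py).astype(np.int64)
        fx = (px - x0).astype(np.float32)
        fy = (py - y0).astype(np.float32)
        corners = []
        sampled = np.zeros((n, q, hd, pt, dh), dtype=np.float32)
        for dx, dy in ((0, 0), (1, 0), (0, 1), (1, 1)):
            xi, yi = x0 + dx, y0 + dy
            inb = ((xi >= 0) & (xi < wid) & (yi >= 0) & (yi < hgt)) \
                .astype(np.float32)
            cell = starts[l] + np.clip(yi, 0, hgt - 1) * wid \
                + np.clip(xi, 0, wid - 1)
            flat = base + cell * hd                    # (N, Q, hd, pt)
            wx = fx if dx else 1.0 - fx
            wy = fy if dy else 1.0 - fy
            w = wx * wy * inb
            vals = v2d.take(flat.ravel(), axis=0) \
                .reshape(n, q, hd, pt, dh)
            sampled += vals * w[..., None]
            corners.append((flat, w, inb, vals, dx, dy))
        out_data += np.einsum("nqhpd,nqhp->nqhd", sampled,
                              attn.data[:, :, :, l, :], optimize=True)
        ctx.append((corners, sampled, fx, fy, hgt, wid))

    def backward(g):
        # g: (N, Q, hd, dh)
        lgrad = np.zeros(loc.shape, dtype=np.float32) if loc.requires_grad else None
        agrad = np.zeros(attn.shape, dtype=np.float32) if attn.requires_grad else None
        scat_idx, scat_val = [], []
        for l, (corners, sampled, fx, fy, hgt, wid) in enumerate(ctx):
            a_l = attn.data[:, :, :, l, :]
            if agrad is not None:
                agrad[:, :, :, l, :] = np.einsum(
                    "nqhd,nqhpd->nqhp", g, sampled, optimize=True)
            d_sampled = a_l[..., None] * g[:, :, :, None, :]
            dfx = np.zeros_like(fx)
            dfy = np.zeros_like(fy)
            for flat, w, inb, vals, dx, dy in corners:
                if values.requires_grad:
                    scat_idx.append(flat.ravel())
                    scat_val.append((d_sampled * w[..., None])
                                    .reshape(-1, dh))
                dw = np.einsum("nqhpd,nqhpd->nqhp", d_sampled, vals,
                               optimize=True) * inb
                wx = fx if dx else 1.0 - fx
                wy = fy if dy else 1.0 - fy
                dfx += dw * wy * (1.0 if dx else -1.0)
                dfy += dw * wx * (1.0 if dy else -1.0)
            if lgrad is not None:
                lgrad[:, :, :, l, :, 0] = dfx * wid
                lgrad[:, :, :, l, :, 1] = dfy * hgt
        if values.requires_grad:
            all_idx = np.concatenate(scat_idx)
            all_val = np.concatenate(scat_val)
            nrow = n * ln * hd
            vgrad = np.empty((nrow, dh), dtype=np.float32)
            for d in range(dh):
                vgrad[:, d] = np.bincount(all_idx, weights=all_val[:, d],
                                          minlength=nrow)
            values._accum(vgrad.reshape(values.shape))
        if lgrad is not None:
            loc._accum(lgrad)
        if agrad is not None:
            attn._accum(agrad)

    return Tensor._make(out_data, (values, loc, attn), backward)


# ---------------------------------------------------------------------------
# Transformer blocks
# ---------------------------------------------------------------------------

class _FFNBlock(Module):
    def __init__(self, dim, hidden, rng):
        super().__init__()
        self.lin1 = Linear(dim, hidden, rng)
        self.lin2 = Linear(hidden, dim, rng)

    def forward(self, x):
        return self.lin2(self.lin1(x).relu())


class EncoderLayer(Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.attn = DeformableAttention(cfg.hidden_dim, cfg.heads, 4,
                                        cfg.deformable_points, rng)
        self.norm1 = LayerNorm(cfg.hidden_dim)
        self.ffn = _FFNBlock(cfg.hidden_dim, cfg.ffn_hidden_dim, rng)
        self.norm2 = LayerNorm(cfg.hidden_dim)

    def forward(self, tokens, pos, reference, shapes):
        q = tokens + pos
        tokens = self.norm1(tokens + self.attn(q, reference, tokens, shapes))
        return self.norm2(tokens + self.ffn(tokens))


class DecoderLayer(Module):
    def __init__(self, cfg: ModelConfig, rng):
        super().__init__()
        self.self_attn = MultiheadAttention(cfg.hidden_dim, cfg.heads, rng)
        self.norm1 = LayerNorm(cfg.hidden_dim)
        self.cross_attn = DeformableAttention(cfg.hidden_dim, cfg.heads, 4,
                                              cfg.deformable_points, rng)
        self.norm2 = LayerNorm(cfg.hidden_dim)
        self.ffn = _FFNBlock(cfg.hidden_dim, cfg.ffn_hidden_dim, rng)
        self.norm3 = LayerNorm(cfg.hidden_dim)

    def forward(self, queries, qpos, reference, memory, shapes):
        q = queries + qpos
        queries = self.norm1(queries + self.self_attn(q, q, queries))
        queries = self.norm2(
            queries + self.cross_attn(queries + qpos, reference, memory, shapes)
        )
        return self.norm3(queries + self.ffn(queries))


class FFNHead(Module):
    """Detection head: 3-layer MLP -> 4 box offsets; linear -> class logits."""

    def __init__(self, cfg: ModelConfig, rng, class_prior: float = 0.01):
        super().__init__()
        self.box_mlp = MLP(cfg.hidden_dim, cfg.hidden_dim, 4, 3, rng)
        # zero the last MLP layer so refinement starts at the identity
        last = self.box_mlp._modules[f"lin{self.box_mlp.n_layers - 1}"]
        last.weight.data[:] = 0.0
        last.bias.data[:] = 0.0
        self.cls = Linear(cfg.hidden_dim, cfg.num_classes, rng)
        self.cls.bias.data[:] = math.log(class_prior / (1 - class_prior))

    def forward(self, x: Tensor):
        return self.box_mlp(x), self.cls(x)


# ---------------------------------------------------------------------------
# The detector
# ---------------------------------------------------------------------------

class WaveletDetector(Module):
    """Backbone + WTP projection + deformable encoder/decoder + M+1 heads."""

    def __init__(self, config: ModelConfig, seed: int = 0,
                 backbone: Module | None = None):
        super().__init__()
        rng = np.random.default_rng(seed)
        self.config = config
        self.backbone = backbone or TinyBackbone(config.backbone_channels, rng)
        d = config.hidden_dim
        for l, c in enumerate(self.backbone.channels):
            bound = 1.0 / math.sqrt(c)
            self._parameters[f"proj_w{l}"] = Parameter(
                rng.uniform(-bound, bound, (d, c, 1, 1)))
            self._parameters[f"proj_b{l}"] = Parameter(np.zeros(d))
        if config.use_wtp:
            n_wtp = 1 if config.wtp.share_across_scales else 4
            for i in range(n_wtp):
                self._modules[f"wtp{i}"] = WaveletProjection(d, config.wtp, rng)
        else:
            # ablation: plain kernel-3 dense convolution block per scale
            bound = 1.0 / math.sqrt(d * 9)
            for l in range(4):
                self._parameters[f"nowtp_w{l}"] = Parameter(
                    rng.uniform(-bound, bound, (d, d, 3, 3)))
                self._parameters[f"nowtp_b{l}"] = Parameter(np.zeros(d))
        self.level_embed = Parameter(rng.normal(0, 0.02, (4, d)))
        for i in range(config.encoder_layers):
            self._modules[f"enc{i}"] = EncoderLayer(config, rng)
        for i in range(config.decoder_layers):
            self._modules[f"dec{i}"] = DecoderLayer(config, rng)
        for i in range(config.decoder_layers + 1):
            self._modules[f"head{i}"] = FFNHead(config, rng)

    # -- stages --------------------------------------------------------------
    def head(self, i: int) -> FFNHead:
        return self._modules[f"head{i}"]

    def project(self, pyramid: FeaturePyramid) -> ContentEncoding:
        cfg = self.config
        tokens, levels, positions, shapes = [], [], [], []
        for l, fmap in enumerate(pyramid.maps):
            x = conv2d(fmap, self._parameters[f"proj_w{l}"],
                       self._parameters[f"proj_b{l}"])
            if cfg.use_wtp:
                wtp = self._modules["wtp0" if cfg.wtp.share_across_scales
                                    else f"wtp{l}"]
                x = wtp(x)
            else:
                x = conv2d(x, self._parameters[f"nowtp_w{l}"],
                           self._parameters[f"nowtp_b{l}"], padding=1)
            n, d, hgt, wid = x.shape
            shapes.append((hgt, wid))
            tokens.append(x.reshape(n, d, hgt * wid).transpose(0, 2, 1))
            levels.append(np.full(hgt * wid, l))
            ys, xs = np.meshgrid(np.arange(hgt), np.arange(wid), indexing="ij")
            positions.append(np.stack(
                [(xs.ravel() + 0.5) / wid, (ys.ravel() + 0.5) / hgt], axis=-1))
        level_index = np.concatenate(levels)
        positions = np.concatenate(positions).astype(np.float32)
        pos = sinusoidal_position_encoding(positions, self.config.hidden_dim)
        return ContentEncoding(tokens=concat(tokens, axis=1), pos=pos,
                               level_index=level_index, positions=positions,
                               shapes=shapes)

    def encode(self, content: ContentEncoding) -> Tensor:
        tokens = content.tokens
        n = tokens.shape[0]
        pos = Tensor(content.pos[None]) + self.level_embed[content.level_index]
        ref = np.broadcast_to(content.positions[None], (n, *content.positions.shape))
        for i in range(self.config.encoder_layers):
            tokens = self._modules[f"enc{i}"](tokens, pos, ref, content.shapes)
        return tokens

    def _anchors(self, content: ContentEncoding) -> np.ndarray:
        """One anchor per token: its center, base size 0.05 * 2**level,
        inverse-sigmoid transformed (the uniform grid prior)."""
        sizes = (self.config.anchor_base_size
                 * 2.0 ** content.level_index)[:, None]
        anchors = np.concatenate(
            [content.positions, np.repeat(sizes, 2, axis=1)], axis=-1)
        return inverse_sigmoid(anchors)

    def select_topk(self, refined: Tensor, content: ContentEncoding):
        """Encoder head + confidence-ranked top-K proposal selection."""
        k = self.config.num_queries
        n, ln, d = refined.shape
        if ln < k:
            raise ValueError(
                f"token count {ln} < K={k}; use a larger image or smaller K"
            )
        delta, logits = self.head(0)(refined)
        anchors = Tensor(np.broadcast_to(self._anchors(content)[None],
                                         (n, ln, 4)).copy())
        box_logits = anchors + delta
        scores = logits.data.max(axis=-1)          # max-class confidence
        order = np.argsort(-scores, axis=1, kind="stable")[:, :k]
        nidx = np.arange(n)[:, None]
        sel_content = refined[nidx, order].detach()
        sel_box_logits = box_logits[nidx, order]
        sel_logits = logits[nidx, order]
        enc_pred = LayerPredictions(boxes=sel_box_logits.sigmoid(),
                                    class_logits=sel_logits, layer_index=0)
        return sel_content, sel_box_logits.detach(), enc_pred

    def decode(self, queries: Tensor, box_logits: Tensor, memory: Tensor,
               content: ContentEncoding) -> list:
        """Iterative refinement; returns LayerPredictions for layers 1..M."""
        cfg = self.config
        outputs = []
        prev_detached = box_logits                # input to this layer (const)
        prev_undetached = box_logits              # one-step-back undetached
        for i in range(cfg.decoder_layers):
            ref_sig = 1.0 / (1.0 + np.exp(-prev_detached.data))
            qpos = Tensor(sinusoidal_position_encoding(ref_sig, cfg.hidden_dim))
            layer = self._modules[f"dec{i}"]
            queries = layer(queries, qpos, ref_sig[..., :2], memory,
                            content.shapes)
            delta, logits = self.head(i + 1)(queries)
            report_logits = prev_undetached + delta      # look forward twice
            prev_undetached = prev_detached + delta
            prev_detached = prev_undetached.detach()
            outputs.append(LayerPredictions(boxes=report_logits.sigmoid(),
                                            class_logits=logits,
                                            layer_index=i + 1))
        return outputs

    # -- end-to-end ----------------------------------------------------------
    def forward(self, images) -> list:
        """Full forward pass -> M+1 LayerPredictions (index 0 = encoder head),
        each holding batched (N, K, .) boxes and logits."""
        pyramid = extract_features(images, self.backbone)
        content = self.project(pyramid)
        refined = self.encode(content)
        queries, box_logits, enc_pred = self.select_topk(refined, content)
        dec_preds = self.decode(queries, box_logits, refined, content)
        return [enc_pred] + dec_preds

    def predict(self, image, threshold: float | None = None,
                image_id: int = 0) -> list:
        """Final-layer detections above the confidence threshold, rescaled to
        original pixel coordinates.  No NMS."""
        threshold = (self.config.score_threshold if threshold is None
                     else threshold)
        if isinstance(image, ImageTensor):
            h, w = image.original_size
            arr = image.data[None]
        else:
            arr = np.asarray(image, dtype=np.float32)
            if arr.ndim == 3:
                arr = arr[None]
            h, w = arr.shape[-2:]
        with no_grad():
            layers = self.forward(Tensor(arr))
        final = layers[-1]
        boxes = final.boxes.data[0]                       # (K, 4) cxcywh
        probs = 1.0 / (1.0 + np.exp(-final.class_logits.data[0]))
        cats = probs.argmax(axis=-1)
        scores = probs.max(axis=-1)
        records = []
        for q in range(len(boxes)):
            if scores[q] > threshold:
                cx, cy, bw, bh = boxes[q]
                records.append(DetectionRecord(
                    image_id=image_id, category_id=int(cats[q]),
                    bbox=[float((cx - bw / 2) * w), float((cy - bh / 2) * h),
                          float(bw * w), float(bh * h)],
                    score=float(scores[q])))
        records.sort(key=lambda r: -r.score)
        return records


def perturb_parameters(model: Module, fraction: float, seed: int) -> Module:
    """Add elementwise Gaussian noise of sd = fraction * |parameter| to every
    trainable parameter (frozen buffers, e.g. fixed wavelet analysis filters,
    are exempt).  Reproducible under ``seed``; returns the model."""
    if fraction < 0:
        raise ValueError("fraction must be >= 0")
    if fraction == 0:
        return model
    rng = np.random.default_rng(seed)
    for _, p in model.named_parameters():
        noise = rng.standard_normal(p.data.shape).astype(np.float32)
        p.data += fraction * np.abs(p.data) * noise
    return model
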