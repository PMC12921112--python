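"""Haar wavelet-transform projection (WTP) neck.

A single WTP level splits a feature map into four half-resolution subbands
(LL/LH/HL/HH) with the fixed 2x2 orthonormal Haar analysis bank, passes each
subband through its own depthwise learnable convolution, and maps the result
back to full resolution with a *separately parameterized* synthesis bank
(transposed convolution).  The module output is the residual fusion

    F' = F_conv(F) + IWT(F'_conv(WT(F)))

For multi-level operation the transform recurses on the LL band: the deeper
level's output replaces the LL band before each synthesis step.  All
convolutions are depthwise (per-channel): the wavelet filters never mix
channels, so channel count is preserved at every stage.

Four trainability modes control which filter banks receive gradients:

    NO   both banks frozen at the Haar initialization
    WT   analysis learnable, synthesis frozen
    IWT  analysis frozen, synthesis learnable   (default)
    ALL  both learnable
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autograd import Tensor
from .nn import Module, Parameter, depthwise_conv2d

__all__ = [
    "LEARNABLE_MODES",
    "haar_filters",
    "HaarFilterBank",
    "SubbandSet",
    "WTPConfig",
    "haar_decompose",
    "haar_reconstruct",
    "wtp_forward",
    "build_trainability",
    "WaveletProjection",
]

LEARNABLE_MODES = ("NO", "WT", "IWT", "ALL")

BAND_NAMES = ("ll", "lh", "hl", "hh")


class ShapeError(ValueError):
    pass


class ConfigError(ValueError):
    pass


def haar_filters() -> np.ndarray:
    """The 2x2 orthonormal Haar bank, shape (4, 2, 2), order LL, LH, HL, HH.

    LL is the 2-D average; LH is horizontally high-pass (column difference);
    HL is vertically high-pass (row difference); HH is diagonal.  Each filter
    has unit Frobenius norm and the four are mutually orthogonal.
    """
    h = 0.5
    return np.array(
        [
            [[h, h], [h, h]],     # LL
            [[h, -h], [h, -h]],   # LH
            [[h, h], [-h, -h]],   # HL
            [[h, -h], [-h, h]],   # HH
        ],
        dtype=np.float32,
    )


@dataclass
class WTPConfig:
    """Configuration of the wavelet projection.

    levels: number of recursive Haar decompositions of the LL band (>= 1).
    kernel_size: odd kernel size of the depthwise learnable convolutions.
    learnable_mode: which filter banks train -- one of NO / WT / IWT / ALL.
    share_across_scales: reuse one set of WTP weights for all pyramid scales.
    """

    levels: int = 2
    kernel_size: int = 5
    learnable_mode: str = "IWT"
    share_across_scales: bool = False

    def __post_init__(self):
        if self.levels < 1:
            raise ConfigError(f"levels must be >= 1, got {self.levels}")
        if self.kernel_size % 2 != 1:
            raise ConfigError(f"kernel_size must be odd, got {self.kernel_size}")
        if self.learnable_mode not in LEARNABLE_MODES:
            raise ConfigError(
                f"learnable_mode must be one of {LEARNABLE_MODES}, "
                f"got {self.learnable_mode!r}"
            )


class HaarFilterBank(Module):
    """Analysis + synthesis filter banks, each of shape (4, 2, 2).

    Both banks start at the exact Haar initialization; ``analysis_trainable``
    and ``synthesis_trainable`` decide whether each is a trainable parameter
    or a frozen buffer.
    """

    def __init__(self, analysis_trainable: bool = False,
                 synthesis_trainable: bool = True):
        super().__init__()
        self.analysis_trainable = analysis_trainable
        self.synthesis_trainable = synthesis_trainable
        init = haar_filters()
        if analysis_trainable:
            self.analysis = Parameter(init.copy())
        else:
            self.register_buffer("analysis", Tensor(init.copy()))
        if synthesis_trainable:
            self.synthesis = Parameter(init.copy())
        else:
            self.register_buffer("synthesis", Tensor(init.copy()))

    @classmethod
    def from_mode(cls, mode: str) -> "HaarFilterBank":
        if mode not in LEARNABLE_MODES:
            raise ConfigError(f"unknown learnable mode {mode!r}")
        return cls(analysis_trainable=mode in ("WT", "ALL"),
                   synthesis_trainable=mode in ("IWT", "ALL"))


@dataclass
class SubbandSet:
    """The four Haar subbands of one feature map at one decomposition level."""

    ll: Tensor
    lh: Tensor
    hl: Tensor
    hh: Tensor
    level: int = 1

    def bands(self):
        return (self.ll, self.lh, self.hl, self.hh)

    def __post_init__(self):
        shapes = {b.shape for b in self.bands()}
        if len(shapes) != 1:
            raise ShapeError(f"subband shape mismatch: {sorted(shapes)}")


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def haar_decompose(feature, bank: HaarFilterBank | None = None,
                   level: int = 1) -> SubbandSet:
    """Stride-2 depthwise cross-correlation with the four analysis filters.

    ``feature`` has shape (..., H, W) with H, W even (any leading axes; the
    transform never mixes them).  Each output subband has spatial dims
    (H/2, W/2).
    """
    bank = bank if bank is not None else HaarFilterBank.from_mode("NO")
    x = _as_tensor(feature)
    *lead, h, w = x.shape
    if h % 2 or w % 2:
        raise ShapeError(
            f"haar_decompose requires even spatial dims, got {h}x{w} "
            f"(level {level})"
        )
    blocks = x.reshape(*lead, h // 2, 2, w // 2, 2)
    outs = []
    for k in range(4):
        f = bank.analysis[k].reshape(2, 1, 2)        # aligns to axes (-3,-1)
        outs.append((blocks * f).sum(axis=(-3, -1)))
    return SubbandSet(*outs, level=level)


def haar_reconstruct(subbands: SubbandSet, bank: HaarFilterBank | None = None) -> Tensor:
    """Stride-2 depthwise transposed convolution with the synthesis filters,
    summed over the four bands.  Output spatial dims double the subbands'."""
    bank = bank if bank is not None else HaarFilterBank.from_mode("NO")
    *lead, h2, w2 = subbands.ll.shape
    acc = None
    for k, band in enumerate(subbands.bands()):
        f = bank.synthesis[k].reshape(2, 1, 2)
        term = band.reshape(*lead, h2, 1, w2, 1) * f  # (..., h2, 2, w2, 2)
        acc = term if acc is None else acc + term
    return acc.reshape(*lead, 2 * h2, 2 * w2)


def build_trainability(config: WTPConfig, bank: HaarFilterBank) -> dict:
    """Re-register the bank's filters so that exactly the banks selected by
    ``config.learnable_mode`` are trainable parameters; the rest become
    frozen buffers.  Returns the resulting contract."""
    want_a = config.learnable_mode in ("WT", "ALL")
    want_s = config.learnable_mode in ("IWT", "ALL")
    for name, want in (("analysis", want_a), ("synthesis", want_s)):
        current = getattr(bank, name)
        bank._parameters.pop(name, None)
        bank._buffers.pop(name, None)
        if want:
            setattr(bank, name, Parameter(current.data.copy()))
        else:
            bank.register_buffer(name, Tensor(current.data.copy()))
    bank.analysis_trainable = want_a
    bank.synthesis_trainable = want_s
    return {"analysis_trainable": want_a, "synthesis_trainable": want_s}


def _replicate_pad_lr(x: Tensor, pad_b: int, pad_r: int) -> Tensor:
    """Edge-replicate pad on the bottom/right of the last two axes."""
    if pad_b == 0 and pad_r == 0:
        return x
    h, w = x.shape[-2], x.shape[-1]
    ridx = np.concatenate([np.arange(h), np.full(pad_b, h - 1)])
    cidx = np.concatenate([np.arange(w), np.full(pad_r, w - 1)])
    nd = x.ndim
    sl_r = (slice(None),) * (nd - 2) + (ridx,)
    x = x[sl_r]
    sl_c = (slice(None),) * (nd - 1) + (cidx,)
    return x[sl_c]


class WaveletProjection(Module):
    """The full multi-level WTP block for one feature map of C channels.

    Owns: one HaarFilterBank per level, one depthwise kernel-k identity-path
    convolution (``f_conv``), and four depthwise kernel-k subband convolutions
    per level.  Learnable convolutions are initialized at the identity
    (unit-impulse kernels), so an untrained block computes F + IWT(WT(F)) = 2F
    and the residual path starts as a faithful copy of its input.
    """

    def __init__(self, channels: int, config: WTPConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        self.config = config
        k = config.kernel_size
        for lvl in range(config.levels):
            self._modules[f"bank{lvl}"] = HaarFilterBank.from_mode(config.learnable_mode)
        self.f_conv = Parameter(self._impulse(channels, k))
        for lvl in range(config.levels):
            for b in BAND_NAMES:
                self._parameters[f"band_conv{lvl}_{b}"] = Parameter(
                    self._impulse(channels, k)
                )

    @staticmethod
    def _impulse(channels: int, k: int) -> np.ndarray:
        w = np.zeros((channels, k, k), dtype=np.float32)
        w[:, k // 2, k // 2] = 1.0
        return w

    def bank(self, level: int) -> HaarFilterBank:
        return self._modules[f"bank{level}"]

    def _band_conv(self, level: int, name: str, x: Tensor) -> Tensor:
        w = self._parameters[f"band_conv{level}_{name}"]
        return depthwise_conv2d(x, w, padding=self.config.kernel_size // 2)

    def _level_forward(self, x: Tensor, lvl: int) -> Tensor:
        h, w = x.shape[-2], x.shape[-1]
        if h % 2 or w % 2:
            raise ShapeError(
                f"WTP level {lvl}: spatial dims {h}x{w} not divisible by 2"
            )
        sub = haar_decompose(x, self.bank(lvl), level=lvl + 1)
        conved = [self._band_conv(lvl, name, b)
                  for name, b in zip(BAND_NAMES, sub.bands())]
        if lvl + 1 < self.config.levels:
            conved[0] = self._level_forward(conved[0], lvl + 1)
        return haar_reconstruct(SubbandSet(*conved, level=lvl + 1), self.bank(lvl))

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, C, H, W) -> (N, C, H, W).  Odd dims are edge-replicated up
        to the next multiple of 2**levels before the transform and cropped
        back afterwards."""
        x = _as_tensor(x)
        if x.ndim == 3:
            return self.forward(x.reshape(1, *x.shape)).reshape(x.shape)
        n, c, h, w = x.shape
        if c != self.channels:
            raise ShapeError(f"expected {self.channels} channels, got {c}")
        mult = 2 ** self.config.levels
        pad_b = (-h) % mult
        pad_r = (-w) % mult
        xp = _replicate_pad_lr(x, pad_b, pad_r)
        ident = depthwise_conv2d(xp, self.f_conv,
                                 padding=self.config.kernel_size // 2)
        out = ident + self._level_forward(xp, 0)
        if pad_b or pad_r:
            out = out[:, :, :h, :w]
        return out


def wtp_forward(feature, config: WTPConfig, params: WaveletProjection) -> Tensor:
    """Functional entry point: apply a WaveletProjection to one feature map."""
    if not isinstance(params, WaveletProjection):
        raise TypeError("params must be a WaveletProjection module")
    if params.config.learnable_mode not in LEARNABLE_MODES:
        raise ConfigError(f"unknown learnable mode {params.config.learnable_mode!r}")
    return params(_as_tensor(feature))
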