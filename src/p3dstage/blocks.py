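"""Decoupled spatio-temporal convolution operators and pseudo-3D residual blocks.

A dense ``T×S×S`` video kernel is factorized into a spatial ``1×S×S``
convolution (a 2-D CNN applied frame-wise) and a temporal ``T×1×1``
convolution (a 1-D CNN along the frame axis).  The two operators are combined
inside a bottleneck residual unit ``H(x) = F(x) + x`` in one of three
topologies:

=======  =======================  ==========================================
variant  core                     reading
=======  =======================  ==========================================
A        ``T(S(u))``              serial: spatial then temporal
B        ``S(u) + T(u)``          parallel branches, summed
C        ``S(u) + T(S(u))``       serial-parallel: spatial output re-used
=======  =======================  ==========================================

Both operators may be dilated: a kernel of ``k`` taps at dilation rate ``r``
covers an equivalent dense extent ``K = r·(k−1) + 1`` without additional
parameters, so the receptive field grows while the feature resolution is
preserved (stride 1 with same-padding ``r·(k−1)/2``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .errors import InvalidArgumentError, ShapeError

__all__ = [
    "VARIANTS",
    "DilationSpec",
    "ConvSpec",
    "BlockConfig",
    "P3DBlock",
    "effective_kernel_size",
    "same_padding",
    "apply_conv",
    "block_forward",
    "count_block_params",
]

VARIANTS = ("A", "B", "C")


def effective_kernel_size(k: int, r: int) -> int:
    """Equivalent dense kernel extent of ``k`` taps at dilation rate ``r``.

    ``K = r·(k−1) + 1``: dilation spreads the taps ``r`` apart, inserting
    ``r−1`` holes between neighbours, so ``r = 1`` recovers the dense kernel
    and a pointwise kernel (``k = 1``) is unaffected by any rate.
    """
    k, r = int(k), int(r)
    if k < 1 or k % 2 == 0:
        raise InvalidArgumentError(f"kernel extent must be odd and >= 1, got k={k}")
    if r < 1:
        raise InvalidArgumentError(f"dilation rate must be >= 1, got r={r}")
    return r * (k - 1) + 1


def same_padding(k: int, r: int = 1) -> int:
    """Per-side zero padding that preserves the axis extent at stride 1.

    Equals ``(K − 1)/2 = r·(k−1)/2``; defined only for odd ``k`` (no symmetric
    same-padding exists for even kernels).
    """
    return (effective_kernel_size(k, r) - 1) // 2


@dataclass(frozen=True)
class DilationSpec:
    """A dilated kernel axis: ``k`` taps at rate ``r`` covering ``K`` cells."""

    k: int
    r: int = 1

    def __post_init__(self):
        effective_kernel_size(self.k, self.r)  # validates

    @property
    def K(self) -> int:
        return effective_kernel_size(self.k, self.r)

    @property
    def padding(self) -> int:
        return same_padding(self.k, self.r)


@dataclass(frozen=True)
class ConvSpec:
    """Declarative description of one decoupled convolution.

    ``axis_role`` constrains the kernel: a spatial conv has extent 1 on the
    time axis (``1×k×k``), a temporal conv has extent 1 on both image axes
    (``k×1×1``) and a pointwise conv is ``1×1×1``.  Spatial convs therefore
    never mix information across frames and temporal convs never mix across
    pixels.
    """

    axis_role: str
    in_channels: int
    out_channels: int
    kernel: tuple[int, int, int]
    dilation: tuple[int, int, int] = (1, 1, 1)
    stride: tuple[int, int, int] = (1, 1, 1)
    padding: tuple[int, int, int] = (0, 0, 0)
    has_bias: bool = False

    def __post_init__(self):
        if self.axis_role not in ("spatial", "temporal", "pointwise"):
            raise InvalidArgumentError(f"unknown axis_role {self.axis_role!r}")
        if self.in_channels < 1 or self.out_channels < 1:
            raise InvalidArgumentError("channel counts must be positive")
        t, h, w = self.kernel
        if self.axis_role == "spatial" and not (t == 1 and h == w):
            raise InvalidArgumentError(
                f"spatial conv requires kernel (1,k,k), got {self.kernel}")
        if self.axis_role == "temporal" and not (h == 1 and w == 1):
            raise InvalidArgumentError(
                f"temporal conv requires kernel (k,1,1), got {self.kernel}")
        if self.axis_role == "pointwise" and self.kernel != (1, 1, 1):
            raise InvalidArgumentError(
                f"pointwise conv requires kernel (1,1,1), got {self.kernel}")

    @classmethod
    def spatial(cls, in_channels, out_channels, k=3, *, r=1, stride=1):
        return cls("spatial", in_channels, out_channels, (1, k, k),
                   dilation=(1, r, r), stride=(1, stride, stride),
                   padding=(0, same_padding(k, r), same_padding(k, r)))

    @classmethod
    def temporal(cls, in_channels, out_channels, k=3, *, r=1, stride=1):
        return cls("temporal", in_channels, out_channels, (k, 1, 1),
                   dilation=(r, 1, 1), stride=(stride, 1, 1),
                   padding=(same_padding(k, r), 0, 0))

    @classmethod
    def pointwise(cls, in_channels, out_channels, *, stride=(1, 1, 1)):
        return cls("pointwise", in_channels, out_channels, (1, 1, 1),
                   stride=tuple(stride))

    def to_module(self, rng=None, init="zeros") -> nn.Conv3d:
        return nn.Conv3d(self.in_channels, self.out_channels, self.kernel,
                         stride=self.stride, dilation=self.dilation,
                         padding=self.padding, bias=self.has_bias,
                         rng=rng, init=init)


def apply_conv(x: np.ndarray, spec: ConvSpec, weights: np.ndarray,
               bias: np.ndarray | None = None) -> np.ndarray:
    """Functional convolution: run ``spec`` with explicit ``weights`` on ``x``."""
    expected = (spec.out_channels, spec.in_channels, *spec.kernel)
    if weights.shape != expected:
        raise ShapeError(f"weights shape {weights.shape} != spec shape {expected}")
    if x.ndim != 5 or x.shape[1] != spec.in_channels:
        raise ShapeError(
            f"input shape {x.shape} incompatible with spec "
            f"(expects (N,{spec.in_channels},T,H,W))")
    conv = spec.to_module()
    conv.weight.data[...] = weights
    if spec.has_bias:
        if bias is None:
            raise InvalidArgumentError("spec.has_bias but no bias given")
        conv.bias.data[...] = bias
    return conv.forward(x)


@dataclass(frozen=True)
class BlockConfig:
    """Full description of one bottleneck pseudo-3D residual block.

    ``planes`` is the bottleneck width ``p``; the block outputs
    ``expansion·p`` channels.  ``include_temporal=False`` drops the temporal
    operator, leaving a plain frame-wise 2-D bottleneck (used in the final
    network stage).  The block stride is applied on the entry pointwise conv
    so that all three variant topologies keep addable branch shapes.
    """

    variant: str
    in_channels: int
    planes: int
    expansion: int = 4
    spatial_dilation: int = 1
    temporal_dilation: int = 1
    stride: tuple[int, int, int] = (1, 1, 1)
    include_temporal: bool = True

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise InvalidArgumentError(
                f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if min(self.in_channels, self.planes, self.expansion) < 1:
            raise InvalidArgumentError("channels/planes/expansion must be positive")

    @property
    def out_channels(self) -> int:
        return self.expansion * self.planes

    @property
    def needs_projection(self) -> bool:
        return self.in_channels != self.out_channels or any(s > 1 for s in self.stride)


class _ConvUnit(nn.Module):
    """conv -> norm -> (optional) activation; all three skippable in linear mode."""

    def __init__(self, spec: ConvSpec, *, rng, activate=True, linear=False):
        self.conv = spec.to_module(rng=rng, init="he")
        self.norm = nn.Identity() if linear else nn.BatchNorm3d(spec.out_channels)
        self.act = nn.ReLU() if (activate and not linear) else nn.Identity()

    def forward(self, x, train=False):
        return self.act.forward(self.norm.forward(self.conv.forward(x, train),
                                                  train), train)

    def backward(self, grad):
        return self.conv.backward(self.norm.backward(self.act.backward(grad)))


class P3DBlock(nn.Module):
    """Bottleneck residual block with a decoupled spatio-temporal core.

    Path: pointwise reduce (carries the block stride) → variant core →
    pointwise expand; output = ReLU(path + identity/projection).  In
    ``linear=True`` mode every normalisation and activation is replaced by the
    identity, exposing the purely linear operator for algebraic testing.
    """

    def __init__(self, cfg: BlockConfig, *, rng: np.random.Generator | None = None,
                 linear: bool = False):
        if rng is None:
            rng = np.random.default_rng(0)
        self.cfg = cfg
        self.linear = linear
        p = cfg.planes
        self.reduce = _ConvUnit(
            ConvSpec.pointwise(cfg.in_channels, p, stride=cfg.stride),
            rng=rng, linear=linear)
        self.spatial = _ConvUnit(
            ConvSpec.spatial(p, p, 3, r=cfg.spatial_dilation),
            rng=rng, linear=linear)
        self.temporal = (
            _ConvUnit(ConvSpec.temporal(p, p, 3, r=cfg.temporal_dilation),
                      rng=rng, linear=linear)
            if cfg.include_temporal else None)
        self.expand = _ConvUnit(
            ConvSpec.pointwise(p, cfg.out_channels),
            rng=rng, activate=False, linear=linear)
        if cfg.needs_projection:
            self.project = _ConvUnit(
                ConvSpec.pointwise(cfg.in_channels, cfg.out_channels,
                                   stride=cfg.stride),
                rng=rng, activate=False, linear=linear)
        else:
            self.project = None
        self.out_act = nn.Identity() if linear else nn.ReLU()

    def forward(self, x, train=False):
        cfg = self.cfg
        if x.shape[1] != cfg.in_channels:
            raise ShapeError(
                f"block expects {cfg.in_channels} channels, got {x.shape}")
        u = self.reduce.forward(x, train)
        s = self.spatial.forward(u, train)
        if self.temporal is None:
            core = s
            self._route = "S"
        elif cfg.variant == "A":
            core = self.temporal.forward(s, train)
            self._route = "A"
        elif cfg.variant == "B":
            t = self.temporal.forward(u, train)
            if t.shape != s.shape:
                raise ShapeError(
                    f"parallel branches disagree: spatial {s.shape} vs temporal {t.shape}")
            core = s + t
            self._route = "B"
        else:  # C
            t = self.temporal.forward(s, train)
            if t.shape != s.shape:
                raise ShapeError(
                    f"parallel branches disagree: spatial {s.shape} vs temporal {t.shape}")
            core = s + t
            self._route = "C"
        y = self.expand.forward(core, train)
        shortcut = x if self.project is None else self.project.forward(x, train)
        return self.out_act.forward(y + shortcut, train)

    def backward(self, grad):
        g = self.out_act.backward(grad)
        g_short = g if self.project is None else self.project.backward(g)
        g_core = self.expand.backward(g)
        route = self._route
        if route == "S":
            gu = self.spatial.backward(g_core)
        elif route == "A":
            gu = self.spatial.backward(self.temporal.backward(g_core))
        elif route == "B":
            gu = self.spatial.backward(g_core) + self.temporal.backward(g_core)
        else:  # C: core = s + T(s)
            gs = g_core + self.temporal.backward(g_core)
            gu = self.spatial.backward(gs)
        gx = self.reduce.backward(gu)
        return gx + g_short


def block_forward(x: np.ndarray, cfg: BlockConfig, params: dict | None = None,
                  *, linear: bool = False, rng=None,
                  train: bool = False) -> np.ndarray:
    """Functional block application; ``params`` is a ``state_dict``-style mapping."""
    block = P3DBlock(cfg, rng=rng, linear=linear)
    if params is not None:
        state = block.state_dict()
        for name, arr in params.items():
            if name not in state:
                raise InvalidArgumentError(f"unknown block parameter {name!r}")
            state[name] = np.asarray(arr, dtype=np.float32)
        block.load_state_dict(state)
    return block.forward(x, train=train)


def count_block_params(cfg: BlockConfig) -> int:
    """Exact trainable-scalar count of a block, in closed form.

    Counts conv weights plus normalisation scale/shift; convolutions carry no
    bias (redundant with the normalisation shift).  Each variant contains
    exactly one spatial and (when enabled) one temporal conv, so the count is
    variant-independent, and dilation never changes it.
    """
    p, e, cin = cfg.planes, cfg.expansion, cfg.in_channels
    total = cin * p + 2 * p          # reduce + norm
    total += 9 * p * p + 2 * p       # spatial 1x3x3 + norm
    if cfg.include_temporal:
        total += 3 * p * p + 2 * p   # temporal 3x1x1 + norm
    total += e * p * p + 2 * e * p   # expand + norm
    if cfg.needs_projection:
        total += cin * e * p + 2 * e * p
    return total
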