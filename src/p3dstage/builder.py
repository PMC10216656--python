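"""Assembly of the full pseudo-3D residual network from a declarative config.

The network follows the classic four-stage bottleneck ResNet plan: a spatial
stem (1×7×7 conv, stride (1,2,2), then a 1×3×3 spatial max-pool), four stages
of bottleneck blocks whose variants cycle A,B,C over the *global* block index,
global average pooling over (T,H,W) and a single affine classification head.
The default layout is the 152-layer-style (3, 8, 36, 3) with widths
64/128/256/512 at expansion 4.  Temporal convolutions are enabled per stage
(default: stages 1–3; the final stage uses frame-wise 2-D bottlenecks), and no
temporal downsampling happens before the global pool, so a 10-frame input
keeps its 10 frames throughout.

Parameter accounting is exact and deterministic: the per-layer inventory is
derived from the configuration alone and always equals the live count of the
instantiated model.  A dense C3D reconstruction is provided as the reference
point for parameter-count comparisons.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn
from .blocks import BlockConfig, P3DBlock, VARIANTS, count_block_params
from .errors import ConfigError, ShapeError

__all__ = [
    "NetworkConfig",
    "ModelHandle",
    "variant_sequence",
    "build_network",
    "count_parameters",
    "build_c3d_reference",
    "summarize",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Complete architectural description; the parameter count is a pure
    function of this object."""

    stage_layout: tuple[int, ...] = (3, 8, 36, 3)
    planes_per_stage: tuple[int, ...] = (64, 128, 256, 512)
    expansion: int = 4
    # an int applies to all stages; a 4-tuple sets the rate per stage
    spatial_dilation: int | tuple[int, ...] = 2
    temporal_dilation: int | tuple[int, ...] = 2
    num_classes: int = 3
    input_shape: tuple[int, int, int, int] = (3, 10, 224, 224)
    stem_channels: int = 64
    stem_kernel: tuple[int, int, int] = (1, 7, 7)
    stem_stride: tuple[int, int, int] = (1, 2, 2)
    stem_pool: tuple[int, int, int] = (1, 3, 3)
    stem_pool_stride: tuple[int, int, int] = (1, 2, 2)
    # first block of stages 2-4 downsamples spatially; no temporal stride
    downsample_schedule: tuple[tuple[int, int, int], ...] = (
        (1, 1, 1), (1, 2, 2), (1, 2, 2), (1, 2, 2))
    # temporal convs per stage; the final stage is spatial-only by default
    temporal_stages: tuple[bool, ...] = (True, True, True, False)

    def __post_init__(self):
        if len(self.stage_layout) != 4 or len(self.planes_per_stage) != 4:
            raise ConfigError("exactly four stages are required")
        if any(n < 1 for n in self.stage_layout):
            raise ConfigError(f"empty stage in layout {self.stage_layout}")
        for a, b in zip(self.planes_per_stage, self.planes_per_stage[1:]):
            if b != 2 * a:
                raise ConfigError(
                    f"stage widths must double, got {self.planes_per_stage}")
        if self.num_classes < 2:
            raise ConfigError("num_classes must be >= 2")
        if self.input_shape[1] < 1:
            raise ConfigError("input must have at least one frame")
        for name in ("spatial_dilation", "temporal_dilation"):
            v = getattr(self, name)
            if isinstance(v, (tuple, list)) and len(v) != 4:
                raise ConfigError(f"{name} must be an int or a 4-tuple, got {v}")

    def dilation_for_stage(self, stage_index: int) -> tuple[int, int]:
        """(spatial, temporal) dilation rate of one stage (0-based)."""
        out = []
        for v in (self.spatial_dilation, self.temporal_dilation):
            out.append(v[stage_index] if isinstance(v, (tuple, list)) else v)
        return tuple(out)

    # -- (de)serialization ------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        def tup(v):
            return tuple(tuple(x) if isinstance(x, (list, tuple)) else x for x in v) \
                if isinstance(v, (list, tuple)) else v
        return cls(**{k: tup(v) for k, v in d.items()})

    @classmethod
    def from_file(cls, path) -> "NetworkConfig":
        text = open(path).read()
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            return cls.from_dict(yaml.safe_load(text))
        return cls.from_dict(json.loads(text))


def variant_sequence(n_blocks: int) -> list[str]:
    """Deterministic A,B,C cycle over the global block index (crosses stage
    boundaries without resetting)."""
    if n_blocks < 1:
        raise ConfigError("need at least one block")
    return [VARIANTS[i % 3] for i in range(n_blocks)]


class _P3DNetwork(nn.Module):
    def __init__(self, cfg: NetworkConfig, rng: np.random.Generator):
        c_in, frames = cfg.input_shape[0], cfg.input_shape[1]
        self.stem_conv = nn.Conv3d(
            c_in, cfg.stem_channels, cfg.stem_kernel, stride=cfg.stem_stride,
            padding=tuple(k // 2 for k in cfg.stem_kernel), rng=rng)
        self.stem_norm = nn.BatchNorm3d(cfg.stem_channels)
        self.stem_act = nn.ReLU()
        self.stem_pool = nn.MaxPool3d(
            cfg.stem_pool, stride=cfg.stem_pool_stride,
            padding=tuple(k // 2 for k in cfg.stem_pool))

        t = frames
        variants = variant_sequence(sum(cfg.stage_layout))
        self.blocks = []
        self.block_configs = []
        gi = 0
        channels = cfg.stem_channels
        for si, (n_blocks, planes) in enumerate(
                zip(cfg.stage_layout, cfg.planes_per_stage)):
            stage_stride = cfg.downsample_schedule[si]
            if stage_stride[0] > 1:
                t_next = (t - 1) // stage_stride[0] + 1
                if t_next == t:  # stride cannot reduce the frame count
                    raise ConfigError(
                        f"stage {si + 1}: temporal stride {stage_stride[0]} "
                        f"has too few frames to act on (had {t})")
                t = t_next
            sdil, tdil = cfg.dilation_for_stage(si)
            for bi in range(n_blocks):
                bcfg = BlockConfig(
                    variant=variants[gi],
                    in_channels=channels,
                    planes=planes,
                    expansion=cfg.expansion,
                    spatial_dilation=sdil,
                    temporal_dilation=tdil,
                    stride=stage_stride if bi == 0 else (1, 1, 1),
                    include_temporal=cfg.temporal_stages[si],
                )
                self.blocks.append(P3DBlock(bcfg, rng=rng))
                self.block_configs.append(bcfg)
                channels = bcfg.out_channels
                gi += 1
        self.pool = nn.GlobalAvgPool()
        self.head = nn.Linear(channels, cfg.num_classes, rng=rng)

    def forward(self, x, train=False):
        x = self.stem_act.forward(
            self.stem_norm.forward(self.stem_conv.forward(x, train), train), train)
        x = self.stem_pool.forward(x, train)
        for block in self.blocks:
            x = block.forward(x, train=train)
        return self.head.forward(self.pool.forward(x, train), train)

    def backward(self, grad):
        grad = self.pool.backward(self.head.backward(grad))
        for block in reversed(self.blocks):
            grad = block.backward(grad)
        grad = self.stem_pool.backward(grad)
        return self.stem_conv.backward(
            self.stem_norm.backward(self.stem_act.backward(grad)))


@dataclass
class ModelHandle:
    """An instantiated network plus its config and per-layer parameter inventory."""

    model: nn.Module
    config: object
    inventory: dict = field(default_factory=dict)
    kind: str = "p3d"

    def forward(self, x, train=False):
        return self.model.forward(x, train=train)

    def predict_scores(self, x):
        return nn.softmax(self.model.forward(np.asarray(x, dtype=np.float32)))


def _inventory(model: nn.Module) -> dict:
    inv = {}
    for name, p in model.named_parameters():
        inv[name] = p.size
    return inv


def build_network(cfg: NetworkConfig | None = None, *, seed: int = 0) -> ModelHandle:
    """Instantiate the full network described by ``cfg`` (default config if None)."""
    cfg = cfg or NetworkConfig()
    rng = np.random.default_rng(seed)
    model = _P3DNetwork(cfg, rng)
    return ModelHandle(model=model, config=cfg, inventory=_inventory(model))


def count_parameters(handle: ModelHandle) -> int:
    """Total trainable scalars; equals the sum of the per-layer inventory."""
    total = handle.model.num_parameters()
    assert total == sum(handle.inventory.values()), "inventory drifted from model"
    return total


# ---------------------------------------------------------------------------
# C3D reference reconstruction (dense 3x3x3 convolutions throughout)
# ---------------------------------------------------------------------------

_C3D_WIDTHS = (64, 128, 256, 256, 512, 512, 512, 512)
_C3D_FLAT = 8192  # 512 channels x 1 x 4 x 4 after five pools on 16x112x112 input


class _C3D(nn.Module):
    """Standard C3D: 8 dense 3×3×3 convs, 5 max-pools, two 4096-wide FC layers.

    Canonical input is (3, 16, 112, 112); the first pool is spatial-only.
    Biases everywhere (no normalisation layers), matching the original design.
    """

    def __init__(self, num_classes: int, rng: np.random.Generator):
        layers = []
        cin = 3
        # conv group sizes: 1,1,2,2,2 with a pool after each group
        plan = [(64,), (128,), (256, 256), (512, 512), (512, 512)]
        for gi, group in enumerate(plan):
            for cout in group:
                layers.append(nn.Conv3d(cin, cout, (3, 3, 3),
                                        padding=(1, 1, 1), bias=True, rng=rng))
                layers.append(nn.ReLU())
                cin = cout
            if gi == 0:
                layers.append(nn.MaxPool3d((1, 2, 2)))
            elif gi == len(plan) - 1:
                # final pool pads spatially so 112x112 inputs land on the
                # canonical 4x4 grid feeding the 8192-wide first FC layer
                layers.append(nn.MaxPool3d((2, 2, 2), padding=(0, 1, 1)))
            else:
                layers.append(nn.MaxPool3d((2, 2, 2)))
        layers.append(nn.Flatten())
        layers.append(nn.Linear(_C3D_FLAT, 4096, rng=rng))
        layers.append(nn.ReLU())
        layers.append(nn.Linear(4096, 4096, rng=rng))
        layers.append(nn.ReLU())
        layers.append(nn.Linear(4096, num_classes, rng=rng))
        self.net = nn.Sequential(*layers)

    def forward(self, x, train=False):
        return self.net.forward(x, train=train)

    def backward(self, grad):
        return self.net.backward(grad)


def build_c3d_reference(num_classes: int = 3, *, seed: int = 0) -> ModelHandle:
    """Dense-3D reference network used for parameter-count comparison."""
    if num_classes < 2:
        raise ConfigError("num_classes must be >= 2")
    rng = np.random.default_rng(seed)
    model = _C3D(num_classes, rng)
    return ModelHandle(model=model, config={"kind": "c3d", "num_classes": num_classes},
                       inventory=_inventory(model), kind="c3d")


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _block_out_shape(bcfg: BlockConfig, shape):
    _, t, h, w = shape
    st, sh, sw = bcfg.stride
    return (bcfg.out_channels, (t - 1) // st + 1, (h - 1) // sh + 1,
            (w - 1) // sw + 1)


def summarize(handle: ModelHandle) -> str:
    """Per-layer text table: name, output shape on the configured input,
    parameter count; the totals row equals :func:`count_parameters`.

    Output shapes are derived by shape arithmetic (no forward pass), so the
    summary is cheap even for the full-size network.
    """
    if handle.kind != "p3d":
        raise ConfigError("summarize supports networks built by build_network")
    cfg: NetworkConfig = handle.config
    model: _P3DNetwork = handle.model
    rows = []
    shape = cfg.input_shape  # (C,T,H,W)
    shape = model.stem_conv.output_shape(shape)
    stem_params = (model.stem_conv.weight.size
                   + model.stem_norm.gamma.size + model.stem_norm.beta.size)
    rows.append(("stem", shape, stem_params))
    shape = model.stem_pool.output_shape(shape)
    rows.append(("stem_pool", shape, 0))
    for i, bcfg in enumerate(model.block_configs):
        shape = _block_out_shape(bcfg, shape)
        rows.append((f"block{i:02d}[{bcfg.variant}]", shape,
                     count_block_params(bcfg)))
    rows.append(("global_pool", (shape[0],), 0))
    head_params = model.head.weight.size + model.head.bias.size
    rows.append((f"head({cfg.num_classes})", (cfg.num_classes,), head_params))
    total = sum(r[2] for r in rows)
    assert total == count_parameters(handle), "summary drifted from live count"

    buf = io.StringIO()
    buf.write(f"{'layer':<16}{'output shape':<22}{'params':>12}\n")
    for name, shp, n in rows:
        buf.write(f"{name:<16}{str(tuple(shp)):<22}{n:>12,}\n")
    buf.write(f"{'total':<16}{'':<22}{total:>12,}\n")
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Checkpoints: npz with the config embedded, so files are self-describing
# ---------------------------------------------------------------------------

def save_checkpoint(handle: ModelHandle, path) -> None:
    state = handle.model.state_dict()
    cfg = (handle.config.to_dict() if isinstance(handle.config, NetworkConfig)
           else handle.config)
    meta = json.dumps({"kind": handle.kind, "config": cfg})
    np.savez_compressed(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
                        **state)


def load_checkpoint(path) -> ModelHandle:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    if meta["kind"] == "p3d":
        handle = build_network(NetworkConfig.from_dict(meta["config"]))
    elif meta["kind"] == "c3d":
        handle = build_c3d_reference(meta["config"]["num_classes"])
    else:
        raise ConfigError(f"unknown checkpoint kind {meta['kind']!r}")
    handle.model.load_state_dict(state)
    return handle
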