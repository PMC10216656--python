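"""From raw angiography sequences to fixed-shape model inputs.

The pipeline mirrors clinical practice for subtraction angiography: pick the
start frame at contrast arrival (manually via a manifest, or with an intensity
heuristic), keep that frame and the following nine (10 frames total), crop the
region of interest and resample it to 224×224, augment with the eight dihedral
views, and split by source id into train/validation/test at 6:2:2 with no
leakage across splits.

Coordinate convention everywhere: 0-based, half-open boxes, row-major
(``top, left, height, width``).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .errors import GeometryError, InvalidArgumentError, WindowError

__all__ = [
    "STAGES",
    "FrameSequence",
    "ROISpec",
    "SplitAssignment",
    "StartFrameSuggestion",
    "suzuki_to_stage",
    "select_window",
    "suggest_start_frame",
    "crop_resize",
    "resize_frames",
    "augment_views",
    "oversample_views",
    "tta_predict",
    "stratified_split",
    "read_frame_directory",
    "read_dicom_sequence",
    "save_sample",
    "load_sample",
    "DIHEDRAL_VIEWS",
]

STAGES = ("mild", "moderate", "severe")
TARGET_SIZE = (224, 224)
WINDOW_LENGTH = 10

#: (rotation quarter-turns, horizontal flip) for the 8 dihedral views;
#: the first entry is the identity.
DIHEDRAL_VIEWS = tuple((k, f) for f in (False, True) for k in (0, 1, 2, 3))


def suzuki_to_stage(suzuki: int) -> str:
    """Map the six angiographic progression stages onto three severity grades:
    1–2 mild, 3–4 moderate, 5–6 severe."""
    if not 1 <= int(suzuki) <= 6:
        raise InvalidArgumentError(f"Suzuki stage must be 1..6, got {suzuki}")
    return STAGES[(int(suzuki) - 1) // 2]


@dataclass(frozen=True)
class FrameSequence:
    """Ordered grayscale frames of one hemisphere's angiography run.

    Frames are a ``(T, H, W)`` float array normalised to [0, 1] on ingest
    (per-sequence min–max).
    """

    frames: np.ndarray
    source_id: str
    label: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        arr = np.asarray(self.frames, dtype=np.float32)
        if arr.ndim != 3 or arr.shape[0] < 1:
            raise InvalidArgumentError(
                f"frames must be (T,H,W) with T>=1, got shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise InvalidArgumentError("frames contain non-finite pixels")
        if self.label is not None and self.label not in STAGES:
            raise InvalidArgumentError(
                f"label must be one of {STAGES}, got {self.label!r}")
        object.__setattr__(self, "frames", arr)

    @classmethod
    def from_raw(cls, frames, source_id, label=None, metadata=None):
        """Ingest raw frames with per-sequence min–max normalisation to [0,1]."""
        arr = np.asarray(frames, dtype=np.float32)
        lo, hi = float(arr.min()), float(arr.max())
        if hi > lo:
            arr = (arr - lo) / (hi - lo)
        else:
            arr = np.zeros_like(arr)
        return cls(arr, source_id, label, metadata or {})

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class ROISpec:
    """Crop box (top, left, height, width), 0-based half-open; target 224×224."""

    top: int
    left: int
    height: int
    width: int
    target: tuple[int, int] = TARGET_SIZE

    def __post_init__(self):
        if self.height < 1 or self.width < 1:
            raise GeometryError(
                f"crop box must be non-empty, got {self.height}x{self.width} "
                f"(0-based, half-open, row-major)")


@dataclass(frozen=True)
class StartFrameSuggestion:
    index: int
    low_confidence: bool = False


def select_window(seq: FrameSequence, start: int,
                  length: int = WINDOW_LENGTH) -> FrameSequence:
    """Take ``length`` consecutive frames from ``start`` (the arrival frame and
    the following ``length−1``); never pads silently."""
    if start < 0:
        raise WindowError(f"start frame must be >= 0, got {start}")
    available = seq.n_frames - start
    if available < length:
        raise WindowError(
            f"need {length} frames from index {start} but only {max(available, 0)} "
            f"remain of {seq.n_frames}")
    return replace(seq, frames=seq.frames[start:start + length])


def suggest_start_frame(seq: FrameSequence) -> StartFrameSuggestion:
    """Heuristic contrast-arrival frame: the index with the largest
    frame-to-frame *decrease* in mean intensity (contrast darkens vessels in
    subtraction images).  Advisory only; a manifest start frame overrides it.
    """
    if seq.n_frames < 2:
        raise InvalidArgumentError("need at least 2 frames")
    means = seq.frames.mean(axis=(1, 2))
    drops = means[:-1] - means[1:]
    if drops.max() <= 0:
        return StartFrameSuggestion(0, low_confidence=True)
    return StartFrameSuggestion(int(drops.argmax()) + 1)


def crop_resize(seq: FrameSequence, roi: ROISpec) -> FrameSequence:
    """Crop every frame with the same box, then bilinearly resample to the
    target size.  Values stay in [0, 1]."""
    h, w = seq.frame_shape
    if (roi.top < 0 or roi.left < 0 or roi.top + roi.height > h
            or roi.left + roi.width > w):
        raise GeometryError(
            f"crop box (top={roi.top}, left={roi.left}, height={roi.height}, "
            f"width={roi.width}; 0-based, half-open, row-major) exceeds frame "
            f"shape {(h, w)}")
    crop = seq.frames[:, roi.top:roi.top + roi.height,
                      roi.left:roi.left + roi.width]
    out = resize_frames(crop, roi.target)
    return replace(seq, frames=out)


def resize_frames(frames: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Bilinear per-frame resampling of a (T,H,W) stack; identity when the
    size already matches."""
    t, h, w = frames.shape
    if (h, w) == tuple(target):
        return frames.copy()
    out = np.empty((t, *target), dtype=np.float32)
    for i in range(t):
        out[i] = _sk_resize(frames[i], target, order=1, mode="edge",
                            anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def _dihedral(frames: np.ndarray, k: int, flip: bool) -> np.ndarray:
    out = np.rot90(frames, k=k, axes=(1, 2))
    if flip:
        out = out[:, :, ::-1]
    return np.ascontiguousarray(out)


def augment_views(seq: FrameSequence) -> list[FrameSequence]:
    """The 8 dihedral views (right-angle rotations × horizontal flip), each
    transform applied identically to all frames; labels unchanged.

    These are the only lossless square-raster symmetries, which is why the
    augmentation set is fixed to this group.
    """
    h, w = seq.frame_shape
    if h != w:
        raise GeometryError(
            f"dihedral views need square frames, got {(h, w)} "
            f"(a quarter-turn would change the shape)")
    views = []
    for k, flip in DIHEDRAL_VIEWS:
        views.append(replace(
            seq,
            frames=_dihedral(seq.frames, k, flip),
            metadata={**seq.metadata, "view": (k, flip)},
        ))
    return views


def tta_predict(model, seq: FrameSequence, *, channels: int | None = None) -> np.ndarray:
    """Test-time augmentation: mean softmax score over the 8 dihedral views.

    ``model`` is any handle exposing ``forward`` on (N,C,T,H,W) batches.  The
    single-channel frame stack is replicated to ``channels`` if the network
    expects more than one input channel.
    """
    views = augment_views(seq)
    batch = np.stack([v.frames for v in views])[:, None]  # (8,1,T,H,W)
    if channels is None:
        channels = _model_channels(model)
    if channels > 1:
        batch = np.repeat(batch, channels, axis=1)
    logits = model.forward(batch.astype(np.float32))
    return nn.softmax(logits).mean(axis=0)


def _model_channels(model) -> int:
    cfg = getattr(model, "config", None)
    shape = getattr(cfg, "input_shape", None)
    return shape[0] if shape else 1


def oversample_views(sequences, target_per_class: int, seed: int = 0):
    """Grow under-represented classes by sampling distinct dihedral views.

    For each class below ``target_per_class``, additional views (never the
    identity, never a duplicate view of the same source) are drawn with the
    seed until the quota is met or the 7 non-identity views per source are
    exhausted.  Returns the original sequences plus the sampled views; view
    provenance stays in ``metadata['view']`` and source ids are preserved so
    split assignment still happens per source.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[FrameSequence]] = {s: [] for s in STAGES}
    for seq in sequences:
        if seq.label is None:
            raise InvalidArgumentError(f"sequence {seq.source_id!r} is unlabeled")
        by_class[seq.label].append(seq)
    out = list(sequences)
    for stage, members in by_class.items():
        if not members:
            continue
        deficit = target_per_class - len(members)
        if deficit <= 0:
            continue
        # (source, view) pairs not yet used; view 0 is the identity
        pool = [(seq, v) for seq in members for v in range(1, 8)]
        rng.shuffle(pool)
        if deficit > len(pool):
            warnings.warn(
                f"class {stage!r}: only {len(pool)} distinct non-identity "
                f"views available, quota {target_per_class} not reached",
                stacklevel=2)
        for seq, v in pool[:deficit]:
            k, flip = DIHEDRAL_VIEWS[v]
            out.append(replace(
                seq, frames=_dihedral(seq.frames, k, flip),
                metadata={**seq.metadata, "view": (k, flip)}))
    return out


@dataclass(frozen=True)
class SplitAssignment:
    """source_id → split mapping; disjoint and exhaustive by construction."""

    assignment: dict
    ratios: tuple[float, float, float]
    seed: int

    def ids(self, split: str) -> list[str]:
        return sorted(k for k, v in self.assignment.items() if v == split)


_SPLITS = ("train", "validation", "test")


def stratified_split(items, ratios=(0.6, 0.2, 0.2), seed: int = 0) -> SplitAssignment:
    """Per-class largest-remainder allocation to train/validation/test.

    ``items`` maps source_id → stage label (or is an iterable of pairs).  Each
    class is shuffled with the seed and allocated by largest-remainder
    rounding, so e.g. class sizes (516, 512, 515) at 6:2:2 give train sizes
    (310, 307, 309).  All augmented views of a source inherit its assignment,
    so no source ever leaks across splits.  A class with fewer than 3 items is
    assigned entirely to train with a warning.
    """
    items = dict(items)
    ratios = tuple(float(r) for r in ratios)
    if len(ratios) != 3 or abs(sum(ratios) - 1.0) > 1e-9:
        raise InvalidArgumentError(f"ratios must be three values summing to 1, got {ratios}")
    for sid, label in items.items():
        if label not in STAGES:
            raise InvalidArgumentError(
                f"item {sid!r} has unknown label {label!r}")
    rng = np.random.default_rng(seed)
    assignment = {}
    for stage in STAGES:
        ids = sorted(sid for sid, lab in items.items() if lab == stage)
        if not ids:
            continue
        if len(ids) < 3:
            warnings.warn(
                f"class {stage!r} has only {len(ids)} items; assigning all to train",
                stacklevel=2)
            for sid in ids:
                assignment[sid] = "train"
            continue
        rng.shuffle(ids)
        n = len(ids)
        quotas = [r * n for r in ratios]
        floors = [int(np.floor(q)) for q in quotas]
        leftover = n - sum(floors)
        # largest remainder; ties broken by split order (train, validation, test)
        order = sorted(range(3), key=lambda j: (-(quotas[j] - floors[j]), j))
        for j in order[:leftover]:
            floors[j] += 1
        start = 0
        for split, count in zip(_SPLITS, floors):
            for sid in ids[start:start + count]:
                assignment[sid] = split
            start += count
    return SplitAssignment(assignment, ratios, int(seed))


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_dicom_sequence(path, source_id=None, label=None) -> FrameSequence:
    """Read a multi-frame DICOM file into a normalised FrameSequence."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float32)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise InvalidArgumentError(
            f"expected grayscale multi-frame DICOM, got pixel array {arr.shape}")
    return FrameSequence.from_raw(arr, source_id or Path(path).stem, label)


def read_frame_directory(manifest_path):
    """Read sequences described by a JSON manifest.

    The manifest is a list of records with ``source_id``, ``label``, ``frames``
    (ordered image paths relative to the manifest), and optional
    ``start_frame`` and ``roi`` ``[top, left, height, width]``.  Returns a list
    of ``(FrameSequence, record)`` pairs; windowing/cropping is left to the
    caller so manual choices stay visible.
    """
    import imageio.v3 as iio

    manifest_path = Path(manifest_path)
    records = json.loads(manifest_path.read_text())
    out = []
    for rec in records:
        frames = np.stack([
            np.asarray(iio.imread(manifest_path.parent / f), dtype=np.float32)
            for f in rec["frames"]
        ])
        if frames.ndim == 4:  # RGB(A) -> luminance
            frames = frames[..., :3].mean(axis=-1)
        seq = FrameSequence.from_raw(frames, rec["source_id"], rec.get("label"))
        out.append((seq, rec))
    return out


def save_sample(path, seq: FrameSequence) -> None:
    """Write one processed sample as a compressed array container (npz)."""
    np.savez_compressed(
        path, frames=seq.frames,
        meta=np.frombuffer(json.dumps({
            "source_id": seq.source_id,
            "label": seq.label,
            "metadata": {k: v for k, v in seq.metadata.items()
                         if isinstance(v, (int, float, str, list, tuple))},
        }).encode(), dtype=np.uint8))


def load_sample(path) -> FrameSequence:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        frames = data["frames"]
    return FrameSequence(frames, meta["source_id"], meta["label"],
                         meta.get("metadata") or {})
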