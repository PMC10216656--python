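"""Windowing, geometry, dihedral augmentation/TTA and stratified splitting."""

import json

import numpy as np
import pytest

from p3dstage import nn
from p3dstage.errors import (GeometryError, InvalidArgumentError, WindowError)
from p3dstage.preprocess import (DIHEDRAL_VIEWS, FrameSequence, ROISpec,
                                 augment_views, crop_resize, load_sample,
                                 read_frame_directory, save_sample,
                                 select_window, stratified_split,
                                 suggest_start_frame, suzuki_to_stage,
                                 tta_predict)


def _seq(frames, sid="s0", label=None):
    return FrameSequence(np.asarray(frames, dtype=np.float32), sid, label)


def _random_seq(rng, t=10, size=16, label="mild"):
    return _seq(rng.random((t, size, size)), label=label)


# ---------------------------------------------------------------------------
# labels and windows
# ---------------------------------------------------------------------------

def test_suzuki_mapping():
    assert [suzuki_to_stage(s) for s in range(1, 7)] == \
        ["mild", "mild", "moderate", "moderate", "severe", "severe"]
    with pytest.raises(InvalidArgumentError):
        suzuki_to_stage(7)


def test_select_window_index_arithmetic(rng):
    seq = _random_seq(rng, t=25)
    win = select_window(seq, 6)
    assert win.n_frames == 10
    assert np.array_equal(win.frames, seq.frames[6:16])
    assert win.source_id == seq.source_id and win.label == seq.label


def test_select_window_identity_and_error(rng):
    seq = _random_seq(rng, t=10)
    assert np.array_equal(select_window(seq, 0).frames, seq.frames)
    with pytest.raises(WindowError, match="7"):
        select_window(_random_seq(rng, t=12), 5)


def test_suggest_start_frame_on_synthetic_arrival():
    from p3dstage.synthdsa import PhantomParams, generate_sample
    params = PhantomParams(trunk_visibility=0.95, stenosis_factor=0.6,
                           cloud_density=10, trunk_arrival=4.0, cloud_arrival=4.0)
    for seed in range(5):
        sample = generate_sample("mild", params, seed)
        assert suggest_start_frame(sample.sequence).index == 4


def test_suggest_start_frame_degenerate_cases():
    flat = _seq(np.full((5, 4, 4), 0.5))
    out = suggest_start_frame(flat)
    assert out.index == 0 and out.low_confidence
    fade_up = _seq(np.linspace(0.1, 0.9, 6)[:, None, None] * np.ones((6, 4, 4)))
    assert suggest_start_frame(fade_up).low_confidence
    two = _seq(np.stack([np.full((4, 4), 0.9), np.full((4, 4), 0.2)]))
    assert suggest_start_frame(two).index == 1


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def test_crop_resize_identity_when_box_matches_target(rng):
    seq = _random_seq(rng, t=3, size=224)
    out = crop_resize(seq, ROISpec(0, 0, 224, 224))
    assert np.max(np.abs(out.frames - seq.frames)) == 0


def test_crop_resize_constant_invariance():
    seq = _seq(np.full((2, 448, 448), 0.37, dtype=np.float32))
    out = crop_resize(seq, ROISpec(0, 0, 448, 448))
    assert out.frames.shape == (2, 224, 224)
    assert np.allclose(out.frames, 0.37, atol=1e-6)


def test_crop_resize_checkerboard_mean_preserved():
    board = np.indices((448, 448)).sum(axis=0) % 2
    seq = _seq(board[None].astype(np.float32))
    out = crop_resize(seq, ROISpec(0, 0, 448, 448))
    assert out.frames.mean() == pytest.approx(board.mean(), abs=1e-6)


def test_crop_resize_out_of_bounds(rng):
    with pytest.raises(GeometryError, match="half-open"):
        crop_resize(_random_seq(rng, size=100), ROISpec(50, 50, 100, 100))


def test_crop_resize_idempotent_on_full_frame(rng):
    seq = _random_seq(rng, t=2, size=224)
    once = crop_resize(seq, ROISpec(0, 0, 224, 224))
    twice = crop_resize(once, ROISpec(0, 0, 224, 224))
    assert np.array_equal(once.frames, twice.frames)


# ---------------------------------------------------------------------------
# dihedral augmentation
# ---------------------------------------------------------------------------

def test_augment_views_count_and_identity(rng):
    seq = _random_seq(rng)
    views = augment_views(seq)
    assert len(views) == 8
    assert np.array_equal(views[0].frames, seq.frames)
    for v in views:
        assert v.label == seq.label
        assert v.frames.shape == seq.frames.shape


def test_rot90_four_times_is_identity(rng):
    seq = _random_seq(rng)
    out = seq.frames
    for _ in range(4):
        out = np.rot90(out, axes=(1, 2))
    assert np.array_equal(out, seq.frames)


def test_dihedral_group_closure(rng):
    """Views of views yield the same set of 8 distinct rasters."""
    seq = _random_seq(rng)
    first = {v.frames.tobytes() for v in augment_views(seq)}
    assert len(first) == 8
    second = set()
    for v in augment_views(seq):
        second |= {w.frames.tobytes() for w in augment_views(v)}
    assert second == first


def test_augment_views_rejects_non_square(rng):
    seq = _seq(rng.random((3, 8, 10)))
    with pytest.raises(GeometryError):
        augment_views(seq)


# ---------------------------------------------------------------------------
# test-time augmentation
# ---------------------------------------------------------------------------

class _DummyModel:
    """Logistic head on the mean of a fixed spatial mask (view-sensitive)."""

    def __init__(self, size):
        rng = np.random.default_rng(0)
        self.mask = rng.random((size, size)).astype(np.float32)

    def forward(self, x, train=False):
        feat = (x * self.mask).mean(axis=(1, 2, 3, 4))
        return np.column_stack([feat, -feat, feat * 0.5])


def test_tta_equals_explicit_eight_pass_mean(rng):
    seq = _random_seq(rng, size=12)
    model = _DummyModel(12)
    got = tta_predict(model, seq, channels=1)
    views = augment_views(seq)
    scores = [nn.softmax(model.forward(v.frames[None, None]))[0] for v in views]
    assert np.allclose(got, np.mean(scores, axis=0), atol=1e-7)
    assert got.sum() == pytest.approx(1.0)


def test_tta_invariant_to_content_blind_model(rng):
    class Constant:
        def forward(self, x, train=False):
            return np.tile([2.0, 1.0, 0.0], (x.shape[0], 1))

    seq = _random_seq(rng, size=12)
    single = nn.softmax(Constant().forward(seq.frames[None, None]))[0]
    assert np.allclose(tta_predict(Constant(), seq, channels=1), single)


# ---------------------------------------------------------------------------
# stratified splitting
# ---------------------------------------------------------------------------

def _items(counts):
    items = {}
    for stage, n in zip(("mild", "moderate", "severe"), counts):
        for i in range(n):
            items[f"{stage}-{i}"] = stage
    return items


def test_split_exact_ratios():
    split = stratified_split(_items((150, 150, 150)), seed=4)
    for stage in ("mild", "moderate", "severe"):
        ids = [k for k, v in split.assignment.items() if k.startswith(stage)]
        by = {s: sum(1 for i in ids if split.assignment[i] == s)
              for s in ("train", "validation", "test")}
        assert by == {"train": 90, "validation": 30, "test": 30}


def test_split_largest_remainder_on_printed_counts():
    """Class sizes (516, 512, 515) at 6:2:2 give train sizes (310, 307, 309)."""
    split = stratified_split(_items((516, 512, 515)), seed=0)
    train_sizes = [
        sum(1 for k, v in split.assignment.items()
            if v == "train" and k.startswith(stage))
        for stage in ("mild", "moderate", "severe")
    ]
    assert train_sizes == [310, 307, 309]


def test_split_deterministic_disjoint_exhaustive():
    items = _items((40, 30, 20))
    a = stratified_split(items, seed=11)
    b = stratified_split(items, seed=11)
    assert a.assignment == b.assignment
    assert set(a.assignment) == set(items)
    c = stratified_split(items, seed=12)
    assert c.assignment != a.assignment  # a different shuffle moves someone


def test_split_no_leakage_across_augmented_views(rng):
    """All 8 views of a source inherit its assignment."""
    items = _items((12, 12, 12))
    split = stratified_split(items, seed=3)
    for sid, where in split.assignment.items():
        for k, f in DIHEDRAL_VIEWS:
            assert split.assignment[sid] == where  # view keyed by source id


def test_split_small_class_goes_to_train():
    items = _items((10, 10, 2))
    with pytest.warns(UserWarning, match="severe"):
        split = stratified_split(items, seed=0)
    assert all(split.assignment[k] == "train"
               for k in items if k.startswith("severe"))


def test_split_rejects_bad_ratios():
    with pytest.raises(InvalidArgumentError):
        stratified_split(_items((5, 5, 5)), ratios=(0.5, 0.2, 0.2))


# ---------------------------------------------------------------------------
# I/O round trips
# ---------------------------------------------------------------------------

def test_sample_npz_round_trip(tmp_path, rng):
    seq = _random_seq(rng, label="moderate")
    save_sample(tmp_path / "s.npz", seq)
    back = load_sample(tmp_path / "s.npz")
    assert np.array_equal(back.frames, seq.frames)
    assert back.label == "moderate" and back.source_id == seq.source_id


def test_read_frame_directory_png(tmp_path, rng):
    import imageio.v3 as iio

    frames = (rng.random((3, 16, 16)) * 255).astype(np.uint8)
    for i, frame in enumerate(frames):
        iio.imwrite(tmp_path / f"f{i}.png", frame)
    manifest = [{"source_id": "case1", "label": "severe",
                 "frames": [f"f{i}.png" for i in range(3)]}]
    (tmp_path / "manifest.json").write_text(json.dumps(manifest))
    [(seq, rec)] = read_frame_directory(tmp_path / "manifest.json")
    assert seq.n_frames == 3 and seq.label == "severe"
    assert 0.0 <= seq.frames.min() and seq.frames.max() <= 1.0


def test_read_multiframe_dicom(tmp_path, rng):
    import pydicom
    from pydicom.dataset import Dataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    arr = (rng.random((4, 12, 12)) * 1000).astype(np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = generate_uid()
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.NumberOfFrames = 4
    ds.Rows, ds.Columns = 12, 12
    ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = arr.tobytes()
    path = tmp_path / "seq.dcm"
    ds.save_as(path, enforce_file_format=True)

    from p3dstage.preprocess import read_dicom_sequence
    seq = read_dicom_sequence(path, source_id="case2", label="mild")
    assert seq.n_frames == 4 and seq.frame_shape == (12, 12)
    assert seq.frames.max() <= 1.0


# ---------------------------------------------------------------------------
# augmentation-for-balance
# ---------------------------------------------------------------------------

def test_oversample_views_meets_quota(rng):
    seqs = [_random_seq(rng, label="mild") for _ in range(3)] + \
        [_random_seq(rng, label="moderate") for _ in range(10)] + \
        [_random_seq(rng, label="severe") for _ in range(10)]
    for i, s in enumerate(seqs):
        object.__setattr__(s, "source_id", f"src{i}")
    from p3dstage.preprocess import oversample_views
    grown = oversample_views(seqs, target_per_class=10, seed=5)
    counts = {}
    for s in grown:
        counts[s.label] = counts.get(s.label, 0) + 1
    assert counts == {"mild": 10, "moderate": 10, "severe": 10}
    # added views are distinct (source, view) pairs, never the identity
    added = grown[len(seqs):]
    keys = {(s.source_id, tuple(s.metadata["view"])) for s in added}
    assert len(keys) == len(added)
    assert all(s.metadata["view"] != (0, False) for s in added)
    # determinism
    again = oversample_views(seqs, target_per_class=10, seed=5)
    assert [(s.source_id, s.metadata.get("view")) for s in again] == \
        [(s.source_id, s.metadata.get("view")) for s in grown]


def test_oversample_views_warns_when_quota_unreachable(rng):
    seqs = [_random_seq(rng, label="mild"),
            *[_random_seq(rng, label="moderate") for _ in range(12)],
            *[_random_seq(rng, label="severe") for _ in range(12)]]
    from p3dstage.preprocess import oversample_views
    with pytest.warns(UserWarning, match="mild"):
        grown = oversample_views(seqs, target_per_class=12, seed=1)
    assert sum(1 for s in grown if s.label == "mild") == 8  # 1 + 7 views
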