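"""Tests for segment sampling, geometric preprocessing, and dataset indexing."""

import numpy as np
import pytest

from pbatn.data_pipeline import (
    CLASS_NAMES,
    Clip,
    Normalization,
    SamplerConfig,
    clip_to_batch,
    load_clip_frames,
    load_dataset,
    resize_pad,
    sample_segments,
    sliding_window_collect,
)
from pbatn.synthetic import SceneParams, generate_dataset


def gray_frame(h, w, value=0):
    return np.full((h, w, 3), value, dtype=np.uint8)


class TestSampleSegments:
    def test_eval_midpoints_32_frames(self):
        cfg = SamplerConfig(num_segments=8, mode="eval")
        assert sample_segments(32, cfg) == [2, 6, 10, 14, 18, 22, 26, 30]

    def test_eval_one_frame_per_segment(self):
        cfg = SamplerConfig(num_segments=8, mode="eval")
        assert sample_segments(8, cfg) == list(range(8))

    def test_train_draws_stay_within_segment_bounds(self):
        for seed in range(1000):
            cfg = SamplerConfig(num_segments=8, mode="train", seed=seed)
            idx = sample_segments(32, cfg)
            for i, v in enumerate(idx):
                assert 4 * i <= v < 4 * (i + 1)

    def test_sorted_and_in_range_exhaustive(self):
        for total in range(1, 65):
            for s in range(1, 65):
                for mode in ("train", "eval"):
                    cfg = SamplerConfig(num_segments=s, mode=mode, seed=total)
                    idx = sample_segments(total, cfg)
                    assert len(idx) == s
                    assert all(0 <= v < total for v in idx)
                    assert idx == sorted(idx)

    def test_short_clip_nearest_fill(self):
        cfg = SamplerConfig(num_segments=8, mode="eval")
        idx = sample_segments(3, cfg)
        assert len(idx) == 8
        assert set(idx) <= {0, 1, 2}

    def test_invalid_total_rejected(self):
        with pytest.raises(ValueError):
            sample_segments(0, SamplerConfig())


class TestResizePad:
    def test_414x240_scales_and_pads_to_224(self):
        frame = gray_frame(240, 414, 255)
        out = resize_pad(frame)
        assert out.shape == (224, 224, 3)
        # 240·224/414 = 129.86 → 130 content rows, 47 zero rows above and below
        assert np.all(out[:47] == 0) and np.all(out[-47:] == 0)
        assert np.all(out[47:177] > 0)

    def test_identity_on_target_size(self):
        frame = gray_frame(224, 224, 7)
        np.testing.assert_array_equal(resize_pad(frame), frame)

    def test_exact_halving_448x224(self):
        out = resize_pad(gray_frame(224, 448, 200))
        assert np.all(out[:56] == 0) and np.all(out[-56:] == 0)
        assert np.all(out[56:168] > 0)

    def test_aspect_ratio_preserved_within_rounding(self):
        for h, w in [(240, 414), (100, 37), (250, 251), (64, 64)]:
            out = resize_pad(gray_frame(h, w, 255), target=128)
            rows = np.flatnonzero(out[:, :, 0].any(axis=1))
            cols = np.flatnonzero(out[:, :, 0].any(axis=0))
            ch, cw = len(rows), len(cols)
            assert abs(cw / ch - w / h) <= max(w / h, 1) * (1 / min(ch, cw) + 1e-9)

    def test_odd_remainder_pads_extra_bottom(self):
        # 101×128 content height on a 128 target → 27 pad: 13 top, 14 bottom
        out = resize_pad(gray_frame(101, 128, 255), target=128)
        rows = np.flatnonzero(out[:, :, 0].any(axis=1))
        assert rows[0] == 13 and rows[-1] == 13 + 101 - 1

    def test_invalid_target(self):
        with pytest.raises(ValueError):
            resize_pad(gray_frame(10, 10), target=0)


class TestClipToBatch:
    def test_output_shape_contract(self):
        clip = Clip(frames=[gray_frame(240, 414, 100)] * 32, label=0)
        batch = clip_to_batch(clip, SamplerConfig(mode="eval"))
        assert batch.shape == (8, 3, 224, 224)
        assert batch.dtype == np.float32

    def test_all_black_clip_standardizes_zeros(self):
        clip = Clip(frames=[gray_frame(32, 32, 0)] * 8)
        norm = Normalization()
        batch = clip_to_batch(clip, SamplerConfig(mode="eval"), target=32)
        for c in range(3):
            expected = (0.0 - norm.mean[c]) / norm.std[c]
            np.testing.assert_allclose(batch[:, c], expected, atol=1e-6)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(0)
        frames = [rng.integers(0, 255, (48, 64, 3)).astype(np.uint8) for _ in range(20)]
        clip = Clip(frames=frames)
        cfg = SamplerConfig(mode="train", seed=7)
        np.testing.assert_array_equal(
            clip_to_batch(clip, cfg, target=64), clip_to_batch(clip, cfg, target=64)
        )


class TestSlidingWindow:
    def test_240_frames_at_30fps_one_clip(self):
        stream = (gray_frame(16, 16, i % 255) for i in range(240))
        clips = list(sliding_window_collect(stream, fps=30, window=8))
        assert len(clips) == 1
        assert len(clips[0]) == 8

    def test_one_frame_buckets_pick_every_frame(self):
        stream = [gray_frame(8, 8, 10 * i) for i in range(8)]
        clips = list(sliding_window_collect(iter(stream), fps=1, window=8))
        # one-frame buckets: the eight picks are the eight frames in order
        assert len(clips) == 1
        got = [int(f[0, 0, 0]) for f in clips[0].frames]
        assert got == [0, 10, 20, 30, 40, 50, 60, 70]

    def test_ten_second_stream_hop_one_gives_three(self):
        stream = (gray_frame(8, 8) for _ in range(300))
        clips = list(sliding_window_collect(stream, fps=30, window=8, hop=1))
        assert len(clips) == 3

    def test_short_stream_emits_nothing(self):
        stream = (gray_frame(8, 8) for _ in range(100))
        assert list(sliding_window_collect(stream, fps=30, window=8)) == []


@pytest.fixture(scope="module")
def fixture_root(tmp_path_factory):
    root = tmp_path_factory.mktemp("ds")
    params = SceneParams(frame_size=(32, 32), frames_per_clip=8, agent_radius=4.0)
    generate_dataset(root, clips_per_class=10, params=params, seed=0,
                     test_fraction=0.0)
    return root


class TestLoadDataset:
    def test_sixty_entries_six_classes(self, fixture_root):
        index = load_dataset(fixture_root, test_fraction=0.0)
        assert len(index.entries) == 60
        assert sorted({lab for _, lab in index.entries}) == list(range(6))

    def test_split_ratio_four_to_one(self, fixture_root):
        index = load_dataset(fixture_root, test_fraction=0.0, seed=1)
        counts = index.counts()
        assert counts == {"train": 48, "val": 12, "test": 0}

    def test_split_reproducible(self, fixture_root):
        i1 = load_dataset(fixture_root, seed=5)
        i2 = load_dataset(fixture_root, seed=5)
        assert i1.split == i2.split

    def test_unknown_class_folder_named_in_error(self, tmp_path):
        (tmp_path / "grooming").mkdir()
        with pytest.raises(ValueError, match="grooming"):
            load_dataset(tmp_path)

    def test_clip_roundtrip(self, fixture_root):
        path, label = load_dataset(fixture_root, test_fraction=0.0).entries[0]
        clip = load_clip_frames(path, label)
        assert len(clip) == 8
        assert clip.frames[0].shape == (32, 32, 3)
        assert CLASS_NAMES[label] == path.parent.name
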