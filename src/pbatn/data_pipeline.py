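"""Clip datasets, segment sampling, and geometric preprocessing.

Clips live on disk as one folder of numbered JPEG/PNG frames per clip, one
folder of clips per behavior class.  A clip enters the network as a fixed
number of frames (8 by default): the frame range is divided into that many
equal segments and one frame is drawn per segment — uniformly at random in
training, the segment midpoint in evaluation.  Each frame is scaled so its
longer side is 224 pixels (aspect ratio preserved) and zero-padded to a
224×224 square, then standardized per channel.

An online sliding-window collector mirrors the deployment path: one random
frame per second of stream, a clip emitted every hop once the window is
full.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
from PIL import Image

__all__ = [
    "CLASS_NAMES",
    "Clip",
    "DatasetIndex",
    "SamplerConfig",
    "Normalization",
    "sample_segments",
    "resize_pad",
    "clip_to_batch",
    "sliding_window_collect",
    "load_dataset",
    "load_clip_frames",
]

logger = logging.getLogger(__name__)

#: Fixed behavior class order (index = label id).
CLASS_NAMES = ("activity", "chasing", "mounting", "feeding", "resting", "disturbance")

FRAME_SUFFIXES = (".png", ".jpg", ".jpeg")


def _check_frame(frame: np.ndarray) -> np.ndarray:
    arr = np.asarray(frame)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"frame must be H×W×3, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("frame must have positive height and width")
    return arr.astype(np.uint8, copy=False)


@dataclass
class Clip:
    """An ordered frame sequence with an optional behavior label."""

    frames: list
    label: int | None = None
    clip_id: str = ""

    def __post_init__(self):
        if len(self.frames) < 1:
            raise ValueError("clip must contain at least one frame")
        self.frames = [_check_frame(f) for f in self.frames]
        first = self.frames[0].shape
        for i, f in enumerate(self.frames):
            if f.shape != first:
                raise ValueError(
                    f"frame {i} has shape {f.shape}, expected {first} (all frames equal)"
                )
        if self.label is not None and not 0 <= self.label < len(CLASS_NAMES):
            raise ValueError(f"label {self.label} outside 0..{len(CLASS_NAMES) - 1}")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SamplerConfig:
    num_segments: int = 8
    mode: str = "train"
    seed: int = 0

    def __post_init__(self):
        if self.num_segments < 1:
            raise ValueError("num_segments must be ≥ 1")
        if self.mode not in ("train", "eval"):
            raise ValueError(f"mode must be 'train' or 'eval', got {self.mode!r}")


@dataclass
class Normalization:
    """Per-channel standardization constants on the [0,1] pixel scale."""

    mean: tuple = (0.485, 0.456, 0.406)
    std: tuple = (0.229, 0.224, 0.225)


def sample_segments(total_frames: int, cfg: SamplerConfig) -> list[int]:
    """Pick one frame index per segment.

    The range [0, total_frames) is split into ``num_segments`` segments
    [⌊i·T/S⌋, ⌊(i+1)·T/S⌋).  Training draws uniformly inside each segment
    from the seeded generator; evaluation takes the segment midpoint.
    Clips shorter than the segment count repeat indices by nearest fill.
    """
    if total_frames < 1:
        raise ValueError(f"total_frames must be ≥ 1, got {total_frames}")
    s = cfg.num_segments
    rng = np.random.default_rng(cfg.seed)
    indices = []
    for i in range(s):
        start = (i * total_frames) // s
        end = ((i + 1) * total_frames) // s
        mid = min(((2 * i + 1) * total_frames) // (2 * s), total_frames - 1)
        if cfg.mode == "train" and end > start:
            indices.append(int(rng.integers(start, end)))
        else:
            indices.append(mid)
    return indices


def resize_pad(frame: np.ndarray, target: int = 224) -> np.ndarray:
    """Scale the longer side to ``target`` (bilinear, aspect preserved) and
    zero-pad the shorter side symmetrically; odd remainders pad bottom/right."""
    if target < 1:
        raise ValueError(f"target must be ≥ 1, got {target}")
    frame = _check_frame(frame)
    h, w = frame.shape[:2]
    if (h, w) == (target, target):
        return frame
    if w >= h:
        new_w, new_h = target, max(1, round(h * target / w))
    else:
        new_h, new_w = target, max(1, round(w * target / h))
    img = Image.fromarray(frame).resize((new_w, new_h), Image.BILINEAR)
    out = np.zeros((target, target, 3), dtype=np.uint8)
    top = (target - new_h) // 2
    left = (target - new_w) // 2
    out[top : top + new_h, left : left + new_w] = np.asarray(img)
    return out


def clip_to_batch(
    clip: Clip,
    cfg: SamplerConfig,
    target: int = 224,
    normalization: Normalization | None = None,
) -> np.ndarray:
    """Sample, resize/pad, and standardize a clip into S×3×target×target."""
    norm = normalization or Normalization()
    indices = sample_segments(len(clip), cfg)
    frames = np.stack([resize_pad(clip.frames[i], target) for i in indices])
    x = frames.astype(np.float32) / 255.0
    x = x.transpose(0, 3, 1, 2)  # S×3×H×W
    mean = np.asarray(norm.mean, dtype=np.float32).reshape(1, 3, 1, 1)
    std = np.asarray(norm.std, dtype=np.float32).reshape(1, 3, 1, 1)
    return (x - mean) / std


def sliding_window_collect(
    frame_stream: Iterable[np.ndarray],
    fps: int,
    window: int = 8,
    hop: int = 1,
    seed: int = 0,
) -> Iterator[Clip]:
    """Collect one random frame per one-second bucket and emit clips.

    A clip is emitted whenever ``window`` bucket picks are available; the
    buffer then slides forward by ``hop`` buckets (seconds).  A stream that
    ends before the first window fills emits nothing.
    """
    if fps < 1:
        raise ValueError(f"fps must be ≥ 1, got {fps}")
    if window < 1 or hop < 1:
        raise ValueError("window and hop must be ≥ 1")
    rng = np.random.default_rng(seed)
    picks: list[np.ndarray] = []
    bucket: list[np.ndarray] = []
    emitted = 0

    def close_bucket():
        picks.append(bucket[int(rng.integers(len(bucket)))])
        bucket.clear()

    for frame in frame_stream:
        bucket.append(_check_frame(frame))
        if len(bucket) == fps:
            close_bucket()
            while len(picks) >= window:
                yield Clip(frames=list(picks[:window]), clip_id=f"window_{emitted}")
                emitted += 1
                del picks[:hop]
    if bucket:
        close_bucket()
        if len(picks) >= window:
            yield Clip(frames=list(picks[:window]), clip_id=f"window_{emitted}")
            emitted += 1
    if emitted == 0:
        logger.warning(
            "stream ended before a full %d-second window was collected", window
        )


@dataclass
class DatasetIndex:
    """Enumerated clip folders with labels and a train/val/test assignment."""

    entries: list = field(default_factory=list)  # (Path, label)
    split: dict = field(default_factory=dict)  # Path -> "train"|"val"|"test"
    class_names: tuple = CLASS_NAMES

    def subset(self, name: str) -> list:
        if name not in ("train", "val", "test"):
            raise ValueError(f"unknown split {name!r}")
        return [(p, lab) for p, lab in self.entries if self.split[p] == name]

    def counts(self) -> dict:
        out = {"train": 0, "val": 0, "test": 0}
        for p, _ in self.entries:
            out[self.split[p]] += 1
        return out


def load_clip_frames(clip_dir: Path, label: int | None = None) -> Clip:
    """Read a clip folder's frames in lexicographic order."""
    clip_dir = Path(clip_dir)
    paths = sorted(
        p for p in clip_dir.iterdir() if p.suffix.lower() in FRAME_SUFFIXES
    )
    if not paths:
        raise ValueError(f"no frames found in {clip_dir}")
    frames = [np.asarray(Image.open(p).convert("RGB")) for p in paths]
    return Clip(frames=frames, label=label, clip_id=clip_dir.name)


def load_clip_video(path: Path, label: int | None = None) -> Clip:
    """Optional mp4 backend: read a clip from a video file via imageio.

    Requires an ffmpeg-capable imageio plugin; the frame-folder layout is
    the primary on-disk format and needs no codecs.
    """
    import imageio.v3 as iio

    path = Path(path)
    try:
        frames = [np.asarray(f)[:, :, :3] for f in iio.imiter(path)]
    except Exception as exc:  # plugin or codec missing
        raise RuntimeError(
            f"cannot read {path}: no usable video backend ({exc}); "
            "use the frame-folder layout instead"
        ) from exc
    if not frames:
        raise ValueError(f"no frames decoded from {path}")
    return Clip(frames=frames, label=label, clip_id=path.stem)


def load_dataset(
    root: Path,
    class_names: Sequence[str] = CLASS_NAMES,
    test_fraction: float = 0.1,
    train_val_ratio: float = 4.0,
    seed: int = 0,
) -> DatasetIndex:
    """Index a class-per-folder dataset and assign stratified splits.

    The test fraction is held out first per class; the remainder is split
    train:val at ``train_val_ratio`` (4:1 by default).  Enumeration is
    lexicographic and the shuffle is seeded, so the split is reproducible.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    name_to_label = {name: i for i, name in enumerate(class_names)}
    entries: list[tuple[Path, int]] = []
    per_class: dict[int, list[Path]] = {i: [] for i in range(len(class_names))}
    for class_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        if class_dir.name not in name_to_label:
            raise ValueError(
                f"unknown class folder {class_dir.name!r} (expected one of "
                f"{sorted(name_to_label)})"
            )
        label = name_to_label[class_dir.name]
        clips = sorted(p for p in class_dir.iterdir() if p.is_dir())
        if not clips:
            logger.warning("class folder %s contains no clips", class_dir)
        per_class[label].extend(clips)
        entries.extend((c, label) for c in clips)
    rng = np.random.default_rng(seed)
    split: dict[Path, str] = {}
    for label, clips in per_class.items():
        clips = list(clips)
        order = rng.permutation(len(clips))
        n_test = int(round(len(clips) * test_fraction))
        remainder = len(clips) - n_test
        n_train = int(round(remainder * train_val_ratio / (train_val_ratio + 1.0)))
        for rank, idx in enumerate(order):
            if rank < n_test:
                split[clips[idx]] = "test"
            elif rank < n_test + n_train:
                split[clips[idx]] = "train"
            else:
                split[clips[idx]] = "val"
    return DatasetIndex(entries=entries, split=split, class_names=tuple(class_names))
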