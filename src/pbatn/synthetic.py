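"""Deterministic synthetic six-class behavior clips.

Each clip renders two disk "animals" moving in a square arena, with class
semantics chosen so the discriminating signal mirrors the real monitoring
problem:

* ``activity`` — the pair wanders together: a persistent random walk for
  animal A with animal B holding a fixed-direction offset.  The offset
  direction is random per clip, so a single frame looks exactly like a
  chasing frame; only the relation between offset and motion direction
  differs.
* ``chasing`` — B trails A along its path (B sits where A was a few frames
  earlier), so the inter-animal offset aligns with the motion direction.
  Reversing the frame order turns the follower into a leader: the mean
  cosine between B's step and the B→A bearing flips sign.  Chasing versus
  activity is therefore a temporal-order discrimination by construction.
* ``mounting`` — sustained large disk overlap, nearly static.
* ``feeding`` — one animal pinned at the fixed trough coordinate (a spatial
  cue), the other wandering.
* ``resting`` — both static.
* ``disturbance`` — a third, larger and brighter agent (a staff member)
  crosses the arena.

Gaussian pixel noise is added everywhere.  Every clip is fully determined
by its seed, so datasets regenerate byte-identically.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data_pipeline import CLASS_NAMES, Clip, DatasetIndex, load_dataset

__all__ = [
    "SceneParams",
    "BehaviorEvent",
    "generate_clip",
    "generate_dataset",
    "resolve_labels",
    "follow_gain",
    "BREEDING_BEHAVIORS",
]

logger = logging.getLogger(__name__)

#: Breeding behaviors take precedence in overlap resolution; mounting over chasing.
BREEDING_BEHAVIORS = ("mounting", "chasing")


@dataclass
class SceneParams:
    """Geometry, motion, and noise parameters of the synthetic arena."""

    frame_size: tuple = (64, 64)  # (H, W) pixels
    frames_per_clip: int = 32
    agent_radius: float = 6.0
    speed: float = 2.0  # step length of the leading animal, px/frame
    turn_sigma: float = 0.12  # heading diffusion, radians/frame
    follow_lag: int = 4  # frames B trails A in chasing
    follow_jitter: float = 0.6  # positional jitter of the second animal, px
    overlap_fraction: float = 0.6  # minimum disk overlap during mounting
    trough: tuple = (0.2, 0.8)  # fixed trough coordinate, fractional (y, x)
    noise_sigma: float = 4.0 / 255.0  # Gaussian pixel noise on the [0,1] scale
    agent_intensity: float = 0.7
    background_intensity: float = 0.12
    disturbance_scale: float = 2.2  # staff agent radius multiplier
    disturbance_intensity: float = 1.0

    def __post_init__(self):
        if min(self.frame_size) < 8 or self.agent_radius <= 0 or self.speed < 0:
            raise ValueError("scene dimensions and sizes must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be ≥ 0")
        if not 0 < self.overlap_fraction <= 1:
            raise ValueError("overlap fraction must be in (0, 1]")


@dataclass
class BehaviorEvent:
    """A labeled time interval [start, end) in frames."""

    start: int
    end: int
    behavior: str

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty interval [{self.start}, {self.end})")
        if self.behavior not in CLASS_NAMES:
            raise ValueError(f"unknown behavior {self.behavior!r}")


# -- trajectory construction -------------------------------------------------


def _bounds(params: SceneParams) -> tuple[float, float, float, float]:
    h, w = params.frame_size
    m = params.agent_radius
    return m, h - m, m, w - m  # y_lo, y_hi, x_lo, x_hi


def _persistent_walk(
    rng: np.random.Generator,
    n: int,
    params: SceneParams,
    speed: float | None = None,
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Heading-diffusion random walk with wall reflection; returns n×2 (y,x)."""
    y_lo, y_hi, x_lo, x_hi = _bounds(params)
    speed = params.speed if speed is None else speed
    pos = (
        np.array([rng.uniform(y_lo, y_hi), rng.uniform(x_lo, x_hi)])
        if start is None
        else np.asarray(start, dtype=float).copy()
    )
    heading = rng.uniform(0, 2 * np.pi)
    out = np.empty((n, 2))
    for t in range(n):
        out[t] = pos
        heading += rng.normal(0, params.turn_sigma)
        step = speed * np.array([np.sin(heading), np.cos(heading)])
        nxt = pos + step
        if not y_lo <= nxt[0] <= y_hi:
            heading = -heading  # reflect vertically
            nxt = pos + speed * np.array([np.sin(heading), np.cos(heading)])
        if not x_lo <= nxt[1] <= x_hi:
            heading = np.pi - heading  # reflect horizontally
            nxt = pos + speed * np.array([np.sin(heading), np.cos(heading)])
        pos = np.clip(nxt, [y_lo, x_lo], [y_hi, x_hi])
    return out


def _clamp(traj: np.ndarray, params: SceneParams) -> np.ndarray:
    y_lo, y_hi, x_lo, x_hi = _bounds(params)
    return np.clip(traj, [y_lo, x_lo], [y_hi, x_hi])


def _pair_trajectories(
    behavior: str, params: SceneParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray | None]:
    """Positions of animals A and B (n×2 each) and optionally a third agent."""
    n = params.frames_per_clip
    lag = params.follow_lag
    jitter = rng.normal(0, params.follow_jitter, size=(n, 2))
    third = None
    if behavior in ("activity", "disturbance"):
        a = _persistent_walk(rng, n + lag, params)[lag:]
        # fixed-direction offset: per-frame geometry matches chasing exactly
        angle = rng.uniform(0, 2 * np.pi)
        offset = lag * params.speed * np.array([np.sin(angle), np.cos(angle)])
        b = a + offset + jitter
        if behavior == "disturbance":
            third = _persistent_walk(rng, n, params, speed=params.speed * 1.2)
    elif behavior == "chasing":
        full = _persistent_walk(rng, n + lag, params)
        a = full[lag:]
        b = full[:n] + jitter  # B occupies A's position `lag` frames ago
    elif behavior == "mounting":
        # ≥ overlap_fraction disk overlap ⇒ centers closer than r·(1−f)·2
        center = _persistent_walk(rng, n, params, speed=params.speed * 0.05)
        max_d = 2.0 * params.agent_radius * (1.0 - params.overlap_fraction)
        angle = rng.uniform(0, 2 * np.pi)
        d = rng.uniform(0.3, 0.9) * max_d
        a = center
        b = center + d * np.array([np.sin(angle), np.cos(angle)]) + jitter * 0.2
    elif behavior == "feeding":
        h, w = params.frame_size
        trough_px = np.array([params.trough[0] * h, params.trough[1] * w])
        a = np.tile(trough_px, (n, 1)) + jitter * 0.3
        b = _persistent_walk(rng, n, params)
    elif behavior == "resting":
        spot_a = _persistent_walk(rng, 1, params)[0]
        angle = rng.uniform(0, 2 * np.pi)
        d = rng.uniform(2.5, 4.0) * params.agent_radius
        spot_b = spot_a + d * np.array([np.sin(angle), np.cos(angle)])
        a = np.tile(spot_a, (n, 1))
        b = np.tile(spot_b, (n, 1))
    else:
        raise ValueError(f"unknown behavior {behavior!r}")
    return _clamp(a, params), _clamp(b, params), third


def _render(
    params: SceneParams,
    agents: list[tuple[np.ndarray, float, float]],
    rng: np.random.Generator,
) -> list[np.ndarray]:
    """Draw anti-aliased disks per frame and add Gaussian noise."""
    h, w = params.frame_size
    yy, xx = np.mgrid[0:h, 0:w]
    n = agents[0][0].shape[0]
    frames = []
    for t in range(n):
        img = np.full((h, w), params.background_intensity, dtype=np.float64)
        for traj, radius, intensity in agents:
            dist = np.hypot(yy - traj[t, 0], xx - traj[t, 1])
            mask = np.clip(radius + 0.5 - dist, 0.0, 1.0)  # 1-px soft edge
            img = np.maximum(img, intensity * mask)
        img = img + rng.normal(0, params.noise_sigma, size=(h, w))
        img8 = (np.clip(img, 0, 1) * 255).round().astype(np.uint8)
        frames.append(np.repeat(img8[:, :, None], 3, axis=2))
    return frames


def generate_clip(
    behavior: str,
    params: SceneParams | None = None,
    seed: int = 0,
    return_positions: bool = False,
):
    """Render one labeled clip; fully determined by (behavior, params, seed)."""
    params = params or SceneParams()
    if behavior not in CLASS_NAMES:
        raise ValueError(
            f"unknown behavior {behavior!r} (expected one of {list(CLASS_NAMES)})"
        )
    rng = np.random.default_rng(seed)
    a, b, third = _pair_trajectories(behavior, params, rng)
    agents = [
        (a, params.agent_radius, params.agent_intensity),
        (b, params.agent_radius, params.agent_intensity),
    ]
    if third is not None:
        agents.append(
            (
                third,
                params.agent_radius * params.disturbance_scale,
                params.disturbance_intensity,
            )
        )
    frames = _render(params, agents, rng)
    clip = Clip(
        frames=frames,
        label=CLASS_NAMES.index(behavior),
        clip_id=f"{behavior}_{seed}",
    )
    if return_positions:
        return clip, {"a": a, "b": b, "third": third}
    return clip


def follow_gain(a: np.ndarray, b: np.ndarray) -> float:
    """Mean cosine between B's step direction and the B→A bearing.

    Near +1 when B chases A, near −1 when B leads (e.g. on a reversed
    chasing clip), near 0 for motion unrelated to the bearing.
    """
    steps = np.diff(b, axis=0)
    bearings = (a - b)[:-1]
    keep = (np.linalg.norm(steps, axis=1) > 1e-9) & (
        np.linalg.norm(bearings, axis=1) > 1e-9
    )
    if not np.any(keep):
        return 0.0
    steps, bearings = steps[keep], bearings[keep]
    cos = np.sum(steps * bearings, axis=1) / (
        np.linalg.norm(steps, axis=1) * np.linalg.norm(bearings, axis=1)
    )
    return float(cos.mean())


# -- datasets ----------------------------------------------------------------


def generate_dataset(
    root: Path,
    clips_per_class: int | dict = 10,
    params: SceneParams | None = None,
    seed: int = 0,
    overwrite: bool = False,
    test_fraction: float = 0.1,
    split_seed: int | None = None,
) -> DatasetIndex:
    """Write a class-per-folder dataset of rendered clips plus a manifest.

    Per-clip seeds are drawn from one root seed and recorded in
    ``manifest.json``, so regeneration is byte-identical.  Refuses to touch
    an existing non-empty directory unless ``overwrite`` is set.
    """
    params = params or SceneParams()
    root = Path(root)
    if root.exists() and any(root.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{root} exists and is not empty; pass overwrite=True to replace it"
            )
        shutil.rmtree(root)
    root.mkdir(parents=True, exist_ok=True)
    if isinstance(clips_per_class, int):
        counts = {name: clips_per_class for name in CLASS_NAMES}
    else:
        counts = dict(clips_per_class)
    unknown = set(counts) - set(CLASS_NAMES)
    if unknown:
        raise ValueError(f"unknown behavior names in counts: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    manifest = {
        "class_names": list(CLASS_NAMES),
        "counts": counts,
        "seed": seed,
        "params": asdict(params),
        "clips": {},
    }
    for name in CLASS_NAMES:
        n_clips = counts.get(name, 0)
        class_dir = root / name
        class_dir.mkdir()
        for i in range(n_clips):
            clip_seed = int(rng.integers(0, 2**31 - 1))
            clip = generate_clip(name, params, seed=clip_seed)
            clip_dir = class_dir / f"{name}_{i:04d}"
            clip_dir.mkdir()
            for t, frame in enumerate(clip.frames):
                Image.fromarray(frame).save(clip_dir / f"frame_{t:05d}.png")
            manifest["clips"][f"{name}/{clip_dir.name}"] = clip_seed
    manifest_path = root / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return load_dataset(
        root,
        test_fraction=test_fraction,
        seed=seed if split_seed is None else split_seed,
    )


# -- breeding-precedence label resolution ------------------------------------


def _priority(behavior: str, start: int) -> tuple:
    """Sort key: breeding first (mounting over chasing), then earliest start."""
    if behavior == "mounting":
        rank = 0
    elif behavior == "chasing":
        rank = 1
    else:
        rank = 2
    return (rank, start)


def resolve_labels(events: list[BehaviorEvent]) -> list[BehaviorEvent]:
    """Resolve overlapping events into disjoint single-label intervals.

    Breeding behaviors (mounting, chasing) win over non-breeding wherever
    intervals overlap; mounting wins over chasing; remaining conflicts go to
    the earliest-starting event.  Adjacent resolved intervals with the same
    label are merged.
    """
    if not events:
        raise ValueError("resolve_labels needs at least one event")
    edges = sorted({e.start for e in events} | {e.end for e in events})
    resolved: list[BehaviorEvent] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        covering = [e for e in events if e.start <= lo and e.end >= hi]
        if not covering:
            continue
        winner = min(covering, key=lambda e: _priority(e.behavior, e.start))
        if resolved and resolved[-1].behavior == winner.behavior and resolved[-1].end == lo:
            resolved[-1] = BehaviorEvent(resolved[-1].start, hi, winner.behavior)
        else:
            resolved.append(BehaviorEvent(lo, hi, winner.behavior))
    return resolved
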