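"""Training and evaluation loops.

Optimization defaults to Adam with warmup and cosine learning-rate
decay (momentum SGD is available as an alternative).
All randomness — batch order, per-clip segment sampling, dropout — derives
from one root seed, so two runs with the same seed produce identical
losses.  Clips are read into memory once (the synthetic datasets are
small); training resamples segment frames every epoch while validation
always uses midpoint sampling.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .autograd import Tensor
from .data_pipeline import (
    Clip,
    DatasetIndex,
    Normalization,
    SamplerConfig,
    clip_to_batch,
    load_clip_frames,
)
from .head import cross_entropy_logits
from .metrics import metric_report
from .model import BehaviorModel, save_checkpoint

__all__ = ["SGD", "Adam", "TrainSettings", "fit", "evaluate_clips", "load_split_clips"]

logger = logging.getLogger(__name__)


class SGD:
    """Momentum SGD with optional global gradient-norm clipping."""

    def __init__(
        self,
        params,
        lr: float = 0.05,
        momentum: float = 0.9,
        max_grad_norm: float | None = None,
    ):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.max_grad_norm = max_grad_norm
        self.velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        scale = 1.0
        if self.max_grad_norm is not None:
            total = np.sqrt(
                sum(
                    float(np.sum(np.square(p.grad)))
                    for p in self.params
                    if p.grad is not None
                )
            )
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / (total + 1e-12)
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            v *= self.momentum
            v += p.grad * scale
            p.data -= (self.lr * v).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


class Adam:
    """Adam optimizer with bias correction and optional gradient clipping."""

    def __init__(
        self,
        params,
        lr: float = 1e-3,
        betas: tuple = (0.9, 0.999),
        eps: float = 1e-8,
        max_grad_norm: float | None = None,
    ):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.max_grad_norm = max_grad_norm
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        scale = 1.0
        if self.max_grad_norm is not None:
            total = np.sqrt(
                sum(
                    float(np.sum(np.square(p.grad)))
                    for p in self.params
                    if p.grad is not None
                )
            )
            if total > self.max_grad_norm:
                scale = self.max_grad_norm / (total + 1e-12)
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad * scale
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * np.square(g)
            update = (m / c1) / (np.sqrt(v / c2) + self.eps)
            p.data -= (self.lr * update).astype(p.data.dtype)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    return base_lr * 0.5 * (1.0 + np.cos(np.pi * epoch / max(total_epochs, 1)))


@dataclass
class TrainSettings:
    epochs: int = 20
    batch_size: int = 8
    optimizer: str = "adam"  # "adam" | "sgd"
    lr: float = 1e-3  # Adam default; SGD wants ~0.05
    momentum: float = 0.9
    target_size: int = 64
    seed: int = 0
    checkpoint_path: Path | None = None
    log_every: int = 0  # batches; 0 = epoch-level logging only
    stop_at_val_accuracy: float | None = None  # early stop once reached
    lr_cycle: int | None = None  # cosine cycle length; None = one cycle over epochs
    warmup_epochs: int = 2  # linear ramp before the cosine decay
    max_grad_norm: float | None = 5.0  # global clip; None disables


@dataclass
class History:
    train_loss: list = field(default_factory=list)
    train_accuracy: list = field(default_factory=list)
    val_accuracy: list = field(default_factory=list)
    lr: list = field(default_factory=list)
    best_val_accuracy: float = 0.0
    best_epoch: int = -1
    seconds: float = 0.0


def load_split_clips(index: DatasetIndex, split: str) -> list[Clip]:
    return [load_clip_frames(path, label) for path, label in index.subset(split)]


def _clip_batches(
    clips: list[Clip],
    settings: TrainSettings,
    epoch: int,
    frames: int,
    rng: np.random.Generator,
    norm: Normalization,
):
    order = rng.permutation(len(clips))
    bs = settings.batch_size
    for start in range(0, len(order), bs):
        chosen = order[start : start + bs]
        xs, ys = [], []
        for j in chosen:
            clip = clips[j]
            cfg = SamplerConfig(
                num_segments=frames,
                mode="train",
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            xs.append(clip_to_batch(clip, cfg, target=settings.target_size, normalization=norm))
            ys.append(clip.label)
        yield np.stack(xs), np.asarray(ys)


def evaluate_clips(
    model: BehaviorModel,
    clips: list[Clip],
    target_size: int = 64,
    with_scores: bool = False,
    chunk: int = 8,
):
    """Midpoint-sampled evaluation; returns (accuracy, report or None).

    Clips are scored in chunks so the per-frame work is batched; the fused
    logits are identical to scoring clips one at a time.
    """
    from .autograd import Tensor, no_grad
    from .head import softmax as np_softmax

    sampler = SamplerConfig(num_segments=model.backbone.cfg.input_frames, mode="eval")
    y_true, y_pred, scores = [], [], []
    model.eval()
    for start in range(0, len(clips), chunk):
        group = clips[start : start + chunk]
        x = np.stack([clip_to_batch(c, sampler, target=target_size) for c in group])
        with no_grad():
            fused = model(Tensor(x)).data
        probs = np_softmax(fused, axis=-1)
        y_true.extend(c.label for c in group)
        y_pred.extend(np.argmax(probs, axis=1).tolist())
        scores.extend(probs)
    accuracy = float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
    report = None
    if with_scores:
        report = metric_report(
            y_true, y_pred, list(model.class_names), np.asarray(scores)
        )
    return accuracy, report


def fit(
    model: BehaviorModel,
    train_clips: list[Clip],
    val_clips: list[Clip],
    settings: TrainSettings | None = None,
) -> History:
    """Train with seeded determinism; keeps the best-by-validation weights."""
    settings = settings or TrainSettings()
    rng = np.random.default_rng(settings.seed)
    norm = Normalization()
    if settings.optimizer == "adam":
        opt = Adam(
            model.parameters(), lr=settings.lr, max_grad_norm=settings.max_grad_norm
        )
    elif settings.optimizer == "sgd":
        opt = SGD(
            model.parameters(),
            lr=settings.lr,
            momentum=settings.momentum,
            max_grad_norm=settings.max_grad_norm,
        )
    else:
        raise ValueError(f"unknown optimizer {settings.optimizer!r}")
    frames = model.backbone.cfg.input_frames
    hist = History()
    best_state = None
    t0 = time.time()
    warm = settings.warmup_epochs
    cycle = settings.lr_cycle or (settings.epochs - warm)
    for epoch in range(settings.epochs):
        if epoch < warm:
            opt.lr = settings.lr * (epoch + 1) / (warm + 1)  # linear warmup
        else:
            # cosine decay (with warm restarts if a shorter cycle is set)
            opt.lr = cosine_lr(settings.lr, (epoch - warm) % cycle, cycle)
        model.train()
        losses, correct, seen = [], 0, 0
        for bi, (x, y) in enumerate(
            _clip_batches(train_clips, settings, epoch, frames, rng, norm)
        ):
            logits = model(Tensor(x))
            loss = cross_entropy_logits(logits, y)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int(np.sum(np.argmax(logits.data, axis=1) == y))
            seen += len(y)
            if settings.log_every and (bi + 1) % settings.log_every == 0:
                logger.info("epoch %d batch %d loss %.4f", epoch, bi + 1, losses[-1])
        val_acc, _ = evaluate_clips(model, val_clips, settings.target_size)
        hist.train_loss.append(float(np.mean(losses)))
        hist.train_accuracy.append(correct / max(seen, 1))
        hist.val_accuracy.append(val_acc)
        hist.lr.append(opt.lr)
        logger.info(
            "epoch %d/%d  loss %.4f  train acc %.3f  val acc %.3f  lr %.4f",
            epoch + 1,
            settings.epochs,
            hist.train_loss[-1],
            hist.train_accuracy[-1],
            val_acc,
            opt.lr,
        )
        if val_acc >= hist.best_val_accuracy:
            hist.best_val_accuracy = val_acc
            hist.best_epoch = epoch
            best_state = model.state_dict()
        if (
            settings.stop_at_val_accuracy is not None
            and hist.best_val_accuracy >= settings.stop_at_val_accuracy
        ):
            logger.info("early stop: validation target reached at epoch %d", epoch + 1)
            break
    if best_state is not None:
        model.load_state_dict(best_state)
        if settings.checkpoint_path is not None:
            save_checkpoint(
                settings.checkpoint_path,
                model,
                extra={
                    "best_val_accuracy": hist.best_val_accuracy,
                    "best_epoch": hist.best_epoch,
                },
            )
    hist.seconds = time.time() - t0
    return hist
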