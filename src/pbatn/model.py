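"""Full model assembly: backbone + classification head + checkpoint I/O.

Checkpoints are ``.npz`` archives holding the flat ``name → array`` state
of backbone and head plus a JSON metadata entry (architecture config, head
variant, class names), so a saved model reloads with no external context
and predictions stay label-stable.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .autograd import Tensor, no_grad
from .backbone import Backbone, BackboneConfig
from .data_pipeline import CLASS_NAMES, Clip, Normalization, SamplerConfig, clip_to_batch
from .head import ClassScores, ConsensusHead, GRUHead, consensus, predict

__all__ = ["BehaviorModel", "build_model", "save_checkpoint", "load_checkpoint"]


class BehaviorModel(nn.Module):
    """Backbone + head over clip batches B×T×3×H×W → fused logits B×K."""

    def __init__(
        self,
        backbone: Backbone,
        head: ConsensusHead | GRUHead,
        class_names: tuple = CLASS_NAMES,
        head_variant: str = "pbatn",
    ):
        super().__init__()
        if head.num_classes != len(class_names):
            raise ValueError(
                f"head emits {head.num_classes} classes but {len(class_names)} names given"
            )
        self.backbone = backbone
        self.head = head
        self.class_names = tuple(class_names)
        self.head_variant = head_variant

    def forward(self, batch: Tensor) -> Tensor:
        b, t, c, h, w = batch.shape
        feats = self.backbone(batch.reshape(b * t, c, h, w))
        return self.head(feats.reshape(b, t, -1))

    def score_clip(
        self,
        clip: Clip,
        sampler: SamplerConfig | None = None,
        target: int = 224,
        normalization: Normalization | None = None,
    ) -> ClassScores:
        """Eval-mode scoring of one clip (midpoint segment sampling)."""
        sampler = sampler or SamplerConfig(
            num_segments=self.backbone.cfg.input_frames, mode="eval"
        )
        x = clip_to_batch(clip, sampler, target=target, normalization=normalization)
        return self.score_batch(x)

    def score_batch(self, x: np.ndarray) -> ClassScores:
        """Score one preprocessed T×3×H×W clip batch."""
        self.eval()
        with no_grad():
            feats = self.backbone(Tensor(x)).data
            if isinstance(self.head, ConsensusHead):
                per_frame = self.head.classify_frames(Tensor(feats)).data
                fused = consensus(per_frame)
            else:
                fused = self.head(Tensor(feats[None])).data[0].astype(np.float64)
                per_frame = np.broadcast_to(fused, (x.shape[0], fused.size)).copy()
        _, probs = predict(fused)
        return ClassScores(per_frame=per_frame, fused=fused, probabilities=probs)


def build_model(
    backbone_cfg: BackboneConfig | None = None,
    head_variant: str = "pbatn",
    class_names: tuple = CLASS_NAMES,
    dropout: float = 0.5,
    gru_hidden: int = 512,
    seed: int = 0,
) -> BehaviorModel:
    """Construct PBATn (consensus head) or PBAn (no shift, GRU head).

    The PBAn ablation removes the temporal relation layer (shift fraction
    forced to 0) and computes temporal information through the GRU instead.
    """
    cfg = backbone_cfg or BackboneConfig()
    if head_variant not in ("pbatn", "pban"):
        raise ValueError(f"head_variant must be 'pbatn' or 'pban', got {head_variant!r}")
    if head_variant == "pban":
        cfg = BackboneConfig.from_dict({**cfg.to_dict(), "shift_fraction": 0.0})
    backbone = Backbone(cfg, seed=seed)
    head_rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    if head_variant == "pbatn":
        head = ConsensusHead(
            cfg.feature_dim, len(class_names), dropout=dropout, rng=head_rng
        )
    else:
        head = GRUHead(
            cfg.feature_dim,
            len(class_names),
            hidden=gru_hidden,
            dropout=dropout,
            rng=head_rng,
        )
    return BehaviorModel(backbone, head, class_names, head_variant)


def save_checkpoint(path: Path, model: BehaviorModel, extra: dict | None = None) -> None:
    meta = {
        "backbone": model.backbone.cfg.to_dict(),
        "head_variant": model.head_variant,
        "class_names": list(model.class_names),
        "dropout": model.head.drop.p,
        "extra": extra or {},
    }
    if isinstance(model.head, GRUHead):
        meta["gru_hidden"] = model.head.hidden
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: Path) -> tuple[BehaviorModel, dict]:
    """Rebuild the model from a checkpoint; returns (model, metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {
            k[len("param/") :]: data[k] for k in data.files if k.startswith("param/")
        }
    model = build_model(
        BackboneConfig.from_dict(meta["backbone"]),
        head_variant=meta["head_variant"],
        class_names=tuple(meta["class_names"]),
        dropout=meta["dropout"],
        gru_hidden=meta.get("gru_hidden", 512),
    )
    model.load_state_dict(state)
    model.eval()
    return model, meta
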