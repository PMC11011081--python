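"""Class-activation heat maps.

The final-stage feature maps (C×h×w per frame) are weighted by the
fully-connected layer's weights for the predicted class, rectified,
min-max normalized to [0,1] per frame, and bilinearly upsampled to the
input resolution — a direct CAM over the consensus head's classifier.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .autograd import Tensor, no_grad
from .data_pipeline import Clip, Normalization, SamplerConfig, clip_to_batch
from .head import ConsensusHead, consensus, predict
from .model import BehaviorModel

__all__ = ["cam_heatmap", "cam_from_batch"]


def cam_from_batch(model: BehaviorModel, x: np.ndarray) -> tuple[np.ndarray, int]:
    """Per-frame saliency maps for a preprocessed T×3×H×W batch.

    Returns (maps, predicted_class) with maps of shape T×H×W in [0, 1].
    """
    if not isinstance(model.head, ConsensusHead):
        raise ValueError("class-activation maps require the consensus (FC) head")
    model.eval()
    t, _, h, w = x.shape
    with no_grad():
        maps, _ = model.backbone.forward_maps(Tensor(np.asarray(x, dtype=np.float32)))
        feats = maps.mean(axis=(2, 3)).data
        per_frame = model.head.classify_frames(Tensor(feats)).data
    cls, _ = predict(consensus(per_frame))
    weights = model.head.fc.weight.data[:, cls]  # C
    raw = np.einsum("tchw,c->thw", maps.data, weights)
    raw = np.maximum(raw, 0.0)
    out = np.empty((t, h, w))
    for i in range(t):
        m = raw[i]
        span = m.max() - m.min()
        m = (m - m.min()) / span if span > 0 else np.zeros_like(m)
        out[i] = ndimage.zoom(m, (h / m.shape[0], w / m.shape[1]), order=1)
    return np.clip(out, 0.0, 1.0), cls


def cam_heatmap(
    model: BehaviorModel,
    clip: Clip,
    target: int = 64,
    normalization: Normalization | None = None,
) -> tuple[np.ndarray, int]:
    """Heat maps for a clip via midpoint segment sampling."""
    sampler = SamplerConfig(
        num_segments=model.backbone.cfg.input_frames, mode="eval"
    )
    x = clip_to_batch(clip, sampler, target=target, normalization=normalization)
    return cam_from_batch(model, x)
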