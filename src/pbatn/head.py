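"""Classification heads.

The consensus head is the default: dropout → fully connected map from the
2048-dim per-frame feature to the 6 behavior classes, then segment
consensus — the arithmetic mean of the 8 per-frame logit vectors — with
softmax applied after fusion.  The loss is the standard cross-entropy,
which for one-hot targets reduces to −log of the true-class probability.

The gated-recurrent head (used by the PBAn ablation, whose backbone runs
with shift fraction 0) replaces consensus with a single-layer GRU over the
frame sequence; the final hidden state is mapped to class logits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .autograd import Tensor, as_tensor, log_softmax, no_grad

__all__ = [
    "ClassScores",
    "ConsensusHead",
    "GRUHead",
    "consensus",
    "cross_entropy",
    "cross_entropy_logits",
    "predict",
    "softmax",
]

EPS_PROB = 1e-12


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = np.asarray(logits, dtype=np.float64)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass
class ClassScores:
    """Per-frame logits, fused clip-level logits, and clip probabilities."""

    per_frame: np.ndarray  # T×K
    fused: np.ndarray  # K
    probabilities: np.ndarray  # K, simplex

    def __post_init__(self):
        total = float(self.probabilities.sum())
        if not np.isfinite(total) or abs(total - 1.0) > 1e-6:
            raise ValueError(f"probabilities sum to {total}, not 1")


def consensus(per_frame: np.ndarray) -> np.ndarray:
    """Fuse T×K per-frame logits into one K-vector by the frame mean."""
    arr = np.asarray(per_frame, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 1:
        raise ValueError(f"expected T×K logits with T ≥ 1, got shape {arr.shape}")
    return arr.mean(axis=0)


def cross_entropy(probabilities: np.ndarray, true_class: int) -> float:
    """−log probability of the true class (one-hot cross-entropy)."""
    p = np.asarray(probabilities, dtype=np.float64)
    if p.ndim != 1:
        raise ValueError("probabilities must be a 1-D simplex vector")
    if not (0 <= true_class < p.size):
        raise ValueError(f"true_class {true_class} outside 0..{p.size - 1}")
    if abs(p.sum() - 1.0) > 1e-6 or np.any(p < -1e-9):
        raise ValueError("probabilities do not form a simplex")
    pt = p[true_class]
    if pt < EPS_PROB:
        warnings.warn(
            f"true-class probability {pt:.3g} clamped to {EPS_PROB}", RuntimeWarning
        )
        pt = EPS_PROB
    return float(-np.log(pt))


def cross_entropy_logits(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Batched mean cross-entropy straight from logits (training loss)."""
    logits = as_tensor(logits)
    labels = np.asarray(labels)
    n, k = logits.shape
    onehot = np.zeros((n, k), dtype=np.float32)
    onehot[np.arange(n), labels] = 1.0
    logp = log_softmax(logits, axis=-1)
    return -(logp * Tensor(onehot)).sum() * (1.0 / n)


def predict(fused: np.ndarray) -> tuple[int, np.ndarray]:
    """Argmax decision (ties to the lowest class index) plus probabilities."""
    fused = np.asarray(fused, dtype=np.float64)
    probs = softmax(fused)
    return int(np.argmax(probs)), probs


class ConsensusHead(nn.Module):
    """Dropout → FC(feature_dim → classes) → mean-over-frames consensus."""

    def __init__(
        self,
        feature_dim: int = 2048,
        num_classes: int = 6,
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.feature_dim = feature_dim
        self.num_classes = num_classes
        self.drop = nn.Dropout(dropout, rng=rng)
        self.fc = nn.Linear(feature_dim, num_classes, rng=rng)

    def classify_frames(self, features: Tensor) -> Tensor:
        """(B×)T×C per-frame features → (B×)T×K per-frame logits."""
        features = as_tensor(features)
        if features.shape[-1] != self.feature_dim:
            raise ValueError(
                f"expected feature dim {self.feature_dim}, got {features.shape[-1]}"
            )
        return self.fc(self.drop(features))

    def forward(self, features: Tensor) -> Tensor:
        """B×T×C features → B×K fused logits."""
        per_frame = self.classify_frames(features)
        return per_frame.mean(axis=-2)

    def score_clip(self, features: np.ndarray) -> ClassScores:
        """Eval-mode scoring of one clip's T×C features."""
        self.eval()
        with no_grad():
            per_frame = self.classify_frames(Tensor(features)).data
        fused = consensus(per_frame)
        _, probs = predict(fused)
        return ClassScores(per_frame=per_frame, fused=fused, probabilities=probs)


class GRUHead(nn.Module):
    """Single-layer GRU over per-frame features; final state → class logits."""

    def __init__(
        self,
        feature_dim: int = 2048,
        num_classes: int = 6,
        hidden: int = 512,
        dropout: float = 0.5,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.feature_dim = feature_dim
        self.num_classes = num_classes
        self.hidden = hidden
        self.drop = nn.Dropout(dropout, rng=rng)
        self.w_zrn = nn.Linear(feature_dim, 3 * hidden, rng=rng)
        self.u_zrn = nn.Linear(hidden, 3 * hidden, bias=False, rng=rng)
        self.fc = nn.Linear(hidden, num_classes, rng=rng)

    def forward(self, features: Tensor) -> Tensor:
        """B×T×C features → B×K logits from the final hidden state."""
        features = as_tensor(features)
        if features.ndim == 2:
            features = features.reshape((1,) + features.shape)
        b, t, c = features.shape
        if c != self.feature_dim:
            raise ValueError(f"expected feature dim {self.feature_dim}, got {c}")
        hdim = self.hidden
        h = Tensor(np.zeros((b, hdim), dtype=np.float32))
        for step in range(t):
            x_t = self.drop(features[:, step])
            gx = self.w_zrn(x_t)
            gh = self.u_zrn(h)
            z = (gx[:, :hdim] + gh[:, :hdim]).sigmoid()
            r = (gx[:, hdim : 2 * hdim] + gh[:, hdim : 2 * hdim]).sigmoid()
            n = (gx[:, 2 * hdim :] + r * gh[:, 2 * hdim :]).tanh()
            h = (1.0 - z) * n + z * h
        return self.fc(h)

    def score_clip(self, features: np.ndarray) -> ClassScores:
        self.eval()
        with no_grad():
            fused = self.forward(Tensor(features)).data[0].astype(np.float64)
        _, probs = predict(fused)
        # the GRU has no meaningful per-frame logits; repeat the fused vector
        per_frame = np.broadcast_to(fused, (features.shape[0], fused.size)).copy()
        return ClassScores(per_frame=per_frame, fused=fused, probabilities=probs)


def gru_reference(features: np.ndarray, w: np.ndarray, u: np.ndarray, b: np.ndarray):
    """Plain-numpy unrolled GRU recurrence (independent oracle for tests).

    ``w``: C×3H input weights, ``u``: H×3H recurrent weights, ``b``: 3H bias.
    """
    hdim = u.shape[0]
    h = np.zeros(hdim)

    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    for x_t in features:
        gx = x_t @ w + b
        gh = h @ u
        z = sig(gx[:hdim] + gh[:hdim])
        r = sig(gx[hdim : 2 * hdim] + gh[hdim : 2 * hdim])
        n = np.tanh(gx[2 * hdim :] + r * gh[2 * hdim :])
        h = (1 - z) * n + z * h
    return h
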