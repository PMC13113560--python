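"""Confidence-ranked Top-K mean pooling of frame-level clip features.

A video clip is represented by N frame features and frame logits from the
frozen visual branch. Each frame's confidence is the maximum softmax
probability of its logits; the k most confident frames are selected (ties
broken toward the smaller frame index, for determinism) and their features
and logits are mean-pooled into the clip-level representation. Still images
are 1-frame clips with k = 1.

Pooling logits happens in logit space, so the confidence of the pooled
logits generally differs from the mean of the frame confidences (Jensen);
that is expected, not a bug.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FrameFeatureSet",
    "ConfidenceVector",
    "KeyFrameSet",
    "ClipRepresentation",
    "frame_confidences",
    "select_topk",
    "aggregate_clip",
    "sample_frame_indices",
    "sample_frames",
    "pool_clip",
]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Overflow-safe softmax (max-subtracted)."""
    logits = np.asarray(logits, dtype=np.float64)
    with np.errstate(invalid="ignore"):  # inf logits propagate as nan
        shifted = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


@dataclass(frozen=True)
class FrameFeatureSet:
    """Per-frame features (N x D) and logits (N x C) of one clip."""

    features: np.ndarray
    logits: np.ndarray
    frame_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        features = np.asarray(self.features, dtype=np.float64)
        logits = np.asarray(self.logits, dtype=np.float64)
        if features.ndim != 2 or logits.ndim != 2:
            raise ValueError("features and logits must be 2-D")
        if features.shape[0] != logits.shape[0]:
            raise ValueError("features and logits must have one row per frame")
        if features.shape[0] < 1:
            raise ValueError("a clip needs at least one frame")
        if not (np.all(np.isfinite(features)) and np.all(np.isfinite(logits))):
            raise ValueError("non-finite frame features or logits")
        idx = self.frame_indices
        idx = np.arange(features.shape[0]) if idx is None else np.asarray(idx)
        object.__setattr__(self, "features", features)
        object.__setattr__(self, "logits", logits)
        object.__setattr__(self, "frame_indices", idx)

    @property
    def n_frames(self) -> int:
        return self.features.shape[0]


@dataclass(frozen=True)
class ConfidenceVector:
    """Per-frame max-softmax confidences, each in [1/C, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1:
            raise ValueError("confidences must be 1-D")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class KeyFrameSet:
    """Indices of the selected key frames (sorted ascending)."""

    indices: np.ndarray
    k: int

    def __post_init__(self) -> None:
        indices = np.sort(np.asarray(self.indices, dtype=np.intp))
        if np.unique(indices).size != indices.size:
            raise ValueError("key-frame indices must be distinct")
        object.__setattr__(self, "indices", indices)


@dataclass(frozen=True)
class ClipRepresentation:
    """Clip-level pooled feature (D,) and logits (C,)."""

    feature: np.ndarray
    logits: np.ndarray


def frame_confidences(f: FrameFeatureSet) -> ConfidenceVector:
    """Max class probability of each frame's logits."""
    probs = softmax(f.logits, axis=1)
    return ConfidenceVector(values=probs.max(axis=1))


def select_topk(c: ConfidenceVector | np.ndarray, k: int) -> KeyFrameSet:
    """Indices of the ``min(k, N)`` largest confidences; ties -> lower index.

    Implemented as a stable descending sort, which is equivalent to
    exhaustively maximizing total selected confidence under the
    lowest-index tie rule.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    values = c.values if isinstance(c, ConfidenceVector) else np.asarray(c, dtype=np.float64)
    n = values.size
    order = np.argsort(-values, kind="stable")
    return KeyFrameSet(indices=order[: min(k, n)], k=k)


def aggregate_clip(
    f: FrameFeatureSet, s: KeyFrameSet, aggregation: str = "mean"
) -> ClipRepresentation:
    """Pool selected frames' features and logits (mean, or elementwise max)."""
    if s.indices.size == 0:
        raise ValueError("cannot aggregate an empty key-frame set")
    if s.indices.max() >= f.n_frames:
        raise ValueError("key-frame index out of range for clip")
    if aggregation == "mean":
        feature = f.features[s.indices].mean(axis=0)
        logits = f.logits[s.indices].mean(axis=0)
    elif aggregation == "max":
        feature = f.features[s.indices].max(axis=0)
        logits = f.logits[s.indices].max(axis=0)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r} (use 'mean' or 'max')")
    return ClipRepresentation(feature=feature, logits=logits)


def sample_frame_indices(clip_length: int, n_frames: int = 10) -> np.ndarray:
    """Endpoint-inclusive uniform frame indices.

    Rounds an arithmetic progression from 0 to ``clip_length - 1`` with
    ``n_frames`` points; clips shorter than ``n_frames`` return every frame.
    """
    if clip_length < 1:
        raise ValueError("clip must be nonempty")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if clip_length <= n_frames:
        return np.arange(clip_length)
    return np.rint(np.linspace(0, clip_length - 1, n_frames)).astype(np.intp)


def sample_frames(clip: Sequence, n_frames: int = 10) -> list:
    """Uniformly subsample an ordered frame collection."""
    idx = sample_frame_indices(len(clip), n_frames)
    return [clip[i] for i in idx]


def pool_clip(
    f: FrameFeatureSet, k: int = 5, aggregation: str = "mean"
) -> ClipRepresentation:
    """Confidence -> Top-K -> aggregate, in one call. k > N clamps to N."""
    conf = frame_confidences(f)
    s = select_topk(conf, k)
    return aggregate_clip(f, s, aggregation=aggregation)
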