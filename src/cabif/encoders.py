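"""Frozen encoder contract and deterministic toy encoders.

The fusion core never trains feature extractors: each modality supplies a
frozen ``encode`` (item -> D-dim feature) and ``classify`` (feature -> C-dim
logits). Any pretrained backbone can be wrapped to satisfy the contract; the
toy prototype encoder shipped here makes the full pipeline testable without
trained weights. Its logits are the negative half squared distance to fixed
class prototypes, a valid (Gaussian-generative) logit model.

Adapter notes for real backbones: input-side conventions (image resizing,
channel normalization, spectrogram shaping) belong to the wrapped encoder,
not to the fusion core; the core only sees (feature, logits) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "EncoderContract",
    "ModalityOutput",
    "ToyPrototypeEncoder",
    "apply_encoder",
    "make_toy_encoder",
    "make_toy_encoder_from_prototypes",
]


@dataclass(frozen=True)
class ModalityOutput:
    """One modality's pooled feature and logits for a single sample."""

    feature: np.ndarray  # (D,)
    logits: np.ndarray  # (C,)
    modality: str = "visual"

    def __post_init__(self) -> None:
        feature = np.asarray(self.feature, dtype=np.float64)
        logits = np.asarray(self.logits, dtype=np.float64)
        if feature.ndim != 1 or logits.ndim != 1:
            raise ValueError("feature and logits must be 1-D")
        if not (np.all(np.isfinite(feature)) and np.all(np.isfinite(logits))):
            raise ValueError("non-finite encoder output")
        object.__setattr__(self, "feature", feature)
        object.__setattr__(self, "logits", logits)


@dataclass
class EncoderContract:
    """A frozen per-modality encoder: ``encode`` + ``classify`` + dimensions.

    ``frozen`` documents the training-time contract (parameters never
    update); it is not Python-level immutability.
    """

    feature_dim: int
    num_classes: int
    encode: Callable[[object], np.ndarray]
    classify: Callable[[np.ndarray], np.ndarray]
    modality: str = "visual"
    frozen: bool = field(default=True)


def apply_encoder(item: object, enc: EncoderContract) -> ModalityOutput:
    """Run ``item`` through a frozen encoder, checking the contract's shapes."""
    feature = np.asarray(enc.encode(item), dtype=np.float64)
    if feature.shape != (enc.feature_dim,):
        raise ValueError(
            f"encoder contract violation: encode returned shape {feature.shape}, "
            f"expected ({enc.feature_dim},)"
        )
    logits = np.asarray(enc.classify(feature), dtype=np.float64)
    if logits.shape != (enc.num_classes,):
        raise ValueError(
            f"encoder contract violation: classify returned shape {logits.shape}, "
            f"expected ({enc.num_classes},)"
        )
    return ModalityOutput(feature=feature, logits=logits, modality=enc.modality)


class ToyPrototypeEncoder(EncoderContract):
    """Nearest-prototype encoder over fixed, seeded class prototypes.

    ``encode`` is the identity on D-dim embedding items (2-D toy media are
    flattened through a fixed seeded random projection); ``classify`` returns
    -0.5 * ||f - mu_k||^2 per class k.
    """

    def __init__(self, prototypes: np.ndarray, modality: str = "visual", seed: int = 0):
        prototypes = np.asarray(prototypes, dtype=np.float64)
        if prototypes.ndim != 2:
            raise ValueError("prototypes must be (num_classes, feature_dim)")
        self.prototypes = prototypes
        num_classes, feature_dim = prototypes.shape
        self._projection_seed = seed
        self._projections: dict[int, np.ndarray] = {}
        super().__init__(
            feature_dim=feature_dim,
            num_classes=num_classes,
            encode=self._encode,
            classify=self._classify,
            modality=modality,
        )

    def _encode(self, item: object) -> np.ndarray:
        x = np.asarray(item, dtype=np.float64)
        if x.ndim == 1 and x.size == self.feature_dim:
            return x
        flat = x.ravel()
        proj = self._projections.get(flat.size)
        if proj is None:
            rng = np.random.default_rng([self._projection_seed, flat.size])
            proj = rng.normal(size=(self.feature_dim, flat.size)) / np.sqrt(flat.size)
            self._projections[flat.size] = proj
        return proj @ flat

    def _classify(self, feature: np.ndarray) -> np.ndarray:
        feature = np.asarray(feature, dtype=np.float64)
        if feature.ndim == 1:
            return self.classify_batch(feature[None, :])[0]
        return self.classify_batch(feature)

    def classify_batch(self, features: np.ndarray) -> np.ndarray:
        """Vectorized logits for a (n, D) feature matrix."""
        features = np.asarray(features, dtype=np.float64)
        diff = features[:, None, :] - self.prototypes[None, :, :]
        return -0.5 * np.einsum("nkd,nkd->nk", diff, diff)


def make_toy_encoder(
    num_classes: int,
    feature_dim: int,
    prototype_scale: float = 3.0,
    seed: int = 0,
    modality: str = "visual",
) -> ToyPrototypeEncoder:
    """Seeded toy encoder with equal-energy class prototypes.

    Prototypes are uniform random directions scaled to norm
    ``prototype_scale`` (scale 0 collapses them all to the origin, giving
    uniform logits). Equal energy keeps the softmax of distance logits free
    of per-class norm biases, so separability is controlled by scale alone.
    """
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    if feature_dim < 2:
        raise ValueError("feature_dim must be >= 2")
    rng = np.random.default_rng([seed, 0 if modality == "visual" else 1])
    directions = rng.normal(size=(num_classes, feature_dim))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    prototypes = prototype_scale * directions / norms
    return ToyPrototypeEncoder(prototypes, modality=modality, seed=seed)


def make_toy_encoder_from_prototypes(
    prototypes: np.ndarray, modality: str = "visual", seed: int = 0
) -> ToyPrototypeEncoder:
    """Wrap an existing prototype matrix (e.g. the synthetic generator's)."""
    return ToyPrototypeEncoder(prototypes, modality=modality, seed=seed)
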