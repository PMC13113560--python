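"""Confidence calibration: temperature scaling and power-law modality weights.

Per sample, each modality's logits are temperature-scaled and softmaxed
(p = softmax(z / T)); the maximum calibrated probability is that modality's
confidence c. The visual fusion weight is the power-law normalization

    wv = cv**alpha / (cv**alpha + ca**alpha),      wa = 1 - wv.

Tv, Ta and alpha are learnable scalars, all initialized to 1 and updated by
backpropagation together with the fusion parameters. Temperatures > 1
flatten a distribution (more conservative confidence) without changing the
class ranking; alpha > 1 sharpens the weight split toward the more
confident modality, alpha < 1 evens it out.

Positivity is enforced by projection: after every optimizer step the
scalars are clamped to [t_min, t_max] and [alpha_min, alpha_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .topk_pooling import softmax

__all__ = [
    "CalibratorParams",
    "CalibratedDistributions",
    "ModalityWeights",
    "temperature_softmax",
    "modality_confidences",
    "confidence_weights",
    "calibrate",
]

T_MIN, T_MAX = 0.05, 20.0
ALPHA_MIN, ALPHA_MAX = 0.1, 10.0


@dataclass
class CalibratorParams:
    """Learnable scalars (Tv, Ta, alpha), stored as 0-d arrays so the
    optimizer can update them in place."""

    tv: np.ndarray = field(default_factory=lambda: np.array(1.0))
    ta: np.ndarray = field(default_factory=lambda: np.array(1.0))
    alpha: np.ndarray = field(default_factory=lambda: np.array(1.0))
    t_min: float = T_MIN
    t_max: float = T_MAX
    alpha_min: float = ALPHA_MIN
    alpha_max: float = ALPHA_MAX

    def __post_init__(self) -> None:
        self.tv = np.asarray(self.tv, dtype=np.float64)
        self.ta = np.asarray(self.ta, dtype=np.float64)
        self.alpha = np.asarray(self.alpha, dtype=np.float64)
        if float(self.tv) <= 0 or float(self.ta) <= 0:
            raise ValueError("temperatures must be positive")
        if float(self.alpha) <= 0:
            raise ValueError("alpha must be positive")

    def clamp(self) -> None:
        """Project the scalars back into their bounds (call after each step)."""
        self.tv[...] = np.clip(self.tv, self.t_min, self.t_max)
        self.ta[...] = np.clip(self.ta, self.t_min, self.t_max)
        self.alpha[...] = np.clip(self.alpha, self.alpha_min, self.alpha_max)


@dataclass(frozen=True)
class CalibratedDistributions:
    """Temperature-calibrated class distributions, one per modality."""

    pv: np.ndarray
    pa: np.ndarray


@dataclass(frozen=True)
class ModalityWeights:
    """Calibrated confidences and the normalized fusion weights."""

    cv: np.ndarray | float
    ca: np.ndarray | float
    wv: np.ndarray | float
    wa: np.ndarray | float


def temperature_softmax(
    zv: np.ndarray, za: np.ndarray, params: CalibratorParams
) -> CalibratedDistributions:
    """``pv = softmax(zv / Tv)``, ``pa = softmax(za / Ta)`` (1-D or batched)."""
    tv, ta = float(params.tv), float(params.ta)
    if tv <= 0 or ta <= 0:
        raise ValueError("temperatures must be positive")
    zv = np.asarray(zv, dtype=np.float64)
    za = np.asarray(za, dtype=np.float64)
    if not (np.all(np.isfinite(zv)) and np.all(np.isfinite(za))):
        raise ValueError("non-finite logits")
    return CalibratedDistributions(pv=softmax(zv / tv), pa=softmax(za / ta))


def modality_confidences(d: CalibratedDistributions):
    """Each modality's confidence = max of its calibrated distribution."""
    return d.pv.max(axis=-1), d.pa.max(axis=-1)


def confidence_weights(cv, ca, alpha: float = 1.0) -> ModalityWeights:
    """Power-law normalized weights; ``wv + wa == 1`` by construction."""
    cv = np.asarray(cv, dtype=np.float64)
    ca = np.asarray(ca, dtype=np.float64)
    if np.any(cv <= 0) or np.any(ca <= 0):
        raise ValueError("confidences must be positive")
    cva, caa = cv**alpha, ca**alpha
    wv = cva / (cva + caa)
    return ModalityWeights(cv=cv, ca=ca, wv=wv, wa=1.0 - wv)


def calibrate(
    zv: np.ndarray, za: np.ndarray, params: CalibratorParams
) -> ModalityWeights:
    """Full calibration chain: temperature softmax -> max -> power-law weights."""
    d = temperature_softmax(zv, za, params)
    cv, ca = modality_confidences(d)
    return confidence_weights(cv, ca, float(params.alpha))
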