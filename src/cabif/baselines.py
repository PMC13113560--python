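"""Simple audio-visual fusion baselines for the comparison harness.

Four strategies at increasing capacity:

- ``logit_avg``: average the two modalities' logits (parameter-free);
- ``score_fusion``: average the two softmax probability vectors
  (parameter-free);
- ``concat``: LayerNorm over the concatenated features, then a linear head
  (trainable);
- ``shared_fusion``: LayerNorm-concat through a shared Linear(2D, H) -> SiLU
  trunk, then a linear head (trainable).

All baselines consume the same per-sample (feature, logits) pair per
modality as the full fusion net and expose the same ``FusedOutput``
prediction contract, so the comparison harness swaps methods freely. For
clip inputs, frame aggregation happens upstream via Top-K mean pooling, the
same module the full model uses.
"""

from __future__ import annotations

import numpy as np

from .bif_fusion import FusedOutput, _linear_init, _ln_forward, _ln_backward, _silu, _silu_grad
from .topk_pooling import softmax

__all__ = [
    "fuse_logit_avg",
    "fuse_score_avg",
    "ConcatBaseline",
    "SharedFusionBaseline",
    "build_trainable_baseline",
]

LOG_GUARD = 1e-12


def _as_output(z: np.ndarray, p: np.ndarray | None = None, phi=None) -> FusedOutput:
    p = softmax(z) if p is None else p
    y_hat = np.argmax(z, axis=-1)
    if z.ndim == 1:
        return FusedOutput(phi=phi, z_fuse=z, y_hat=int(y_hat), p_fuse=p,
                           fused_confidence=float(p.max()))
    return FusedOutput(phi=phi, z_fuse=z, y_hat=y_hat, p_fuse=p,
                       fused_confidence=p.max(axis=-1))


def fuse_logit_avg(zv: np.ndarray, za: np.ndarray) -> FusedOutput:
    """Elementwise mean of the two logit vectors."""
    zv = np.asarray(zv, dtype=np.float64)
    za = np.asarray(za, dtype=np.float64)
    if zv.shape != za.shape:
        raise ValueError(f"logit shape mismatch: {zv.shape} vs {za.shape}")
    return _as_output((zv + za) / 2.0)


def fuse_score_avg(zv: np.ndarray, za: np.ndarray) -> FusedOutput:
    """Mean of the two softmax distributions; logits reported as log(p)."""
    zv = np.asarray(zv, dtype=np.float64)
    za = np.asarray(za, dtype=np.float64)
    if zv.shape != za.shape:
        raise ValueError(f"logit shape mismatch: {zv.shape} vs {za.shape}")
    p = (softmax(zv) + softmax(za)) / 2.0
    return _as_output(np.log(np.maximum(p, LOG_GUARD)), p=p)


class ConcatBaseline:
    """LayerNorm(concat(fv, fa)) -> linear head. Trainable."""

    name = "concat"

    def __init__(self, D: int, C: int, seed: int = 0):
        rng = np.random.default_rng([seed, 11])
        self.D, self.C = D, C
        W, b = _linear_init(rng, C, 2 * D)
        self.params = {
            "g": np.ones(2 * D), "b": np.zeros(2 * D), "W": W, "bh": b,
        }

    DECAY_KEYS = ("W",)
    CALIBRATOR_KEYS = ()

    def param_dict(self):
        return self.params

    def forward(self, fv, fa, zv=None, za=None) -> dict:
        fv = np.atleast_2d(np.asarray(fv, dtype=np.float64))
        fa = np.atleast_2d(np.asarray(fa, dtype=np.float64))
        cat = np.concatenate([fv, fa], axis=1)
        phi, xhat, ivar = _ln_forward(cat, self.params["g"], self.params["b"])
        z = phi @ self.params["W"].T + self.params["bh"]
        p = softmax(z, axis=1)
        out = FusedOutput(phi=phi, z_fuse=z, y_hat=np.argmax(z, axis=1),
                          p_fuse=p, fused_confidence=p.max(axis=1))
        return dict(out=out, phi=phi, xhat=xhat, ivar=ivar)

    def backward(self, cache: dict, dz: np.ndarray) -> dict:
        grads = {"W": dz.T @ cache["phi"], "bh": dz.sum(axis=0)}
        dphi = dz @ self.params["W"]
        _, grads["g"], grads["b"] = _ln_backward(
            dphi, cache["xhat"], cache["ivar"], self.params["g"]
        )
        return grads

    def predict(self, fv, fa, zv=None, za=None) -> FusedOutput:
        return self.forward(fv, fa)["out"]


class SharedFusionBaseline:
    """LayerNorm(concat) -> shared Linear(2D, H) -> SiLU -> head. Trainable."""

    name = "shared_fusion"

    def __init__(self, D: int, C: int, H: int | None = None, seed: int = 0):
        if H is None:
            H = max(D // 2, 1)
        rng = np.random.default_rng([seed, 13])
        self.D, self.C, self.H = D, C, H
        W1, b1 = _linear_init(rng, H, 2 * D)
        W2, b2 = _linear_init(rng, C, H)
        self.params = {
            "g": np.ones(2 * D), "b": np.zeros(2 * D),
            "W1": W1, "b1": b1, "W2": W2, "b2": b2,
        }

    DECAY_KEYS = ("W1", "W2")
    CALIBRATOR_KEYS = ()

    def param_dict(self):
        return self.params

    def forward(self, fv, fa, zv=None, za=None) -> dict:
        fv = np.atleast_2d(np.asarray(fv, dtype=np.float64))
        fa = np.atleast_2d(np.asarray(fa, dtype=np.float64))
        cat = np.concatenate([fv, fa], axis=1)
        phi, xhat, ivar = _ln_forward(cat, self.params["g"], self.params["b"])
        h = phi @ self.params["W1"].T + self.params["b1"]
        u = _silu(h)
        z = u @ self.params["W2"].T + self.params["b2"]
        p = softmax(z, axis=1)
        out = FusedOutput(phi=phi, z_fuse=z, y_hat=np.argmax(z, axis=1),
                          p_fuse=p, fused_confidence=p.max(axis=1))
        return dict(out=out, phi=phi, xhat=xhat, ivar=ivar, h=h, u=u)

    def backward(self, cache: dict, dz: np.ndarray) -> dict:
        grads = {"W2": dz.T @ cache["u"], "b2": dz.sum(axis=0)}
        dh = (dz @ self.params["W2"]) * _silu_grad(cache["h"])
        grads["W1"] = dh.T @ cache["phi"]
        grads["b1"] = dh.sum(axis=0)
        dphi = dh @ self.params["W1"]
        _, grads["g"], grads["b"] = _ln_backward(
            dphi, cache["xhat"], cache["ivar"], self.params["g"]
        )
        return grads

    def predict(self, fv, fa, zv=None, za=None) -> FusedOutput:
        return self.forward(fv, fa)["out"]


def build_trainable_baseline(name: str, D: int, C: int, H: int | None = None,
                             seed: int = 0):
    """Construct a trainable baseline by name (``concat`` or ``shared_fusion``)."""
    if name == "concat":
        return ConcatBaseline(D, C, seed=seed)
    if name == "shared_fusion":
        return SharedFusionBaseline(D, C, H=H, seed=seed)
    raise ValueError(f"unknown trainable baseline {name!r}")
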