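"""Bidirectional Inter-modulation Fusion (BIF) with reliability weighting.

Both modality features are layer-normalized, then each side generates a
bounded modulation signal for the other through a lightweight MLP
(Linear(D, H) -> SiLU -> Linear(H, D)) squashed by tanh, so every signal
entry lies strictly inside (-1, 1). The signals are injected as residuals
scaled by the per-sample modality weights from the calibration module:

    as_published (default):  fv_cm = fv_n + wv * sa,   fa_cm = fa_n + wa * sv
    crossed:                 fv_cm = fv_n + wv * sv,   fa_cm = fa_n + wa * sa

``sv`` is generated from the audio feature and ``sa`` from the visual one.
The published pairing routes each modality's own-derived signal back into
its own stream; the "crossed" variant implements the cross-correction
reading and is exposed behind a flag rather than silently substituted.

The modulated features are concatenated (length 2D), layer-normalized and
classified by a linear head. Because |signal| < 1 and the scalar weight
w <= 1, the modulation perturbs each normalized feature by at most w in
max-norm — fusion can never erase a modality, only nudge it.

:class:`CabifNet` bundles the calibrator and fusion parameters with a
manual forward/backward pass (pure NumPy); gradients are checked against
finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import CalibratorParams
from .topk_pooling import softmax

__all__ = [
    "LN_EPS",
    "FusionParams",
    "NormalizedFeatures",
    "ModulationSignals",
    "ModulatedFeatures",
    "FusedOutput",
    "layer_normalize",
    "modulation_signals",
    "inter_modulate",
    "fuse_and_classify",
    "CabifNet",
]

LN_EPS = 1e-5
VARIANTS = ("as_published", "crossed")


def _linear_init(rng: np.random.Generator, fan_out: int, fan_in: int):
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_out, fan_in))
    b = rng.uniform(-bound, bound, size=fan_out)
    return w, b


@dataclass
class FusionParams:
    """All learnable fusion parameters (NumPy arrays, updated in place).

    Layout: two modulation MLPs (audio->visual and visual->audio), three
    layer-norm affines (per-modality inputs and the fused vector) and the
    linear classification head over the 2D concatenation.
    """

    D: int
    H: int
    C: int
    W1_a2v: np.ndarray
    b1_a2v: np.ndarray
    W2_a2v: np.ndarray
    b2_a2v: np.ndarray
    W1_v2a: np.ndarray
    b1_v2a: np.ndarray
    W2_v2a: np.ndarray
    b2_v2a: np.ndarray
    g_v: np.ndarray
    b_v: np.ndarray
    g_a: np.ndarray
    b_a: np.ndarray
    g_f: np.ndarray
    b_f: np.ndarray
    W_head: np.ndarray
    b_head: np.ndarray

    @classmethod
    def initialize(
        cls,
        D: int,
        C: int,
        H: int | None = None,
        seed: int = 0,
        zero_init_last: bool = False,
    ) -> "FusionParams":
        """Fan-in uniform init; ``zero_init_last`` zeroes the MLPs' output
        layers so training starts at the degenerate LayerNorm-concat point."""
        if H is None:
            H = max(D // 4, 1)
        rng = np.random.default_rng([seed, 97])
        W1a, b1a = _linear_init(rng, H, D)
        W2a, b2a = _linear_init(rng, D, H)
        W1v, b1v = _linear_init(rng, H, D)
        W2v, b2v = _linear_init(rng, D, H)
        Wh, bh = _linear_init(rng, C, 2 * D)
        if zero_init_last:
            W2a, b2a = np.zeros((D, H)), np.zeros(D)
            W2v, b2v = np.zeros((D, H)), np.zeros(D)
        return cls(
            D=D, H=H, C=C,
            W1_a2v=W1a, b1_a2v=b1a, W2_a2v=W2a, b2_a2v=b2a,
            W1_v2a=W1v, b1_v2a=b1v, W2_v2a=W2v, b2_v2a=b2v,
            g_v=np.ones(D), b_v=np.zeros(D),
            g_a=np.ones(D), b_a=np.zeros(D),
            g_f=np.ones(2 * D), b_f=np.zeros(2 * D),
            W_head=Wh, b_head=bh,
        )

    def as_dict(self) -> dict[str, np.ndarray]:
        """Name -> array views (shared storage, for the optimizer)."""
        return {
            k: getattr(self, k)
            for k in (
                "W1_a2v", "b1_a2v", "W2_a2v", "b2_a2v",
                "W1_v2a", "b1_v2a", "W2_v2a", "b2_v2a",
                "g_v", "b_v", "g_a", "b_a", "g_f", "b_f",
                "W_head", "b_head",
            )
        }


@dataclass(frozen=True)
class NormalizedFeatures:
    fv_n: np.ndarray
    fa_n: np.ndarray


@dataclass(frozen=True)
class ModulationSignals:
    sv: np.ndarray
    sa: np.ndarray


@dataclass(frozen=True)
class ModulatedFeatures:
    fv_cm: np.ndarray
    fa_cm: np.ndarray


@dataclass(frozen=True)
class FusedOutput:
    """Fused vector, logits, argmax prediction and fused confidence."""

    phi: np.ndarray | None
    z_fuse: np.ndarray
    y_hat: np.ndarray | int
    p_fuse: np.ndarray
    fused_confidence: np.ndarray | float


def _ln_forward(x: np.ndarray, gain: np.ndarray, bias: np.ndarray):
    """Standardize over the last axis (eps-guarded), then affine."""
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    ivar = 1.0 / np.sqrt(var + LN_EPS)
    xhat = (x - mu) * ivar
    return gain * xhat + bias, xhat, ivar


def _ln_backward(dy: np.ndarray, xhat: np.ndarray, ivar: np.ndarray, gain: np.ndarray):
    dgain = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    dbias = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * gain
    dx = ivar * (
        dxhat
        - dxhat.mean(axis=-1, keepdims=True)
        - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
    )
    return dx, dgain, dbias


def _silu(x: np.ndarray) -> np.ndarray:
    return x / (1.0 + np.exp(-x))


def _silu_grad(x: np.ndarray) -> np.ndarray:
    s = 1.0 / (1.0 + np.exp(-x))
    return s * (1.0 + x * (1.0 - s))


def layer_normalize(
    fv: np.ndarray, fa: np.ndarray, params: FusionParams
) -> NormalizedFeatures:
    """Per-vector layer normalization of both modality features."""
    fv = np.asarray(fv, dtype=np.float64)
    fa = np.asarray(fa, dtype=np.float64)
    if not (np.all(np.isfinite(fv)) and np.all(np.isfinite(fa))):
        raise ValueError("non-finite features")
    fv_n, _, _ = _ln_forward(fv, params.g_v, params.b_v)
    fa_n, _, _ = _ln_forward(fa, params.g_a, params.b_a)
    return NormalizedFeatures(fv_n=fv_n, fa_n=fa_n)


def modulation_signals(
    n: NormalizedFeatures, params: FusionParams
) -> ModulationSignals:
    """tanh-bounded cross-modal signals: sv from audio, sa from visual."""
    h_av = n.fa_n @ params.W1_a2v.T + params.b1_a2v
    sv = np.tanh(_silu(h_av) @ params.W2_a2v.T + params.b2_a2v)
    h_va = n.fv_n @ params.W1_v2a.T + params.b1_v2a
    sa = np.tanh(_silu(h_va) @ params.W2_v2a.T + params.b2_v2a)
    return ModulationSignals(sv=sv, sa=sa)


def inter_modulate(
    n: NormalizedFeatures,
    s: ModulationSignals,
    weights,
    variant: str = "as_published",
) -> ModulatedFeatures:
    """Inject weighted residual modulation signals into each stream.

    ``weights`` is a ModalityWeights (or any object with wv/wa); scalar
    weights broadcast over the feature dimension.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown fusion variant {variant!r}; choose from {VARIANTS}")
    wv = np.asarray(weights.wv, dtype=np.float64)
    wa = np.asarray(weights.wa, dtype=np.float64)
    if n.fv_n.ndim == 2 and wv.ndim == 1:
        wv, wa = wv[:, None], wa[:, None]
    if variant == "as_published":
        return ModulatedFeatures(fv_cm=n.fv_n + wv * s.sa, fa_cm=n.fa_n + wa * s.sv)
    return ModulatedFeatures(fv_cm=n.fv_n + wv * s.sv, fa_cm=n.fa_n + wa * s.sa)


def fuse_and_classify(m: ModulatedFeatures, params: FusionParams) -> FusedOutput:
    """Concat -> LayerNorm -> linear head -> softmax / argmax."""
    cat = np.concatenate([m.fv_cm, m.fa_cm], axis=-1)
    phi, _, _ = _ln_forward(cat, params.g_f, params.b_f)
    z = phi @ params.W_head.T + params.b_head
    p = softmax(z)
    y_hat = np.argmax(z, axis=-1)  # np.argmax breaks ties toward lower index
    if z.ndim == 1:
        return FusedOutput(
            phi=phi, z_fuse=z, y_hat=int(y_hat), p_fuse=p,
            fused_confidence=float(p.max()),
        )
    return FusedOutput(
        phi=phi, z_fuse=z, y_hat=y_hat, p_fuse=p,
        fused_confidence=p.max(axis=-1),
    )


class CabifNet:
    """The trainable fusion head: calibrator + BIF + linear classifier.

    Encoders stay outside (frozen); the net consumes per-sample modality
    features (fv, fa) and logits (zv, za). ``forward`` caches every
    intermediate needed by ``backward``, which returns gradients for all
    fusion parameters and the three calibrator scalars.
    """

    def __init__(
        self,
        D: int,
        C: int,
        H: int | None = None,
        variant: str = "as_published",
        seed: int = 0,
        zero_init_last: bool = False,
    ):
        if variant not in VARIANTS:
            raise ValueError(f"unknown fusion variant {variant!r}")
        self.fusion = FusionParams.initialize(
            D, C, H=H, seed=seed, zero_init_last=zero_init_last
        )
        self.calib = CalibratorParams()
        self.variant = variant

    # -- parameter plumbing ------------------------------------------------
    def param_dict(self) -> dict[str, np.ndarray]:
        d = self.fusion.as_dict()
        d.update(Tv=self.calib.tv, Ta=self.calib.ta, alpha=self.calib.alpha)
        return d

    CALIBRATOR_KEYS = ("Tv", "Ta", "alpha")
    DECAY_KEYS = ("W1_a2v", "W2_a2v", "W1_v2a", "W2_v2a", "W_head")

    # -- forward -----------------------------------------------------------
    def forward(self, fv, fa, zv, za) -> dict:
        """Batched forward pass; returns a cache dict (key ``out``: FusedOutput)."""
        fv = np.atleast_2d(np.asarray(fv, dtype=np.float64))
        fa = np.atleast_2d(np.asarray(fa, dtype=np.float64))
        zv = np.atleast_2d(np.asarray(zv, dtype=np.float64))
        za = np.atleast_2d(np.asarray(za, dtype=np.float64))
        B = fv.shape[0]
        tv, ta = float(self.calib.tv), float(self.calib.ta)
        alpha = float(self.calib.alpha)

        # calibration
        pv = softmax(zv / tv, axis=1)
        pa = softmax(za / ta, axis=1)
        jv = np.argmax(zv, axis=1)
        ja = np.argmax(za, axis=1)
        cv = pv[np.arange(B), jv]
        ca = pa[np.arange(B), ja]
        cva, caa = cv**alpha, ca**alpha
        wv = cva / (cva + caa)
        wa = 1.0 - wv

        # fusion trunk
        fv_n, xhat_v, ivar_v = _ln_forward(fv, self.fusion.g_v, self.fusion.b_v)
        fa_n, xhat_a, ivar_a = _ln_forward(fa, self.fusion.g_a, self.fusion.b_a)
        h_av = fa_n @ self.fusion.W1_a2v.T + self.fusion.b1_a2v
        u_av = _silu(h_av)
        m_av = u_av @ self.fusion.W2_a2v.T + self.fusion.b2_a2v
        sv = np.tanh(m_av)
        h_va = fv_n @ self.fusion.W1_v2a.T + self.fusion.b1_v2a
        u_va = _silu(h_va)
        m_va = u_va @ self.fusion.W2_v2a.T + self.fusion.b2_v2a
        sa = np.tanh(m_va)

        if self.variant == "as_published":
            fv_cm = fv_n + wv[:, None] * sa
            fa_cm = fa_n + wa[:, None] * sv
        else:
            fv_cm = fv_n + wv[:, None] * sv
            fa_cm = fa_n + wa[:, None] * sa

        cat = np.concatenate([fv_cm, fa_cm], axis=1)
        phi, xhat_f, ivar_f = _ln_forward(cat, self.fusion.g_f, self.fusion.b_f)
        z = phi @ self.fusion.W_head.T + self.fusion.b_head
        p = softmax(z, axis=1)
        out = FusedOutput(
            phi=phi, z_fuse=z, y_hat=np.argmax(z, axis=1), p_fuse=p,
            fused_confidence=p.max(axis=1),
        )
        return dict(
            out=out, B=B,
            fv=fv, fa=fa, zv=zv, za=za,
            pv=pv, pa=pa, jv=jv, ja=ja, cv=cv, ca=ca, wv=wv, wa=wa,
            xhat_v=xhat_v, ivar_v=ivar_v, xhat_a=xhat_a, ivar_a=ivar_a,
            fv_n=fv_n, fa_n=fa_n,
            h_av=h_av, u_av=u_av, sv=sv, h_va=h_va, u_va=u_va, sa=sa,
            xhat_f=xhat_f, ivar_f=ivar_f, phi=phi,
        )

    # -- backward ----------------------------------------------------------
    def backward(self, cache: dict, dz: np.ndarray) -> dict[str, np.ndarray]:
        """Backprop from d(loss)/d(z_fuse) to every learnable parameter."""
        f = self.fusion
        B = cache["B"]
        tv, ta = float(self.calib.tv), float(self.calib.ta)
        alpha = float(self.calib.alpha)
        grads: dict[str, np.ndarray] = {}

        grads["W_head"] = dz.T @ cache["phi"]
        grads["b_head"] = dz.sum(axis=0)
        dphi = dz @ f.W_head
        dcat, grads["g_f"], grads["b_f"] = _ln_backward(
            dphi, cache["xhat_f"], cache["ivar_f"], f.g_f
        )
        D = f.D
        dfv_cm, dfa_cm = dcat[:, :D], dcat[:, D:]

        wv, wa = cache["wv"], cache["wa"]
        sv, sa = cache["sv"], cache["sa"]
        if self.variant == "as_published":
            dfv_n = dfv_cm.copy()
            dfa_n = dfa_cm.copy()
            dsa = dfv_cm * wv[:, None]
            dsv = dfa_cm * wa[:, None]
            dwv = (dfv_cm * sa).sum(axis=1) - (dfa_cm * sv).sum(axis=1)
        else:
            dfv_n = dfv_cm.copy()
            dfa_n = dfa_cm.copy()
            dsv = dfv_cm * wv[:, None]
            dsa = dfa_cm * wa[:, None]
            dwv = (dfv_cm * sv).sum(axis=1) - (dfa_cm * sa).sum(axis=1)

        # MLP v2a: fv_n -> sa
        dm_va = dsa * (1.0 - sa**2)
        grads["W2_v2a"] = dm_va.T @ cache["u_va"]
        grads["b2_v2a"] = dm_va.sum(axis=0)
        dh_va = (dm_va @ f.W2_v2a) * _silu_grad(cache["h_va"])
        grads["W1_v2a"] = dh_va.T @ cache["fv_n"]
        grads["b1_v2a"] = dh_va.sum(axis=0)
        dfv_n += dh_va @ f.W1_v2a

        # MLP a2v: fa_n -> sv
        dm_av = dsv * (1.0 - sv**2)
        grads["W2_a2v"] = dm_av.T @ cache["u_av"]
        grads["b2_a2v"] = dm_av.sum(axis=0)
        dh_av = (dm_av @ f.W2_a2v) * _silu_grad(cache["h_av"])
        grads["W1_a2v"] = dh_av.T @ cache["fa_n"]
        grads["b1_a2v"] = dh_av.sum(axis=0)
        dfa_n += dh_av @ f.W1_a2v

        _, grads["g_v"], grads["b_v"] = _ln_backward(
            dfv_n, cache["xhat_v"], cache["ivar_v"], f.g_v
        )
        _, grads["g_a"], grads["b_a"] = _ln_backward(
            dfa_n, cache["xhat_a"], cache["ivar_a"], f.g_a
        )

        # calibrator: dwv -> (cv, ca, alpha) -> (Tv, Ta)
        cv, ca = cache["cv"], cache["ca"]
        dcv = dwv * alpha * wv * wa / cv
        dca = -dwv * alpha * wv * wa / ca
        grads["alpha"] = np.asarray(
            (dwv * wv * wa * (np.log(cv) - np.log(ca))).sum()
        )
        # d(max softmax(z/T))/dT = (c/T^2) * (sum_m p_m z_m - z_argmax)
        zv, za = cache["zv"], cache["za"]
        pv, pa = cache["pv"], cache["pa"]
        jv, ja = cache["jv"], cache["ja"]
        idx = np.arange(B)
        dcv_dT = (cv / tv**2) * ((pv * zv).sum(axis=1) - zv[idx, jv])
        dca_dT = (ca / ta**2) * ((pa * za).sum(axis=1) - za[idx, ja])
        grads["Tv"] = np.asarray((dcv * dcv_dT).sum())
        grads["Ta"] = np.asarray((dca * dca_dT).sum())
        return grads

    # -- convenience -------------------------------------------------------
    def predict(self, fv, fa, zv, za) -> FusedOutput:
        """Forward pass returning only the fused output (no cache)."""
        out = self.forward(fv, fa, zv, za)["out"]
        return out

    def weights_for(self, zv, za):
        """Per-sample calibrated weights without running the fusion trunk."""
        from .calibration import calibrate

        return calibrate(zv, za, self.calib)
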