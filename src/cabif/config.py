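"""YAML/JSON configuration surface.

A config file can hold four sections, all optional:

.. code-block:: yaml

    frontend:          # FrontendParams fields (target_rate, hop_length, ...)
      target_rate: 16000
    pooling:
      n_frames: 10
      k: 5
      aggregation: mean
    calibrator:        # clamp bounds and calibrator learning rate
      t_min: 0.05
      t_max: 20.0
      alpha_min: 0.1
      alpha_max: 10.0
      lr: 1.0e-2
    fusion:
      hidden: null     # modulation MLP width H (default D//4)
      variant: as_published   # or: crossed
      zero_init_last: false
    train:             # TrainConfig fields
      epochs: 30
      seed: 0
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml

from .audio_frontend import FrontendParams
from .pipeline import TrainConfig

__all__ = ["load_config", "frontend_from_config", "train_config_from_config"]


def load_config(path: str | Path) -> dict:
    """Read a YAML or JSON config file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def frontend_from_config(cfg: dict) -> FrontendParams:
    return FrontendParams.from_config(cfg.get("frontend", {}))


def train_config_from_config(cfg: dict, **overrides) -> TrainConfig:
    """Merge the train/pooling/fusion/calibrator sections into a TrainConfig."""
    merged: dict = dict(cfg.get("train", {}))
    pooling = cfg.get("pooling", {})
    if "k" in pooling:
        merged.setdefault("k", pooling["k"])
    if "n_frames" in pooling:
        merged.setdefault("n_frames", pooling["n_frames"])
    fusion = cfg.get("fusion", {})
    if "hidden" in fusion:
        merged.setdefault("hidden", fusion["hidden"])
    if "variant" in fusion:
        merged.setdefault("variant", fusion["variant"])
    if "zero_init_last" in fusion:
        merged.setdefault("zero_init_last", fusion["zero_init_last"])
    calibrator = cfg.get("calibrator", {})
    if "lr" in calibrator:
        merged.setdefault("lr_calibrator", calibrator["lr"])
    merged.update(overrides)
    valid = {k: v for k, v in merged.items() if k in TrainConfig.__dataclass_fields__}
    return TrainConfig(**valid)
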