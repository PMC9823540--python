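"""Single-file model checkpoints: parameter tensors + config + version."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .backbone import DetectorConfig, LightweightBackbone, SingleInstanceDetector
from .head import BiCLSTMHead, HeadConfig

__all__ = ["save_model", "load_model", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def save_model(model, path: str | Path) -> Path:
    path = Path(path)
    meta: dict = {
        "format_version": FORMAT_VERSION,
        "kind": model.kind,
        "trained": bool(getattr(model, "trained", False)),
    }
    if isinstance(model, BiCLSTMHead):
        meta["config"] = asdict(model.cfg)
    elif isinstance(model, SingleInstanceDetector):
        meta["config"] = model.cfg.to_dict()
    elif isinstance(model, LightweightBackbone):
        meta["config"] = {"channels": list(model.channels)}
    else:
        raise TypeError(f"cannot checkpoint a {type(model).__name__}")
    state = model.state_dict()
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, __meta__=np.array(json.dumps(meta)), **state)
    return path


def load_model(path: str | Path):
    path = Path(path)
    with np.load(path, allow_pickle=False) as archive:
        meta = json.loads(str(archive["__meta__"]))
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    if meta["format_version"] != FORMAT_VERSION:
        raise ValueError(f"unsupported checkpoint version {meta['format_version']}")
    kind = meta["kind"]
    if kind == "head":
        model = BiCLSTMHead(HeadConfig(**meta["config"]))
    elif kind == "detector":
        model = SingleInstanceDetector(DetectorConfig.from_dict(meta["config"]))
    elif kind == "lightweight":
        model = LightweightBackbone(channels=tuple(meta["config"]["channels"]))
    else:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    model.load_state_dict(state)
    model.trained = meta["trained"]
    model.eval()
    return model
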