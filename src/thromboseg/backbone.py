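"""Per-slice spatial attention maps: providers and extraction contract.

The sequence head consumes one soft foreground map per slice.  Two
interchangeable providers honor the same contract:

* :class:`SingleInstanceDetector` — a detection-style provider with the
  three canonical output branches (classification score, bounding-box
  regression, dense mask).  Only the mask branch is consumed downstream:
  the soft mask of the highest-scoring detection is pasted into
  full-image coordinates, zeros elsewhere; no detection above the score
  threshold yields an all-zero map.
* :class:`LightweightBackbone` — a plain convolutional encoder-decoder
  producing a dense per-pixel foreground probability; small enough to
  train on a CPU in seconds.

:class:`DetectorConfig` captures the detection configuration of the
reference pipeline (a 50-layer residual backbone, three anchor scales and
three aspect ratios, RoI pooling size, head width); it is validated and
serialized with checkpoints so runs are auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .core_data import BoundingBox, PatientStudy, fit_bounding_boxes
from .nn import SGD, Conv2d, Module, Tensor
from .training import TrainConfig, focal_loss

__all__ = [
    "AttentionMap",
    "DetectorConfig",
    "LightweightBackbone",
    "SingleInstanceDetector",
    "configure_detector",
    "extract_attention_map",
    "train_backbone",
]


@dataclass(frozen=True)
class AttentionMap:
    """Soft per-slice foreground map in [0, 1], same H x W as its slice."""

    values: np.ndarray
    provider_tag: str = "lightweight"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError(f"attention map must be 2D, got {v.shape}")
        object.__setattr__(self, "values", np.clip(v, 0.0, 1.0))


@dataclass(frozen=True)
class DetectorConfig:
    backbone_name: str = "resnet50"
    anchor_scales: tuple[float, ...] = (32.0, 64.0, 128.0)
    anchor_ratios: tuple[float, ...] = (0.5, 1.0, 2.0)
    roi_output_size: int = 14
    score_threshold: float = 0.5
    head_width: int = 1024

    def __post_init__(self):
        if len(self.anchor_scales) != 3:
            raise ValueError("exactly 3 anchor scales are required")
        if len(self.anchor_ratios) != 3:
            raise ValueError("exactly 3 anchor aspect ratios are required")
        if not (0.0 <= self.score_threshold <= 1.0):
            raise ValueError("score_threshold must be in [0, 1]")
        if self.head_width < 1 or self.roi_output_size < 1:
            raise ValueError("head_width and roi_output_size must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["anchor_scales"] = list(self.anchor_scales)
        d["anchor_ratios"] = list(self.anchor_ratios)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DetectorConfig":
        d = dict(d)
        d["anchor_scales"] = tuple(d["anchor_scales"])
        d["anchor_ratios"] = tuple(d["anchor_ratios"])
        return cls(**d)


def _to_input(slice2d: np.ndarray) -> Tensor:
    x = np.asarray(slice2d, dtype=np.float64) / 255.0
    if x.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {x.shape}")
    return Tensor(x[None, None])


class LightweightBackbone(Module):
    """Small same-resolution conv net: dense foreground probability."""

    kind = "lightweight"

    def __init__(self, rng: np.random.Generator | int = 0, channels: tuple[int, int, int] = (8, 16, 8)):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        c1, c2, c3 = channels
        self.channels = channels
        self.conv1 = Conv2d(1, c1, 3, rng)
        self.conv2 = Conv2d(c1, c2, 3, rng)
        self.conv3 = Conv2d(c2, c3, 3, rng)
        self.out = Conv2d(c3, 1, 1, rng)
        self.trained = False

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv1(x).relu()
        h = self.conv2(h).relu()
        h = self.conv3(h).relu()
        return self.out(h)  # logits

    def predict_map(self, slice2d: np.ndarray) -> np.ndarray:
        logits = self.forward(_to_input(slice2d))
        return logits.sigmoid().data[0, 0]


class SingleInstanceDetector(Module):
    """Detection-style provider with classification/box/mask branches.

    Single foreground class (thrombus), single best detection: the model
    scores the whole slice, regresses one box and predicts a dense soft
    mask which is zeroed outside the regressed box.  Ties between
    detections cannot arise (at most one is emitted by construction).
    """

    kind = "detector"

    def __init__(self, cfg: DetectorConfig | None = None, rng: np.random.Generator | int = 0):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg or DetectorConfig()
        self.trunk1 = Conv2d(1, 8, 3, rng)
        self.trunk2 = Conv2d(8, 16, 3, rng)
        self.cls_head = Conv2d(16, 1, 1, rng)
        self.box_head = Conv2d(16, 4, 1, rng)
        self.mask_head1 = Conv2d(16, 8, 3, rng)
        self.mask_head2 = Conv2d(8, 1, 1, rng)
        self.trained = False

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
        """Returns (class logit (B,1), normalized box (B,4), mask logits)."""
        h = self.trunk1(x).relu()
        h = self.trunk2(h).relu()
        cls_logit = self.cls_head(h).mean(axis=(2, 3)).reshape(-1, 1)
        box = self.box_head(h).mean(axis=(2, 3)).sigmoid()  # (B,4) in [0,1]
        mask_logits = self.mask_head2(self.mask_head1(h).relu())
        return cls_logit, box, mask_logits

    def predict(self, slice2d: np.ndarray) -> list[dict]:
        """Detections above ``score_threshold`` (0 or 1 entries)."""
        H, W = np.asarray(slice2d).shape
        cls_logit, box, mask_logits = self.forward(_to_input(slice2d))
        score = float(1.0 / (1.0 + np.exp(-cls_logit.data[0, 0])))
        if score < self.cfg.score_threshold:
            return []
        b = box.data[0]
        r0, r1 = sorted((b[0] * (H - 1), b[2] * (H - 1)))
        c0, c1 = sorted((b[1] * (W - 1), b[3] * (W - 1)))
        bbox = BoundingBox(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))
        mask = 1.0 / (1.0 + np.exp(-mask_logits.data[0, 0]))
        pasted = np.zeros_like(mask)
        pasted[bbox.row_min : bbox.row_max + 1, bbox.col_min : bbox.col_max + 1] = mask[
            bbox.row_min : bbox.row_max + 1, bbox.col_min : bbox.col_max + 1
        ]
        return [{"score": score, "box": bbox, "mask": pasted}]

    def predict_map(self, slice2d: np.ndarray) -> np.ndarray:
        detections = self.predict(slice2d)
        if not detections:
            return np.zeros(np.asarray(slice2d).shape, dtype=np.float64)
        best = max(detections, key=lambda d: d["score"])
        return best["mask"]


def configure_detector(cfg: DetectorConfig, seed: int = 0) -> SingleInstanceDetector:
    """Build a detector handle from a validated configuration."""
    if not isinstance(cfg, DetectorConfig):
        cfg = DetectorConfig.from_dict(dict(cfg))
    return SingleInstanceDetector(cfg, rng=np.random.default_rng(seed))


def extract_attention_map(
    slice2d: np.ndarray,
    provider: Module,
    allow_untrained: bool = False,
) -> AttentionMap:
    """Run a provider on one slice; values are clamped into [0, 1].

    Deterministic given fixed provider parameters and input.  Untrained
    providers raise unless explicitly allowed.
    """
    if not getattr(provider, "trained", False) and not allow_untrained:
        raise RuntimeError(
            "provider is untrained; pass allow_untrained=True to override"
        )
    values = provider.predict_map(np.asarray(slice2d))
    return AttentionMap(values=values, provider_tag=getattr(provider, "kind", "external_file"))


def _bce_logit(logit: Tensor, target: float) -> Tensor:
    p = logit.sigmoid().clip(1e-7, 1 - 1e-7)
    return -(target * p.log() + (1 - target) * (1 - p).log()).mean()


def train_backbone(
    provider: Module,
    studies: list[PatientStudy],
    train_cfg: TrainConfig,
) -> tuple[Module, list[float]]:
    """Train either provider on ROI-bearing slices; returns the loss trace.

    Every training slice must carry a nonempty GT mask (apply
    ``filter_slices_with_roi`` first).  The lightweight provider minimizes
    focal loss on its dense map; the detector minimizes the standard
    multi-task sum of a classification term, a box-regression term on the
    tight GT box, and a mask term.
    """
    if not studies:
        raise ValueError("empty training set")
    samples: list[tuple[np.ndarray, np.ndarray, BoundingBox]] = []
    for study in studies:
        for img, msk in zip(study.slices, study.gt_masks):
            if not msk.any():
                raise ValueError(
                    f"study {study.study_id!r} contains a slice without ROI; "
                    "run filter_slices_with_roi first"
                )
            (box,) = fit_bounding_boxes(msk, per_component=False)
            samples.append((img, msk, box))

    lr = train_cfg.lr if train_cfg.lr is not None else 0.0001
    opt = SGD(provider.parameters(), lr=lr, momentum=train_cfg.momentum)
    rng = np.random.default_rng(train_cfg.seed)
    losses: list[float] = []
    provider.train()
    for _ in range(train_cfg.steps):
        img, msk, box = samples[int(rng.integers(len(samples)))]
        H, W = img.shape
        x = _to_input(img)
        if isinstance(provider, SingleInstanceDetector):
            cls_logit, box_pred, mask_logits = provider(x)
            gt_box = Tensor(
                np.array(
                    [
                        box.row_min / max(H - 1, 1),
                        box.col_min / max(W - 1, 1),
                        box.row_max / max(H - 1, 1),
                        box.col_max / max(W - 1, 1),
                    ]
                )[None]
            )
            loss = (
                _bce_logit(cls_logit, 1.0)
                + ((box_pred - gt_box) ** 2).mean()
                + focal_loss(
                    mask_logits.sigmoid(),
                    msk[None, None].astype(np.float64),
                    alpha=train_cfg.focal_alpha,
                    gamma=train_cfg.focal_gamma,
                )
            )
        else:
            probs = provider(x).sigmoid()
            loss = focal_loss(
                probs,
                msk[None, None].astype(np.float64),
                alpha=train_cfg.focal_alpha,
                gamma=train_cfg.focal_gamma,
            )
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    provider.trained = True
    provider.eval()
    return provider, losses
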