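"""Domain containers and volume/mask I/O for postoperative CTA studies.

A :class:`PatientStudy` is an ordered stack of axial grayscale slices with
per-slice binary ground-truth masks of the thrombus region, plus in-plane
pixel spacing (mm) and the slices' 0-based positions in the original
volume.  Readers/writers cover NIfTI (via nibabel) and a lightweight
PNG-stack dialect with a JSON manifest.

Coordinate convention throughout the package: 0-based (row, col) indices;
bounding boxes are inclusive at both ends.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "PatientStudy",
    "BoundingBox",
    "validate_binary_mask",
    "rescale_to_8bit",
    "fit_bounding_boxes",
    "filter_slices_with_roi",
    "write_study",
    "load_study",
]


def validate_binary_mask(mask: np.ndarray) -> np.ndarray:
    """Return ``mask`` as uint8 {0,1}; raise if any other value is present."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask is not binary; found values {vals[:10]}")
    return arr.astype(np.uint8)


@dataclass(frozen=True)
class BoundingBox:
    """Tight axis-aligned rectangle, 0-based, inclusive at both ends."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self):
        if self.row_min > self.row_max or self.col_min > self.col_max:
            raise ValueError(f"degenerate box {self}")
        if min(self.row_min, self.col_min) < 0:
            raise ValueError(f"box extends outside image bounds: {self}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min + 1

    @property
    def width(self) -> int:
        return self.col_max - self.col_min + 1


@dataclass
class PatientStudy:
    """One CTA image volume with aligned ground-truth thrombus masks."""

    study_id: str
    slices: list[np.ndarray]
    gt_masks: list[np.ndarray]
    pixel_spacing: float
    slice_indices: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.slice_indices:
            self.slice_indices = list(range(len(self.slices)))
        if not (len(self.slices) == len(self.gt_masks) == len(self.slice_indices)):
            raise ValueError(
                "slices, gt_masks and slice_indices must have equal length"
            )
        for i, (s, m) in enumerate(zip(self.slices, self.gt_masks)):
            if s.shape != m.shape:
                raise ValueError(
                    f"slice {i}: image shape {s.shape} != mask shape {m.shape}"
                )
            self.gt_masks[i] = validate_binary_mask(m)
        idx = np.asarray(self.slice_indices)
        if len(idx) and np.any(np.diff(idx) <= 0):
            raise ValueError("slice_indices must be strictly increasing")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    @property
    def shape(self) -> tuple[int, int]:
        return self.slices[0].shape


def rescale_to_8bit(
    volume: np.ndarray | Sequence[np.ndarray],
    mode: Literal["volume_minmax", "fixed_range"] = "volume_minmax",
    fixed_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Linearly rescale an intensity stack to the full 8-bit range [0, 255].

    The map is over the full input range with no window-level adjustment.
    ``volume_minmax`` uses the volume's own min/max; ``fixed_range`` maps a
    caller-supplied ``(lo, hi)``, clipping values outside it.  Rounding is
    half-to-even.  A constant volume under ``volume_minmax`` maps to all
    zeros (documented degenerate case).
    """
    vol = np.asarray(volume, dtype=np.float64)
    if vol.size == 0:
        raise ValueError("cannot rescale an empty volume")
    if mode == "volume_minmax":
        lo, hi = float(vol.min()), float(vol.max())
        if lo == hi:
            return np.zeros(vol.shape, dtype=np.uint8)
    elif mode == "fixed_range":
        if fixed_range is None:
            raise ValueError("fixed_range mode requires a (lo, hi) pair")
        lo, hi = map(float, fixed_range)
        if lo >= hi:
            raise ValueError(f"fixed_range requires lo < hi, got ({lo}, {hi})")
    else:
        raise ValueError(f"unknown rescale mode {mode!r}")
    scaled = (np.clip(vol, lo, hi) - lo) * (255.0 / (hi - lo))
    return np.rint(scaled).astype(np.uint8)


def fit_bounding_boxes(
    mask: np.ndarray, per_component: bool = True
) -> list[BoundingBox]:
    """Fit tight rectangles to mask foreground.

    ``per_component=True`` yields one box per 8-connected component;
    otherwise a single box over all foreground.  Empty mask -> empty list.
    """
    m = validate_binary_mask(mask)
    if not m.any():
        return []
    if not per_component:
        rows, cols = np.nonzero(m)
        return [
            BoundingBox(int(rows.min()), int(cols.min()), int(rows.max()), int(cols.max()))
        ]
    labels = measure.label(m, connectivity=2)
    boxes = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox  # half-open
        boxes.append(BoundingBox(r0, c0, r1 - 1, c1 - 1))
    return boxes


def filter_slices_with_roi(study: PatientStudy) -> PatientStudy:
    """Keep exactly the slices whose GT mask has foreground.

    Original ``slice_indices`` are preserved so positions in the source
    volume remain auditable.  A study left with zero slices is unusable
    and raises.
    """
    keep = [i for i, m in enumerate(study.gt_masks) if m.any()]
    if not keep:
        raise ValueError(f"study {study.study_id!r} has no slices with thrombus ROI")
    return PatientStudy(
        study_id=study.study_id,
        slices=[study.slices[i] for i in keep],
        gt_masks=[study.gt_masks[i] for i in keep],
        pixel_spacing=study.pixel_spacing,
        slice_indices=[study.slice_indices[i] for i in keep],
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_META_SUFFIX = "_meta.json"


def write_study(
    study: PatientStudy,
    directory: str | Path,
    format: Literal["nifti", "image_stack"] = "nifti",
) -> Path:
    """Write a study to ``directory``; returns the directory path.

    nifti: ``<id>_image.nii`` + ``<id>_mask.nii`` + ``<id>_meta.json``.
    image_stack: per-slice PNGs + ``manifest.json`` carrying id, spacing
    and slice order.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "study_id": study.study_id,
        "pixel_spacing": study.pixel_spacing,
        "slice_indices": list(map(int, study.slice_indices)),
        "format": format,
    }
    if format == "nifti":
        import nibabel as nib

        affine = np.diag([study.pixel_spacing, study.pixel_spacing, 1.0, 1.0])
        img = np.stack(study.slices, axis=-1)  # (H, W, S)
        msk = np.stack(study.gt_masks, axis=-1).astype(np.uint8)
        nib.save(
            nib.Nifti1Image(img, affine), str(directory / f"{study.study_id}_image.nii")
        )
        nib.save(
            nib.Nifti1Image(msk, affine), str(directory / f"{study.study_id}_mask.nii")
        )
        (directory / f"{study.study_id}{_META_SUFFIX}").write_text(json.dumps(meta))
    elif format == "image_stack":
        import imageio.v3 as iio

        for pos, (img, msk) in enumerate(zip(study.slices, study.gt_masks)):
            iio.imwrite(directory / f"slice_{pos:04d}.png", img.astype(np.uint8))
            iio.imwrite(directory / f"mask_{pos:04d}.png", msk.astype(np.uint8))
        (directory / "manifest.json").write_text(json.dumps(meta))
    else:
        raise ValueError(f"unknown format {format!r}")
    return directory


def load_study(
    path: str | Path, format: Literal["nifti", "image_stack"] = "nifti"
) -> PatientStudy:
    """Load a study written by :func:`write_study`; validates all invariants."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "nifti":
        import nibabel as nib

        metas = sorted(path.glob(f"*{_META_SUFFIX}"))
        if not metas:
            raise FileNotFoundError(f"no study metadata in {path}")
        meta = json.loads(metas[0].read_text())
        sid = meta["study_id"]
        mask_file = path / f"{sid}_mask.nii"
        if not mask_file.exists():
            raise FileNotFoundError(f"missing mask volume {mask_file}")
        img = np.asarray(nib.load(str(path / f"{sid}_image.nii")).dataobj)
        msk = np.asarray(nib.load(str(mask_file)).dataobj)
        if img.shape != msk.shape:
            raise ValueError(
                f"image shape {img.shape} != mask shape {msk.shape} in {path}"
            )
        slices = [img[:, :, i] for i in range(img.shape[2])]
        masks = [msk[:, :, i] for i in range(msk.shape[2])]
    elif format == "image_stack":
        import imageio.v3 as iio

        manifest = path / "manifest.json"
        if not manifest.exists():
            raise FileNotFoundError(f"no manifest.json in {path}")
        meta = json.loads(manifest.read_text())
        slice_files = sorted(path.glob("slice_*.png"))
        slices, masks = [], []
        for sf in slice_files:
            mf = path / sf.name.replace("slice_", "mask_")
            if not mf.exists():
                raise FileNotFoundError(f"missing mask image {mf}")
            slices.append(np.asarray(iio.imread(sf)))
            masks.append(np.asarray(iio.imread(mf)))
    else:
        raise ValueError(f"unknown format {format!r}")
    return PatientStudy(
        study_id=meta["study_id"],
        slices=slices,
        gt_masks=masks,
        pixel_spacing=float(meta["pixel_spacing"]),
        slice_indices=list(meta["slice_indices"]),
    )
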