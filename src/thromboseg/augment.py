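"""N-pair sequence construction and geometry-consistent augmentation.

The head segments the centre slice of an odd-length window of
(slice, attention-map) pairs; :func:`build_sequences` slides that window
over a study, replicating (or reflecting) at the volume ends and marking
padded positions.

Two augmentations are provided, matching the training protocol: elastic
deformation (a random displacement field smoothed by a Gaussian) and
rotation within +/-10 degrees.  One geometric transform is always applied
identically to an image and its mask (linear interpolation for
intensities, nearest-neighbour for masks so they stay binary).  The
sequence-level helper applies a single transform to all N pairs so the
volumetric coherence the head learns is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .backbone import AttentionMap
from .core_data import PatientStudy, validate_binary_mask

__all__ = [
    "AugmentationSpec",
    "PairSequence",
    "build_sequences",
    "elastic_deform",
    "random_rotate",
    "sample_elastic_field",
    "apply_displacement",
    "augment_pair_sequence",
]


@dataclass(frozen=True)
class AugmentationSpec:
    """Augmentation settings; lengths in pixels at the working resolution.

    ``elastic_alpha`` is the displacement magnitude and ``elastic_sigma``
    the Gaussian smoothing std of the random field (defaults tuned for
    64 x 64 slices and scale-proportional); rotation angles are drawn
    uniformly within ``rotation_max_deg`` degrees.
    """

    rotation_max_deg: float = 10.0
    elastic_alpha: float = 8.0
    elastic_sigma: float = 4.0
    seed: int = 0
    enabled: bool = True

    def __post_init__(self):
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be >= 0")
        if self.elastic_alpha < 0 or self.elastic_sigma < 0:
            raise ValueError("elastic parameters must be >= 0")


@dataclass
class PairSequence:
    """Odd-length window of (slice, attention map) pairs around a target."""

    pairs: list[tuple[np.ndarray, AttentionMap]]
    target_index: int
    padding_flags: list[bool]
    study_id: str = ""
    target_slice_index: int = -1

    def __post_init__(self):
        n = len(self.pairs)
        if n % 2 == 0 or n < 1:
            raise ValueError(f"sequence length must be odd and >= 1, got {n}")
        if self.target_index != (n - 1) // 2:
            raise ValueError("target_index must be the centre of the sequence")
        if len(self.padding_flags) != n:
            raise ValueError("padding_flags must align with pairs")
        shapes = {np.asarray(img).shape for img, _ in self.pairs}
        shapes |= {np.asarray(a.values if isinstance(a, AttentionMap) else a).shape for _, a in self.pairs}
        if len(shapes) != 1:
            raise ValueError(f"all pairs must share H x W, got {shapes}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def target_pair(self) -> tuple[np.ndarray, AttentionMap]:
        return self.pairs[self.target_index]


def _boundary_index(i: int, n: int, boundary: str) -> int:
    if 0 <= i < n:
        return i
    if boundary == "replicate":
        return min(max(i, 0), n - 1)
    if boundary == "reflect":
        # reflect about the volume ends without repeating the edge slice
        period = 2 * (n - 1) if n > 1 else 1
        i = abs(i) % period
        return period - i if i >= n else i
    raise ValueError(f"unknown boundary policy {boundary!r}")


def build_sequences(
    study: PatientStudy,
    maps: list[AttentionMap],
    N: int = 5,
    boundary: str = "replicate",
) -> list[PairSequence]:
    """One centred PairSequence per slice of the study.

    Positions outside the volume are filled per the boundary policy and
    flagged as padding.  ``N`` must be odd and positive.
    """
    if N < 1 or N % 2 == 0:
        raise ValueError(f"sequence length N must be odd and >= 1, got {N}")
    if len(maps) != study.n_slices:
        raise ValueError("one attention map per slice is required")
    half = (N - 1) // 2
    n = study.n_slices
    sequences = []
    for target in range(n):
        pairs, flags = [], []
        for off in range(-half, half + 1):
            raw = target + off
            idx = _boundary_index(raw, n, boundary)
            pairs.append((study.slices[idx], maps[idx]))
            flags.append(raw != idx)
        sequences.append(
            PairSequence(
                pairs=pairs,
                target_index=half,
                padding_flags=flags,
                study_id=study.study_id,
                target_slice_index=study.slice_indices[target],
            )
        )
    return sequences


def sample_elastic_field(
    shape: tuple[int, int],
    spec: AugmentationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one smoothed random displacement field (d_row, d_col)."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    d_row = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), spec.elastic_sigma) * spec.elastic_alpha
    d_col = ndimage.gaussian_filter(rng.uniform(-1, 1, shape), spec.elastic_sigma) * spec.elastic_alpha
    return d_row, d_col


def apply_displacement(
    arr: np.ndarray, fld: tuple[np.ndarray, np.ndarray], order: int
) -> np.ndarray:
    """Warp ``arr`` by a displacement field; order 0 keeps masks binary."""
    rows, cols = np.mgrid[0 : arr.shape[0], 0 : arr.shape[1]].astype(np.float64)
    coords = np.array([rows + fld[0], cols + fld[1]])
    warped = ndimage.map_coordinates(
        arr.astype(np.float64), coords, order=order, mode="reflect"
    )
    if np.issubdtype(arr.dtype, np.integer):
        return np.rint(warped).astype(arr.dtype)
    return warped


def elastic_deform(
    image: np.ndarray,
    mask: np.ndarray,
    spec: AugmentationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply one elastic deformation consistently to an image and its mask.

    A single displacement field is sampled per call; the image is warped
    with linear interpolation, the mask with nearest-neighbour.  With no
    explicit ``rng`` the spec seed makes the call deterministic.
    """
    mask = validate_binary_mask(mask)
    if spec.elastic_alpha == 0:
        return image.copy(), mask.copy()
    fld = sample_elastic_field(image.shape, spec, rng)
    return apply_displacement(image, fld, order=1), apply_displacement(mask, fld, order=0)


def _rotate(arr: np.ndarray, angle_deg: float, order: int) -> np.ndarray:
    if angle_deg == 0.0:
        return arr.copy()
    rotated = ndimage.rotate(
        arr.astype(np.float64), angle_deg, reshape=False, order=order, mode="constant", cval=0.0
    )
    if np.issubdtype(arr.dtype, np.integer):
        return np.rint(np.clip(rotated, np.iinfo(arr.dtype).min, np.iinfo(arr.dtype).max)).astype(arr.dtype)
    return rotated


def sample_rotation_angle(
    spec: AugmentationSpec, rng: np.random.Generator | None = None
) -> float:
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    if spec.rotation_max_deg == 0:
        return 0.0
    return float(rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg))


def random_rotate(
    image: np.ndarray,
    mask: np.ndarray,
    spec: AugmentationSpec,
    rng: np.random.Generator | None = None,
    return_angle: bool = False,
):
    """Rotate image and mask about the image centre by one shared angle.

    The angle is drawn uniformly in [-rotation_max_deg, +rotation_max_deg];
    the mask uses nearest-neighbour interpolation and stays binary.
    """
    mask = validate_binary_mask(mask)
    theta = sample_rotation_angle(spec, rng)
    out = (_rotate(image, theta, order=1), _rotate(mask, theta, order=0))
    return (*out, theta) if return_angle else out


def augment_pair_sequence(
    seq: PairSequence,
    gt_mask: np.ndarray,
    spec: AugmentationSpec,
    rng: np.random.Generator | None = None,
) -> tuple[PairSequence, np.ndarray]:
    """Apply ONE elastic field and ONE rotation to all N pairs and the GT.

    Per-slice independent warps would destroy the inter-slice coherence
    the head learns, so the whole window shares a single transform; the
    attention maps are warped alongside their slices (the cheap default in
    a two-stage pipeline where maps are precomputed).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    gt_mask = validate_binary_mask(gt_mask)
    if not spec.enabled:
        return seq, gt_mask
    shape = np.asarray(seq.pairs[0][0]).shape
    fld = sample_elastic_field(shape, spec, rng) if spec.elastic_alpha > 0 else None
    theta = sample_rotation_angle(spec, rng)

    def warp(arr: np.ndarray, order: int) -> np.ndarray:
        out = arr
        if fld is not None:
            out = apply_displacement(out, fld, order)
        return _rotate(out, theta, order)

    new_pairs = []
    for img, att in seq.pairs:
        a = att.values if isinstance(att, AttentionMap) else np.asarray(att)
        new_pairs.append(
            (
                warp(np.asarray(img), order=1),
                AttentionMap(
                    warp(a, order=1),
                    provider_tag=att.provider_tag if isinstance(att, AttentionMap) else "external_file",
                ),
            )
        )
    new_seq = PairSequence(
        pairs=new_pairs,
        target_index=seq.target_index,
        padding_flags=list(seq.padding_flags),
        study_id=seq.study_id,
        target_slice_index=seq.target_slice_index,
    )
    return new_seq, warp(gt_mask, order=0)
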