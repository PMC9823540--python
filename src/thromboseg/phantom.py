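"""Synthetic postoperative-CTA phantom cohorts with exact ground truth.

The clinical data this package targets cannot be redistributed, so the
phantom generator emulates its stated difficulty factors on a desk-scale
geometry: an aneurysm sac rendered as a bright contrast-filled lumen
surrounded by an annular thrombus whose boundary is irregular (low-order
radial harmonics), embedded in a soft-tissue field whose intensities can
be made to overlap the thrombus distribution (``tissue_overlap``), with
optional bright stent-graft streak artifacts crossing the sac and
additive Gaussian noise.  The thrombus centroid drifts smoothly from
slice to slice, giving the volumetric coherence that the Bi-CLSTM head
exploits.

Everything is deterministic given the seed.  GT masks mark exactly the
generated thrombus pixels before noise/artifacts are applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .core_data import PatientStudy

__all__ = [
    "IntensityLevels",
    "PhantomParams",
    "generate_study",
    "generate_cohort",
    "threshold_oracle",
]


@dataclass(frozen=True)
class IntensityLevels:
    """Mean 8-bit intensities of the phantom's tissue classes."""

    background: float = 20.0
    tissue: float = 110.0
    thrombus: float = 150.0
    lumen: float = 240.0
    stent: float = 255.0


@dataclass(frozen=True)
class PhantomParams:
    """Generator configuration; defaults are the package's study conditions.

    Lengths are in pixels at the configured ``image_size`` (64 for tests,
    256 for demos).  ``tissue_overlap`` in [0, 1] scales the std of the
    thrombus intensity jitter as a fraction of the thrombus-tissue gap:
    0 means perfectly separable classes, larger values push the thrombus
    distribution into the tissue range.  ``center_drift`` bounds the
    per-slice displacement of the sac centre (px).
    """

    image_size: int = 64
    n_slices: int = 8
    lumen_radius_range: tuple[float, float] = (5.0, 8.0)
    thrombus_thickness_range: tuple[float, float] = (4.0, 8.0)
    center_drift: float = 2.0
    intensity_levels: IntensityLevels = field(default_factory=IntensityLevels)
    tissue_overlap: float = 0.3
    stent_artifact: bool = True
    stent_streaks: int = 2
    noise_sigma: float = 5.0
    pixel_spacing: float = 0.8
    seed: int = 0

    @classmethod
    def for_size(cls, image_size: int, **overrides) -> "PhantomParams":
        """Defaults with sac geometry scaled proportionally from 64 px."""
        f = image_size / 64.0
        base = cls()
        scaled = dict(
            image_size=image_size,
            lumen_radius_range=tuple(round(v * f, 3) for v in base.lumen_radius_range),
            thrombus_thickness_range=tuple(
                round(v * f, 3) for v in base.thrombus_thickness_range
            ),
            center_drift=round(base.center_drift * f, 3),
        )
        scaled.update(overrides)
        return cls(**scaled)

    def validate(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if not (0.0 <= self.tissue_overlap <= 1.0):
            raise ValueError("tissue_overlap must be in [0, 1]")
        lo_l, hi_l = self.lumen_radius_range
        lo_t, hi_t = self.thrombus_thickness_range
        if min(lo_l, lo_t) <= 0 or lo_l > hi_l or lo_t > hi_t:
            raise ValueError("radius/thickness ranges must be positive and ordered")
        if self.noise_sigma < 0 or self.center_drift < 0:
            raise ValueError("noise_sigma and center_drift must be >= 0")
        # outer radius including boundary irregularity plus a safety rim
        r_max = (hi_l + hi_t) * (1.0 + _PERTURB_TOTAL) + 2.0
        if 2.0 * r_max >= self.image_size:
            raise ValueError(
                f"phantom geometry cannot fit: outer radius {r_max:.1f}px "
                f"does not fit in a {self.image_size}px image"
            )


# total relative amplitude of the radial boundary harmonics
_PERTURB_TOTAL = 0.15


def generate_study(params: PhantomParams, study_id: str = "phantom-000") -> PatientStudy:
    """Render one phantom study; bit-identical for identical params."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    lv = params.intensity_levels

    lumen_r = rng.uniform(*params.lumen_radius_range)
    thickness = rng.uniform(*params.thrombus_thickness_range)
    outer_r = lumen_r + thickness

    rows, cols = np.mgrid[0:size, 0:size].astype(np.float64)
    # frozen per-study boundary shape and soft-tissue texture
    theta_shape_rng = np.random.default_rng(rng.integers(2**31))
    texture = gaussian_filter(rng.normal(0, 1, (size, size)), sigma=size / 10.0)
    texture *= 10.0 / max(np.abs(texture).max(), 1e-12)

    # smooth centroid path: bounded per-slice steps, clamped inside a margin
    margin = outer_r * (1.0 + _PERTURB_TOTAL) + 2.0
    center = np.array([size / 2.0, size / 2.0])
    center += rng.uniform(-0.1, 0.1, size=2) * size
    center = np.clip(center, margin, size - margin)
    centers = []
    for _ in range(params.n_slices):
        centers.append(center.copy())
        step_angle = rng.uniform(0, 2 * np.pi)
        step_len = rng.uniform(0, 0.9 * params.center_drift)
        step = step_len * np.array([np.sin(step_angle), np.cos(step_angle)])
        center = np.clip(center + step, margin, size - margin)

    # body outline: large ellipse, everything outside is air/background
    cy, cx = size / 2.0, size / 2.0
    body = ((rows - cy) / (0.48 * size)) ** 2 + ((cols - cx) / (0.44 * size)) ** 2 <= 1.0

    # one fixed harmonic draw reused for every slice (translation-only drift)
    amps = theta_shape_rng.dirichlet(np.ones(4)) * _PERTURB_TOTAL
    phases = theta_shape_rng.uniform(0, 2 * np.pi, size=4)

    def boundary_scale(theta: np.ndarray) -> np.ndarray:
        out = np.ones_like(theta)
        for k, (a, p) in enumerate(zip(amps, phases), start=2):
            out += a * np.cos(k * theta + p)
        return out

    gap = lv.thrombus - lv.tissue
    slices, masks = [], []
    for c in centers:
        dr, dc = rows - c[0], cols - c[1]
        r = np.hypot(dr, dc)
        theta = np.arctan2(dr, dc)
        r_out = outer_r * boundary_scale(theta)

        img = np.full((size, size), lv.background, dtype=np.float64)
        img[body] = lv.tissue + texture[body]
        thrombus = (r > lumen_r) & (r <= r_out)
        mask = thrombus.astype(np.uint8)
        thrombus_intensity = lv.thrombus + rng.normal(
            0.0, params.tissue_overlap * gap, size=int(thrombus.sum())
        )
        img[thrombus] = thrombus_intensity
        img[r <= lumen_r] = lv.lumen

        if params.stent_artifact and params.stent_streaks > 0:
            for _ in range(params.stent_streaks):
                ang = rng.uniform(0, np.pi)
                offset = rng.uniform(-0.5, 0.5) * outer_r
                d = np.abs(
                    np.cos(ang) * dr - np.sin(ang) * dc - offset
                )  # distance to streak line through the sac
                streak = (d <= 0.7) & (r <= r_out + 2.0)
                img[streak] = lv.stent

        if params.noise_sigma > 0:
            img = img + rng.normal(0.0, params.noise_sigma, img.shape)
        slices.append(np.rint(np.clip(img, 0, 255)).astype(np.uint8))
        masks.append(mask)

    return PatientStudy(
        study_id=study_id,
        slices=slices,
        gt_masks=masks,
        pixel_spacing=params.pixel_spacing,
    )


def study_seed(cohort_seed: int, index: int) -> int:
    """Counter-based per-study seed: SeedSequence([cohort_seed, index])."""
    return int(np.random.SeedSequence([cohort_seed, index]).generate_state(1)[0] % 2**31)


def generate_cohort(
    n_studies: int,
    params: PhantomParams,
    seed: int,
    n_slices_range: tuple[int, int] | None = None,
) -> list[PatientStudy]:
    """Generate ``n_studies`` phantoms with distinct ids and derived seeds.

    If ``n_slices_range=(lo, hi)`` is given, each study's slice count is the
    first draw from its own seeded stream (inclusive bounds), so the cohort
    is reproducible from ``(params, seed)`` alone.
    """
    if n_studies < 1:
        raise ValueError("n_studies must be >= 1")
    cohort = []
    for i in range(n_studies):
        s = study_seed(seed, i)
        p = replace(params, seed=s)
        if n_slices_range is not None:
            lo, hi = n_slices_range
            n = int(np.random.default_rng(s).integers(lo, hi + 1))
            p = replace(p, n_slices=n)
        cohort.append(generate_study(p, study_id=f"phantom-{i:03d}"))
    return cohort


def threshold_oracle(study: PatientStudy, params: PhantomParams) -> list[np.ndarray]:
    """Reference segmenter: band threshold around the thrombus intensity.

    Keeps pixels at or above the tissue/thrombus midpoint and strictly
    below the thrombus/lumen midpoint, which separates the annulus from
    both the darker soft tissue and the brighter lumen.  On a noiseless,
    zero-overlap phantom without stent artifacts it recovers the GT mask
    exactly; it degrades monotonically as ``tissue_overlap`` grows, which
    makes it the baseline difficulty probe for the phantom.
    """
    lv = params.intensity_levels
    lo = (lv.tissue + lv.thrombus) / 2.0
    hi = (lv.thrombus + lv.lumen) / 2.0
    return [
        ((s.astype(np.float64) >= lo) & (s.astype(np.float64) < hi)).astype(np.uint8)
        for s in study.slices
    ]
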