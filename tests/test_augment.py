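"""Sequence windows and geometry-consistent augmentation."""

import numpy as np
import pytest

from thromboseg import (
    AttentionMap,
    AugmentationSpec,
    PatientStudy,
    augment_pair_sequence,
    build_sequences,
    elastic_deform,
    random_rotate,
)
from thromboseg.augment import (
    PairSequence,
    apply_displacement,
    sample_elastic_field,
    sample_rotation_angle,
)
from thromboseg.metrics import compute_metrics


@pytest.fixture
def study10(rng):
    slices = [rng.integers(0, 255, (16, 16)).astype(np.uint8) for _ in range(10)]
    masks = []
    for _ in range(10):
        m = np.zeros((16, 16), np.uint8)
        m[5:9, 6:10] = 1
        masks.append(m)
    return PatientStudy("s10", slices, masks, 0.8)


def maps_for(study):
    return [AttentionMap(np.full(study.shape, 0.5)) for _ in range(study.n_slices)]


class TestBuildSequences:
    @pytest.mark.parametrize("N", [3, 5, 7])
    def test_one_sequence_per_slice(self, study10, N):
        seqs = build_sequences(study10, maps_for(study10), N=N)
        assert len(seqs) == 10
        assert all(len(s) == N for s in seqs)
        assert all(s.target_index == (N - 1) // 2 for s in seqs)

    def test_replicate_padding_at_volume_start(self, study10):
        seqs = build_sequences(study10, maps_for(study10), N=5, boundary="replicate")
        first = seqs[0]
        assert first.padding_flags == [True, True, False, False, False]
        for off in (0, 1):  # offsets -2, -1 replicate slice 0
            assert np.array_equal(first.pairs[off][0], study10.slices[0])

    def test_reflect_padding_mirrors_interior(self, study10):
        seqs = build_sequences(study10, maps_for(study10), N=5, boundary="reflect")
        first = seqs[0]
        assert np.array_equal(first.pairs[0][0], study10.slices[2])
        assert np.array_equal(first.pairs[1][0], study10.slices[1])

    @pytest.mark.parametrize("N", [4, 0, -1])
    def test_invalid_length_errors(self, study10, N):
        with pytest.raises(ValueError):
            build_sequences(study10, maps_for(study10), N=N)

    def test_targets_cover_study_exactly_once(self, study10):
        seqs = build_sequences(study10, maps_for(study10), N=5)
        assert sorted(s.target_slice_index for s in seqs) == study10.slice_indices

    def test_misaligned_maps_rejected(self, study10):
        with pytest.raises(ValueError, match="per slice"):
            build_sequences(study10, maps_for(study10)[:-1], N=3)

    def test_pair_sequence_invariants(self):
        img = np.zeros((4, 4), np.uint8)
        amap = AttentionMap(np.zeros((4, 4)))
        with pytest.raises(ValueError, match="odd"):
            PairSequence([(img, amap)] * 2, 0, [False, False])
        with pytest.raises(ValueError, match="centre"):
            PairSequence([(img, amap)] * 3, 0, [False] * 3)


class TestElastic:
    def test_zero_alpha_is_identity(self, rng):
        img = rng.integers(0, 255, (12, 12)).astype(np.uint8)
        msk = (rng.random((12, 12)) < 0.3).astype(np.uint8)
        spec = AugmentationSpec(elastic_alpha=0.0)
        out_img, out_msk = elastic_deform(img, msk, spec)
        assert np.array_equal(out_img, img) and np.array_equal(out_msk, msk)

    def test_same_seed_identical_outputs(self, rng):
        img = rng.integers(0, 255, (12, 12)).astype(np.uint8)
        msk = (rng.random((12, 12)) < 0.3).astype(np.uint8)
        spec = AugmentationSpec(seed=5)
        a = elastic_deform(img, msk, spec)
        b = elastic_deform(img, msk, spec)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_mask_stays_binary_over_many_cases(self, rng):
        spec = AugmentationSpec(elastic_alpha=10.0, elastic_sigma=3.0)
        for _ in range(100):
            msk = (rng.random((10, 10)) < 0.4).astype(np.uint8)
            img = rng.integers(0, 255, (10, 10)).astype(np.uint8)
            _, out = elastic_deform(img, msk, spec, rng)
            assert set(np.unique(out)) <= {0, 1}

    def test_image_and_mask_share_one_field(self, rng):
        """Transforming a coordinate grid both ways gives the same warp."""
        spec = AugmentationSpec(seed=3)
        grid = np.arange(144, dtype=np.float64).reshape(12, 12)
        fld = sample_elastic_field((12, 12), spec)
        via_img = apply_displacement(grid, fld, order=0)
        via_msk_path = apply_displacement(grid, fld, order=0)
        assert np.array_equal(via_img, via_msk_path)
        # and elastic_deform with the same seed reproduces that field
        out_img, _ = elastic_deform(grid, (grid > 70).astype(np.uint8), spec)
        assert np.array_equal(
            apply_displacement(grid, fld, order=1), out_img
        )


class TestRotation:
    def test_zero_max_angle_is_identity(self, rng):
        img = rng.integers(0, 255, (12, 12)).astype(np.uint8)
        msk = (rng.random((12, 12)) < 0.3).astype(np.uint8)
        out_img, out_msk = random_rotate(img, msk, AugmentationSpec(rotation_max_deg=0.0))
        assert np.array_equal(out_img, img) and np.array_equal(out_msk, msk)

    def test_sampled_angles_within_bounds(self):
        spec = AugmentationSpec(rotation_max_deg=10.0)
        rng = np.random.default_rng(0)
        angles = [sample_rotation_angle(spec, rng) for _ in range(1000)]
        assert all(-10.0 <= a <= 10.0 for a in angles)

    def test_round_trip_dice(self, rng):
        """Rotate by theta then -theta: interpolation-limited recovery."""
        msk = np.zeros((32, 32), np.uint8)
        msk[10:22, 12:24] = 1
        img = rng.integers(0, 255, (32, 32)).astype(np.uint8)
        spec = AugmentationSpec(rotation_max_deg=10.0)
        _, rot, theta = random_rotate(img, msk, spec, rng, return_angle=True)
        from thromboseg.augment import _rotate

        back = _rotate(rot, -theta, order=0)
        assert compute_metrics(back, msk).Dice >= 0.95

    def test_mask_binary_after_rotation(self, rng):
        spec = AugmentationSpec(rotation_max_deg=10.0)
        msk = (rng.random((16, 16)) < 0.4).astype(np.uint8)
        _, out = random_rotate(rng.integers(0, 255, (16, 16)).astype(np.uint8), msk, spec, rng)
        assert set(np.unique(out)) <= {0, 1}


class TestSequenceAugment:
    def _seq(self, rng, n=3, size=16):
        pairs = [
            (
                rng.integers(0, 255, (size, size)).astype(np.uint8),
                AttentionMap(rng.random((size, size))),
            )
            for _ in range(n)
        ]
        return PairSequence(pairs, (n - 1) // 2, [False] * n)

    def test_single_transform_shared_across_pairs(self, rng):
        """All N slices get the same warp: warped constant grids agree."""
        grid = np.tile(np.arange(16, dtype=np.float64), (16, 1)) * 16
        pairs = [(grid.copy(), AttentionMap(grid / grid.max())) for _ in range(3)]
        seq = PairSequence(pairs, 1, [False] * 3)
        gt = (grid > 100).astype(np.uint8)
        spec = AugmentationSpec(seed=4, rotation_max_deg=0.0)
        out, _ = augment_pair_sequence(seq, gt, spec)
        warped = [p[0] for p in out.pairs]
        assert np.array_equal(warped[0], warped[1])
        assert np.array_equal(warped[1], warped[2])

    def test_gt_and_target_image_consistent(self, rng):
        """The GT mask moves with the target image under the shared warp."""
        img = np.zeros((24, 24), np.uint8)
        img[8:16, 8:16] = 200
        gt = (img > 0).astype(np.uint8)
        pairs = [(img.copy(), AttentionMap(gt.astype(float))) for _ in range(3)]
        seq = PairSequence(pairs, 1, [False] * 3)
        spec = AugmentationSpec(seed=7)
        out, gt_out = augment_pair_sequence(seq, gt, spec)
        moved = (out.pairs[1][0] > 100).astype(np.uint8)
        assert compute_metrics(moved, gt_out).Dice >= 0.9

    def test_disabled_spec_is_identity(self, rng):
        seq = self._seq(rng)
        gt = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        out, gt_out = augment_pair_sequence(seq, gt, AugmentationSpec(enabled=False))
        assert out is seq and np.array_equal(gt_out, gt)

    def test_deterministic_given_seed(self, rng):
        seq = self._seq(rng)
        gt = (rng.random((16, 16)) < 0.3).astype(np.uint8)
        spec = AugmentationSpec(seed=11)
        a_seq, a_gt = augment_pair_sequence(seq, gt, spec)
        b_seq, b_gt = augment_pair_sequence(seq, gt, spec)
        assert np.array_equal(a_gt, b_gt)
        for (ai, aa), (bi, ba) in zip(a_seq.pairs, b_seq.pairs):
            assert np.array_equal(ai, bi) and np.array_equal(aa.values, ba.values)
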