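import numpy as np
import pytest

from priorseg.inference import (
    InferenceConfig,
    keep_largest_component,
    merge_with_priors,
    plan_tiles,
    predict_volume,
    segment_subject,
)
from priorseg.model import Network, build_network
from priorseg.priors import PriorSet, build_priors, coordinate_images
from priorseg.volumes import CommonSpaceVolume, LabelMap


def tile_coverage(centers, side, shape):
    cov = np.zeros(shape, dtype=np.int32)
    half = side // 2
    for c in centers:
        sl = tuple(slice(max(x - half, 0), min(x - half + side, s)) for x, s in zip(c, shape))
        cov[sl] += 1
    return cov


def uniform_net(n_channels=1, n_classes=3, depth=2):
    """Zero-weight network: constant 1/C probabilities everywhere."""
    net = Network(build_network(depth, 4, n_channels, n_classes), np.random.default_rng(0))
    for name, p in net.parameters().items():
        if name != "bn.gamma":
            p[...] = 0.0
    return net


class TestPlanTiles:
    def test_single_voxel_needs_few_tiles(self):
        mask = np.zeros((30, 30, 30), bool)
        mask[15, 15, 15] = True
        centers = plan_tiles(mask, 9, 4)
        assert len(centers) <= int(np.ceil(9 / 4)) ** 3
        cov = tile_coverage(centers, 9, mask.shape)
        assert cov[15, 15, 15] >= 1

    def test_disjoint_tiling_at_full_stride(self):
        mask = np.zeros((40, 40, 40), bool)
        mask[3:31, 5:23, 7:16] = True
        centers = plan_tiles(mask, 9, 9)
        cov = tile_coverage(centers, 9, mask.shape)
        assert cov.max() == 1  # disjoint
        assert (cov[mask] >= 1).all()
        extents = (28, 18, 9)
        expected = np.prod([int(np.ceil(e / 9)) for e in extents])
        assert len(centers) == expected

    @pytest.mark.parametrize("stride", [1, 2, 4, 9])
    def test_full_coverage_for_random_masks(self, stride):
        rng = np.random.default_rng(stride)
        for _ in range(5):
            mask = np.zeros((36, 36, 36), bool)
            n_blobs = rng.integers(1, 4)
            for _ in range(n_blobs):
                c = rng.integers(4, 32, size=3)
                r = rng.integers(1, 5)
                sl = tuple(slice(max(x - r, 0), min(x + r, 36)) for x in c)
                mask[sl] = True
            centers = plan_tiles(mask, 9, stride)
            cov = tile_coverage(centers, 9, mask.shape)
            assert (cov[mask] >= 1).all()

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            plan_tiles(np.zeros((10, 10, 10), bool), 9, 4)

    def test_overlarge_stride_rejected(self):
        mask = np.ones((12, 12, 12), bool)
        with pytest.raises(ValueError, match="stride"):
            plan_tiles(mask, 9, 10)


class TestPredictVolume:
    def test_constant_model_gives_constant_average(self):
        net = uniform_net()
        vol = CommonSpaceVolume(np.random.default_rng(0).normal(size=(30, 30, 30)).astype(np.float32))
        mask = np.zeros((30, 30, 30), bool)
        mask[10:20, 10:20, 10:20] = True
        centers = plan_tiles(mask, 9, 4)
        probs, counts = predict_volume(net, vol, centers, InferenceConfig(stride=4))
        covered = counts > 0
        assert (counts[mask] >= 1).all()
        assert np.allclose(probs[:, covered], 1.0 / 3.0, atol=1e-6)
        assert (probs[:, ~covered] == 0).all()

    def test_simplex_preserved_under_overlap_averaging(self):
        net = Network(build_network(2, 4, 1, 3), np.random.default_rng(3))
        vol = CommonSpaceVolume(np.random.default_rng(1).normal(size=(26, 26, 26)).astype(np.float32))
        mask = np.zeros((26, 26, 26), bool)
        mask[8:18, 8:18, 8:18] = True
        centers = plan_tiles(mask, 9, 2)  # heavy overlap
        probs, counts = predict_volume(net, vol, centers, InferenceConfig(stride=2))
        covered = counts > 0
        assert np.allclose(probs[:, covered].sum(axis=0), 1.0, atol=1e-5)

    def test_no_overlap_equals_single_tile_output(self):
        net = Network(build_network(2, 4, 1, 3), np.random.default_rng(4))
        vol = CommonSpaceVolume(np.random.default_rng(2).normal(size=(30, 30, 30)).astype(np.float32))
        mask = np.zeros((30, 30, 30), bool)
        mask[11:20, 11:20, 11:20] = True  # exactly one 9^3 tile
        centers = plan_tiles(mask, 9, 9)
        assert len(centers) == 1
        probs, counts = predict_volume(net, vol, centers, InferenceConfig(stride=9))
        assert counts.max() == 1
        from priorseg.volumes import extract_patch, normalize_appearance

        patch = normalize_appearance(extract_patch(vol.data, tuple(centers[0]), 13).channels[0])
        single = net.forward(patch[None, ..., None])
        assert np.allclose(np.moveaxis(single[0], -1, 0), probs[:, 11:20, 11:20, 11:20], atol=1e-6)


def _tiny_priors(shape=(12, 12, 12)):
    b1 = np.zeros(shape, bool)
    b1[2:6, 2:6, 2:6] = True
    p1 = np.zeros(shape, bool)
    p1[7:9, 7:9, 7:9] = True
    return PriorSet(
        working_volumes={1: b1},
        positive_volumes={1: p1},
        global_volume=b1,
        coordinates=coordinate_images(shape),
    )


class TestMergeWithPriors:
    def test_background_probabilities_leave_only_positive_volumes(self):
        priors = _tiny_priors()
        probs = np.zeros((2, 12, 12, 12))
        probs[0] = 1.0  # all background
        lab = merge_with_priors(probs, priors)
        expected = np.zeros((12, 12, 12), dtype=np.int32)
        expected[priors.positive_volumes[1]] = 1
        assert np.array_equal(lab.data, expected)

    def test_positive_volume_overrides_network_output(self):
        priors = _tiny_priors()
        probs = np.zeros((2, 12, 12, 12))
        probs[0] = 1.0
        probs[:, 7:9, 7:9, 7:9] = [[[[1.0]]], [[[0.0]]]]  # network says background in P^1
        lab = merge_with_priors(probs, priors)
        assert (lab.data[priors.positive_volumes[1]] == 1).all()

    def test_handbuilt_5cube_matches_voxel_merge_oracle(self):
        shape = (5, 5, 5)
        b1 = np.zeros(shape, bool)
        b1[1:4, 1:4, 1:4] = True
        p1 = np.zeros(shape, bool)
        p1[0, 0, 0] = True
        priors = PriorSet({1: b1}, {1: p1}, b1, coordinate_images(shape))
        rng = np.random.default_rng(0)
        probs = rng.dirichlet([1, 1], size=shape).transpose(3, 0, 1, 2)
        lab = merge_with_priors(probs, priors)
        expected = np.zeros(shape, dtype=np.int32)
        for x in range(5):
            for y in range(5):
                for z in range(5):
                    if p1[x, y, z]:
                        expected[x, y, z] = 1
                    elif b1[x, y, z]:
                        expected[x, y, z] = int(np.argmax(probs[:, x, y, z]))
        assert np.array_equal(lab.data, expected)

    def test_argmax_ties_take_lowest_class(self):
        priors = _tiny_priors()
        probs = np.full((2, 12, 12, 12), 0.5)
        lab = merge_with_priors(probs, priors)
        assert (lab.data[priors.global_volume] == 0).all()

    def test_voxels_outside_B_and_P_are_background(self):
        priors = _tiny_priors()
        probs = np.zeros((2, 12, 12, 12))
        probs[1] = 1.0  # network says class 1 everywhere
        lab = merge_with_priors(probs, priors)
        outside = ~(priors.global_volume | priors.positive_volumes[1])
        assert (lab.data[outside] == 0).all()

    def test_overlapping_positive_volumes_rejected(self):
        priors = _tiny_priors()
        priors = PriorSet(
            {1: priors.working_volumes[1], 2: priors.working_volumes[1].copy()},
            {1: priors.positive_volumes[1], 2: np.zeros((12, 12, 12), bool)},
            priors.global_volume,
            coordinate_images((12, 12, 12)),
        )
        priors.positive_volumes[2] = priors.positive_volumes[1]  # corrupt after validation
        probs = np.zeros((3, 12, 12, 12))
        probs[0] = 1.0
        with pytest.raises(ValueError, match="overlap"):
            merge_with_priors(probs, priors)


class TestKeepLargestComponent:
    def test_small_component_removed(self):
        lab = np.zeros((12, 12, 12), dtype=np.int32)
        lab[1:3, 1:3, 1:3] = 1  # 8 voxels... make it 10 vs 3
        lab[1, 3, 1] = 1
        lab[1, 3, 2] = 1
        lab[9:12, 9, 9] = 1  # separate 3-voxel cluster
        out = keep_largest_component(LabelMap(lab, 2), 26)
        assert (out.data[9:12, 9, 9] == 0).all()
        assert out.data.sum() == 10

    def test_single_component_unchanged(self):
        lab = np.zeros((8, 8, 8), dtype=np.int32)
        lab[2:5, 2:5, 2:5] = 1
        out = keep_largest_component(LabelMap(lab, 2))
        assert np.array_equal(out.data, lab)

    def test_empty_class_unchanged(self):
        lab = np.zeros((6, 6, 6), dtype=np.int32)
        out = keep_largest_component(LabelMap(lab, 3))
        assert np.array_equal(out.data, lab)

    def test_idempotent(self, rng):
        lab = (rng.random((14, 14, 14)) > 0.7).astype(np.int32)
        lm = LabelMap(lab, 2)
        once = keep_largest_component(lm)
        twice = keep_largest_component(once)
        assert np.array_equal(once.data, twice.data)

    def test_diagonal_voxels_connected_at_26_not_6(self):
        lab = np.zeros((6, 6, 6), dtype=np.int32)
        lab[1, 1, 1] = 1
        lab[2, 2, 2] = 1  # diagonal neighbor
        lab[4, 4, 4] = 1  # isolated
        out26 = keep_largest_component(LabelMap(lab, 2), 26)
        assert out26.data.sum() == 2
        lab6 = np.zeros((6, 6, 6), dtype=np.int32)
        lab6[1, 1, 1] = 1
        lab6[2, 2, 2] = 1
        out6 = keep_largest_component(LabelMap(lab6, 2), 6)
        assert out6.data.sum() == 1  # diagonal pair split, lowest id kept


class TestSegmentSubject:
    def test_deterministic_and_postproc_only_removes(self, tiny_cohort):
        from priorseg.priors import build_priors

        priors = build_priors([s.labels for s in tiny_cohort[:4]])
        net = Network(build_network(2, 4, 4, 3), np.random.default_rng(0))
        cfg = InferenceConfig(stride=4, batch_size=32)
        seg1 = segment_subject(net, tiny_cohort[4].image, priors, cfg)
        seg2 = segment_subject(net, tiny_cohort[4].image, priors, cfg)
        assert np.array_equal(seg1.labels.data, seg2.labels.data)
        on = seg1.labels.data
        off = seg1.labels_before_postprocessing.data
        assert ((on != 0) <= (off != 0)).all()  # postprocessing only removes
        # every positive-volume voxel carries its class
        for c in priors.classes:
            assert (off[priors.positive_volumes[c]] == c).all()
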