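"""Measurement core: crops, segmentation, distances, Pearson, angles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from _oracles import brute_force_segment, pearson_sum_formula
from fociquant import (
    ImageStack3D,
    SceneParams,
    SeedPoint,
    SegmentationParams,
    SubVolume,
    VoxelSize,
    extract_subvolume,
    make_spot_scene,
    measure_pair,
    pair_distance,
    pearson_pair,
    random_angle_baseline,
    segment_focus,
    triple_angle,
)
from fociquant.foci import BoundaryError, FocusSegmentation, angle_at_vertex


def _stack(shape=(21, 128, 128), fill=1.0, n_channels=1):
    return ImageStack3D(
        [np.full(shape, fill, dtype=np.float64) for _ in range(n_channels)],
        voxel=VoxelSize(),
        stack_id="t",
    )


def _seg_at(centroid_nm, degenerate=False):
    return FocusSegmentation(
        mask=np.ones((1, 1, 1), dtype=bool),
        clip_value=1.0,
        threshold=0.9,
        centroid_nm=np.asarray(centroid_nm, dtype=float),
        n_voxels=1,
        volume_um3=VoxelSize().volume_um3,
        degenerate=degenerate,
    )


class TestExtractSubvolume:
    def test_centred_crop_origin(self):
        stack = _stack()
        sub = extract_subvolume(stack, SeedPoint("t", "L", 0, 50, 60, 10))
        assert sub.origin == (40, 50, 7)
        assert sub.data.shape == (7, 20, 20)

    def test_crop_matches_parent_window(self):
        rng = np.random.default_rng(1)
        stack = ImageStack3D([rng.random((21, 64, 64))], voxel=VoxelSize())
        sub = extract_subvolume(stack, SeedPoint("t", "L", 0, 30, 25, 9))
        window = stack.channels[0][6:13, 15:35, 20:40]
        assert sub.data.sum() == pytest.approx(window.sum(), rel=1e-12)
        assert np.array_equal(sub.data, window)

    def test_boundary_seed_rejected(self):
        with pytest.raises(BoundaryError, match="L"):
            extract_subvolume(_stack(), SeedPoint("t", "L", 0, 3, 3, 1))

    def test_crop_owns_its_memory(self):
        stack = _stack()
        sub = extract_subvolume(stack, SeedPoint("t", "L", 0, 50, 60, 10))
        sub.data[:] = 99.0
        assert stack.channels[0].max() == 1.0


class TestSegmentFocus:
    def test_enumerated_clip_threshold_example(self):
        """2800-voxel crop with 2599 zeros, 50 at 60, 150 at 100 and one hot
        voxel at 250: nearest-rank clip at 100, threshold 90, mask 151."""
        data = np.zeros((7, 20, 20))
        data[1:6, 5:11, 5:10] = 100.0  # 150-voxel blob
        data[3, 7, 10] = 250.0  # hot voxel, 26-connected to the blob
        data[0, 15:20, 10:20] = 60.0  # 50 voxels below threshold
        assert np.count_nonzero(data == 100.0) == 150
        assert np.count_nonzero(data == 60.0) == 50

        sub = SubVolume(origin=(0, 0, 0), data=data, voxel=VoxelSize())
        seg = segment_focus(sub, SegmentationParams())
        assert seg.clip_value == 100.0
        assert seg.threshold == 90.0
        assert seg.n_voxels == 151
        assert seg.volume_um3 == pytest.approx(151 * 624037.5 / 1e9, rel=1e-12)
        assert seg.volume_um3 == pytest.approx(0.09423, abs=5e-6)

    @pytest.mark.parametrize("crop_seed", range(12))
    def test_matches_sort_based_oracle_on_random_crops(self, crop_seed):
        """Segmentation equals an exhaustive sort/BFS re-implementation on
        integer-valued crops (mask, clip, threshold, centroid, volume)."""
        rng = np.random.default_rng(crop_seed)
        data = rng.poisson(3.0, size=(7, 20, 20)).astype(float)
        # add one or two bright blobs at random spots
        for _ in range(rng.integers(1, 3)):
            z, y, x = rng.integers(1, 5), rng.integers(3, 16), rng.integers(3, 16)
            data[z : z + 2, y : y + 3, x : x + 3] += rng.integers(50, 200)
        sub = SubVolume(origin=(4, 6, 2), data=data, voxel=VoxelSize())
        seg = segment_focus(sub, SegmentationParams())
        ref = brute_force_segment(data)
        assert seg.clip_value == ref["clip_value"]
        assert seg.threshold == ref["threshold"]
        assert np.array_equal(seg.mask, ref["mask"])
        assert seg.n_voxels == ref["n_voxels"]
        expected_nm = (np.array((4, 6, 2)) + ref["centroid_local_xyz"]) * (64.5, 64.5, 150.0)
        assert np.allclose(seg.centroid_nm, expected_nm, atol=1e-9)
        assert seg.volume_um3 == seg.n_voxels * 624037.5 / 1e9

    def test_symmetric_gaussian_centroids_at_crop_centre(self):
        zz, yy, xx = np.mgrid[0:7, 0:20, 0:20].astype(float)
        data = 200 * np.exp(
            -0.5 * (((zz - 3) / 1.5) ** 2 + ((yy - 9.5) / 2) ** 2 + ((xx - 9.5) / 2) ** 2)
        )
        sub = SubVolume(origin=(0, 0, 0), data=data, voxel=VoxelSize())
        seg = segment_focus(sub)
        centre_vox = seg.centroid_nm / (64.5, 64.5, 150.0)
        assert np.all(np.abs(centre_vox - (9.5, 9.5, 3.0)) < 0.05)

    def test_constant_crop_is_degenerate_not_an_error(self):
        sub = SubVolume(origin=(0, 0, 0), data=np.full((7, 20, 20), 10.0), voxel=VoxelSize())
        seg = segment_focus(sub)
        assert seg.degenerate
        assert seg.n_voxels == 7 * 20 * 20

    def test_all_zero_crop_raises(self):
        sub = SubVolume(origin=(0, 0, 0), data=np.zeros((7, 20, 20)), voxel=VoxelSize())
        with pytest.raises(ValueError, match="all zero"):
            segment_focus(sub)

    def test_every_masked_voxel_meets_threshold(self):
        rng = np.random.default_rng(7)
        data = rng.poisson(5.0, size=(7, 20, 20)).astype(float)
        data[2:5, 8:12, 8:12] += 120
        sub = SubVolume(origin=(0, 0, 0), data=data, voxel=VoxelSize())
        seg = segment_focus(sub)
        clipped = np.minimum(data, seg.clip_value)
        assert np.all(clipped[seg.mask] >= seg.threshold)
        assert seg.threshold == 0.9 * clipped.max()

    def test_fraction_of_max_clip_mode(self):
        data = np.zeros((7, 20, 20))
        data[3, 9:12, 9:12] = 100.0
        data[3, 10, 10] = 200.0
        sub = SubVolume(origin=(0, 0, 0), data=data, voxel=VoxelSize())
        seg = segment_focus(sub, SegmentationParams(clip_mode="fraction_of_max"))
        assert seg.clip_value == pytest.approx(0.965 * 200.0)
        assert seg.threshold == pytest.approx(0.9 * 0.965 * 200.0)


class TestPairDistance:
    def test_identical_centroids(self):
        assert pair_distance(_seg_at((1, 2, 3)), _seg_at((1, 2, 3))) == 0.0

    def test_ten_pixel_offset_is_645_nm(self):
        a = _seg_at((0.0, 0.0, 0.0))
        b = _seg_at((645.0, 0.0, 0.0))
        assert pair_distance(a, b) == pytest.approx(645.0)

    def test_noise_free_500nm_pair_recovered_within_half_pixel(self, noise_free_pair_scene):
        stack, truth, seeds = noise_free_pair_scene
        m = measure_pair(stack, seeds[0], seeds[1])
        assert abs(m.distance_nm - 500.0) <= 32.0

    def test_degenerate_input_flagged_not_raised(self):
        d = pair_distance(_seg_at((0, 0, 0), degenerate=True), _seg_at((1, 1, 1)))
        assert np.isnan(d)

    @given(
        pts=st.lists(
            st.tuples(*[st.floats(-5000, 5000)] * 3), min_size=3, max_size=3
        )
    )
    def test_symmetry_and_triangle_inequality(self, pts):
        a, b, c = (_seg_at(p) for p in pts)
        dab, dba = pair_distance(a, b), pair_distance(b, a)
        assert dab == dba
        assert pair_distance(a, c) <= dab + pair_distance(b, c) + 1e-9

    def test_median_distance_increases_with_true_separation(self):
        """Monotone recovery over true separations 200..1400 nm at fixed SNR."""
        medians = []
        for sep in (200.0, 400.0, 600.0, 800.0, 1000.0, 1200.0, 1400.0):
            measured = []
            for seed in range(8):
                stack, truth, seeds = make_spot_scene(
                    SceneParams(
                        n_loci=1,
                        shape=(27, 72, 72),
                        separation_nm=sep,
                        seed=1000 + int(sep) + seed,
                    )
                )
                m = measure_pair(stack, seeds[0], seeds[1])
                if not np.isnan(m.distance_nm):
                    measured.append(m.distance_nm)
            medians.append(np.median(measured))
        assert all(b > a for a, b in zip(medians, medians[1:]))


class TestPearson:
    def _sub(self, data, origin=(0, 0, 0)):
        return SubVolume(origin=origin, data=np.asarray(data, float), voxel=VoxelSize())

    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        a = self._sub(rng.random((7, 20, 20)))
        assert pearson_pair(a, a) == pytest.approx(1.0)

    def test_negation_about_mean_is_minus_one(self):
        rng = np.random.default_rng(1)
        data = rng.random((7, 20, 20))
        flipped = 2 * data.mean() - data
        assert pearson_pair(self._sub(data), self._sub(flipped)) == pytest.approx(-1.0)

    def test_matches_textbook_sum_formula(self):
        stack, _, _ = make_spot_scene(
            SceneParams(n_loci=1, separation_nm=400.0, seed=12)
        )
        s0 = extract_subvolume(stack, SeedPoint("scene", "L", 0, 32, 32, 10))
        s1 = extract_subvolume(stack, SeedPoint("scene", "L", 1, 32, 32, 10))
        r = pearson_pair(s0, s1)
        assert r == pytest.approx(pearson_sum_formula(s0.data, s1.data), abs=1e-12)
        assert -1.0 <= r <= 1.0

    def test_zero_variance_is_undefined(self):
        rng = np.random.default_rng(2)
        a = self._sub(np.full((7, 20, 20), 3.0))
        b = self._sub(rng.random((7, 20, 20)))
        assert np.isnan(pearson_pair(a, b))

    def test_mismatched_origins_rejected(self):
        a = self._sub(np.ones((7, 20, 20)), origin=(0, 0, 0))
        b = self._sub(np.ones((7, 20, 20)), origin=(1, 0, 0))
        with pytest.raises(ValueError, match="origin"):
            pearson_pair(a, b)

    def test_colocalized_pairs_correlate_more_than_separated(self):
        """The colocalization readout orders 0 nm above 1000 nm separations
        in nearly all fields — the direction of a true overlap shift."""
        wins = 0
        n = 20
        for seed in range(n):
            r_pair = []
            for sep in (0.0, 1000.0):
                stack, _, seeds = make_spot_scene(
                    SceneParams(n_loci=1, separation_nm=sep, seed=3000 + seed)
                )
                m = measure_pair(stack, seeds[0], seeds[1])
                r_pair.append(m.pearson_r)
            if r_pair[0] > r_pair[1]:
                wins += 1
        assert wins >= 0.95 * n


class TestTripleAngle:
    def test_orthogonal_arms_90_degrees(self):
        t = triple_angle(
            _seg_at((0, 0, 0)), _seg_at((1000, 0, 0)), _seg_at((0, 1000, 0))
        )
        assert t.theta_deg == pytest.approx(90.0, abs=1e-9)

    def test_collinear_cases(self):
        straight = triple_angle(
            _seg_at((0, 0, 0)), _seg_at((-1000, 0, 0)), _seg_at((2000, 0, 0))
        )
        assert straight.theta_deg == pytest.approx(180.0, abs=1e-9)
        folded = triple_angle(
            _seg_at((0, 0, 0)), _seg_at((1000, 0, 0)), _seg_at((2000, 0, 0))
        )
        assert folded.theta_deg == pytest.approx(0.0, abs=1e-9)

    def test_law_of_cosines_identity_holds(self):
        t = triple_angle(
            _seg_at((10, 20, 30)), _seg_at((500, -100, 250)), _seg_at((-300, 400, 90))
        )
        rhs = t.a_nm**2 + t.b_nm**2 - 2 * t.a_nm * t.b_nm * np.cos(np.radians(t.theta_deg))
        assert t.c_nm**2 == pytest.approx(rhs, rel=1e-9)

    def test_coincident_vertex_and_arm_rejected(self):
        with pytest.raises(ValueError, match="undefined|coincide"):
            triple_angle(_seg_at((0, 0, 0)), _seg_at((0, 0, 0)), _seg_at((1, 0, 0)))

    def test_degenerate_segmentation_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            triple_angle(
                _seg_at((0, 0, 0), degenerate=True), _seg_at((1, 0, 0)), _seg_at((0, 1, 0))
            )

    def test_matches_dot_product_oracle_over_many_draws(self):
        """Law-of-cosines angles equal the arccos of the normalised dot
        product to 1e-9 degrees over 10^4 random triples."""
        rng = np.random.default_rng(42)
        pts = rng.normal(size=(10_000, 3, 3)) * 1000
        loc = angle_at_vertex(pts[:, 1], pts[:, 0], pts[:, 2])
        u = pts[:, 0] - pts[:, 1]
        v = pts[:, 2] - pts[:, 1]
        cos = np.einsum("ij,ij->i", u, v) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
        )
        dot = np.degrees(np.arccos(np.clip(cos, -1, 1)))
        assert np.max(np.abs(loc - dot)) < 1e-9


class TestRandomAngleBaseline:
    def test_mean_near_sixty_degrees(self):
        mean, median = random_angle_baseline(10_000, seed=0)
        # SE of the mean is ~0.3 deg at n=10^4
        assert abs(mean - 60.0) < 1.0
        assert 0 <= median <= 180

    def test_single_draw_in_bounds_and_deterministic(self):
        m1 = random_angle_baseline(1, seed=5)
        m2 = random_angle_baseline(1, seed=5)
        assert m1 == m2
        assert 0.0 <= m1[0] <= 180.0

    def test_same_seed_reproduces(self):
        assert random_angle_baseline(500, seed=9) == random_angle_baseline(500, seed=9)

    def test_requires_positive_n(self):
        with pytest.raises(ValueError):
            random_angle_baseline(0)
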