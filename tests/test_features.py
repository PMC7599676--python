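"""Texture matrices vs brute-force enumeration, hand-computed feature
values, shape limits and rotation robustness."""

import numpy as np
import pytest

from meningrad import PhantomSpec, ROIMask, VoxelGrid, extract_features, generate_phantom
from meningrad.features import (
    DIRECTIONS_13,
    GLCM,
    cluster_prominence,
    compute_glcm,
    compute_glrlm,
    compute_glszm,
    difference_entropy,
    first_order,
    high_intensity_large_area_emphasis,
    inverse_difference_normalized,
    low_intensity_large_area_emphasis,
    low_intensity_small_area_emphasis,
    run_length_nonuniformity,
    short_run_low_gray_emphasis,
    spherical_disproportion,
)

from conftest import disc_from_levels, grid_mask_from
from oracles import (
    glcm_counts_brute,
    glrlm_counts_brute,
    glszm_zones_brute,
)


class TestGLCM:
    def test_hand_enumerable_2x2(self):
        levels = np.array([[[1], [1]], [[2], [2]]], dtype=np.int32)  # 2x2x1
        disc = disc_from_levels(levels, ng=2)
        g = compute_glcm(disc)
        counts = glcm_counts_brute(levels, 2)
        np.testing.assert_array_equal(g.matrix, counts / counts.sum())

    def test_constant_roi_all_mass_at_origin(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        g = compute_glcm(disc_from_levels(levels, ng=32))
        assert g.matrix[0, 0] == 1.0
        assert g.matrix.sum() == pytest.approx(1.0)

    def test_single_voxel_has_no_pairs(self):
        levels = np.zeros((3, 3, 3), dtype=np.int32)
        levels[1, 1, 1] = 1
        with pytest.raises(ValueError, match="no co-occurrences"):
            compute_glcm(disc_from_levels(levels, ng=2))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_and_symmetric(self, seed):
        from oracles import random_levels

        rng = np.random.default_rng(seed)
        levels = random_levels(rng, ng=4)
        if (levels > 0).sum() < 2:
            pytest.skip("degenerate ROI")
        g = compute_glcm(disc_from_levels(levels, ng=4))
        counts = glcm_counts_brute(levels, 4)
        assert counts.sum() > 0
        np.testing.assert_array_equal(g.matrix, counts / counts.sum())
        np.testing.assert_array_equal(g.matrix, g.matrix.T)
        assert abs(g.matrix.sum() - 1.0) < 1e-9


class TestGLCMFeatures:
    def test_single_cell_glcm_degenerate_values(self):
        m = np.zeros((4, 4))
        m[0, 0] = 1.0
        g = GLCM(matrix=m, ng=4)
        assert cluster_prominence(g) == 0.0
        assert difference_entropy(g) == 0.0
        assert inverse_difference_normalized(g) == 1.0

    def test_cluster_prominence_two_diagonal_cells(self):
        # p = 1/2 at (1,1) and (2,2): mu_i = mu_j = 1.5, value = 1
        m = np.zeros((2, 2))
        m[0, 0] = m[1, 1] = 0.5
        assert cluster_prominence(GLCM(matrix=m, ng=2)) == pytest.approx(1.0, abs=1e-12)

    def test_cluster_prominence_shift_invariant(self):
        # embedding the same 2-level pattern at higher levels leaves CP unchanged
        for offset in (0, 3, 7):
            m = np.zeros((12, 12))
            m[offset, offset] = 0.4
            m[offset + 1, offset + 1] = 0.3
            m[offset, offset + 1] = m[offset + 1, offset] = 0.15
            if offset == 0:
                ref = cluster_prominence(GLCM(matrix=m, ng=12))
            else:
                assert cluster_prominence(GLCM(matrix=m, ng=12)) == pytest.approx(
                    ref, rel=1e-12
                )

    def test_difference_entropy_fair_coin(self):
        # p_{x-y} uniform over two values -> 1 bit
        m = np.zeros((4, 4))
        m[0, 0] = 0.5  # k = 0
        m[0, 1] = m[1, 0] = 0.25  # k = 1
        assert difference_entropy(GLCM(matrix=m, ng=4)) == pytest.approx(1.0)

    def test_difference_entropy_matches_brute_sum(self):
        rng = np.random.default_rng(9)
        raw = rng.random((8, 8))
        m = (raw + raw.T) / (raw + raw.T).sum()
        g = GLCM(matrix=m, ng=8)
        # independent re-summation
        expected = 0.0
        for k in range(8):
            pk = sum(
                m[i, j] for i in range(8) for j in range(8) if abs(i - j) == k
            )
            if pk > 0:
                expected -= pk * np.log2(pk)
        assert difference_entropy(g) == pytest.approx(expected, abs=1e-12)
        assert 0 <= difference_entropy(g) <= np.log2(8)

    def test_idn_extreme_offdiagonal(self):
        m = np.zeros((32, 32))
        m[0, 31] = 0.5
        m[31, 0] = 0.5
        assert inverse_difference_normalized(GLCM(matrix=m, ng=32)) == pytest.approx(
            32.0 / 63.0
        )

    def test_idn_decreases_with_offdiagonal_mass(self):
        prev = None
        for off_mass in (0.0, 0.2, 0.5, 0.9):
            m = np.zeros((8, 8))
            m[0, 0] = 1 - off_mass
            m[0, 5] = m[5, 0] = off_mass / 2
            v = inverse_difference_normalized(GLCM(matrix=m, ng=8))
            if prev is not None:
                assert v < prev
            prev = v


class TestGLRLM:
    def test_1d_hand_example(self):
        levels = np.array([1, 1, 2], dtype=np.int32).reshape(3, 1, 1)
        per_dir = compute_glrlm(disc_from_levels(levels, ng=2), aggregate="per-direction")
        ax = DIRECTIONS_13.index((1, 0, 0))
        r = per_dir[ax]
        # runs: level 1 length 2, level 2 length 1
        assert r.matrix[0, 1] == 1 and r.matrix[1, 0] == 1 and r.matrix.sum() == 2
        assert run_length_nonuniformity(r) == pytest.approx(1.0)
        assert short_run_low_gray_emphasis(r) == pytest.approx(0.25)

    def test_constant_cube_axis_runs(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        per_dir = compute_glrlm(disc_from_levels(levels, ng=2), aggregate="per-direction")
        ax = DIRECTIONS_13.index((1, 0, 0))
        # 9 lines along an axis, each one run of length 3
        assert per_dir[ax].matrix[0, 2] == 9
        assert per_dir[ax].matrix.sum() == 9

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_line_scan_oracle_per_direction(self, seed):
        from oracles import random_levels

        rng = np.random.default_rng(100 + seed)
        levels = random_levels(rng, ng=3)
        per_dir = compute_glrlm(disc_from_levels(levels, ng=3), aggregate="per-direction")
        n_vox = int((levels > 0).sum())
        for d, r in zip(DIRECTIONS_13, per_dir):
            expected = glrlm_counts_brute(levels, d)
            got = {
                (i + 1, j + 1): int(r.matrix[i, j])
                for i, j in zip(*np.nonzero(r.matrix))
            }
            assert got == expected
            # voxel conservation per direction
            j = np.arange(1, r.matrix.shape[1] + 1)
            assert int((r.matrix * j).sum()) == n_vox


class TestGLSZM:
    def test_constant_cube_single_zone(self):
        levels = np.ones((2, 2, 2), dtype=np.int32)
        s = compute_glszm(disc_from_levels(levels, ng=1))
        assert s.matrix[0, 7] == 1 and s.matrix.sum() == 1
        assert high_intensity_large_area_emphasis(s) == pytest.approx(64.0)
        assert low_intensity_small_area_emphasis(s) == pytest.approx(1.0 / 64.0)
        assert low_intensity_large_area_emphasis(s) == pytest.approx(64.0)

    def test_all_distinct_levels_give_singleton_zones(self):
        levels = np.arange(1, 9, dtype=np.int32).reshape(2, 2, 2)
        s = compute_glszm(disc_from_levels(levels, ng=8))
        assert s.matrix[:, 0].sum() == 8
        assert s.matrix.sum() == 8

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_flood_fill_oracle(self, seed):
        from oracles import random_levels

        rng = np.random.default_rng(200 + seed)
        levels = random_levels(rng, ng=3)
        s = compute_glszm(disc_from_levels(levels, ng=3))
        zones = glszm_zones_brute(levels)
        expected = np.zeros_like(s.matrix)
        for lv, size in zones:
            expected[lv - 1, size - 1] += 1
        np.testing.assert_array_equal(s.matrix, expected)
        j = np.arange(1, s.matrix.shape[1] + 1)
        assert int((s.matrix * j).sum()) == int((levels > 0).sum())


class TestFirstOrder:
    def test_symmetric_quadruple(self):
        vals = np.zeros((4, 1, 1))
        vals[:, 0, 0] = [1, 2, 3, 4]
        grid, mask = grid_mask_from(vals, np.ones((4, 1, 1)))
        f = first_order(grid, mask)
        assert f == {"mean": 2.5, "median": 2.5, "minimum": 1.0, "skewness": 0.0}

    def test_right_tail_positive_skew(self):
        vals = np.zeros((4, 1, 1))
        vals[:, 0, 0] = [0, 0, 0, 10]
        grid, mask = grid_mask_from(vals, np.ones((4, 1, 1)))
        assert first_order(grid, mask)["skewness"] > 0

    @pytest.mark.parametrize("seed", range(10))
    def test_skewness_matches_moment_formula(self, seed):
        from scipy import stats

        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(6, 6, 6))
        grid, mask = grid_mask_from(vals, np.ones((6, 6, 6)))
        f = first_order(grid, mask)
        assert f["skewness"] == pytest.approx(
            float(stats.skew(vals.ravel(), bias=True)), rel=1e-10
        )


class TestSphericalDisproportion:
    def test_digital_sphere_near_unity(self):
        n = 45
        c = (n - 1) / 2
        x, y, z = np.ogrid[:n, :n, :n]
        sphere = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= 20.0**2
        v = spherical_disproportion(ROIMask(sphere))
        assert 1.00 <= v <= 1.05

    def test_large_cube_closed_form(self):
        cube = np.zeros((36, 36, 36), dtype=bool)
        cube[3:33, 3:33, 3:33] = True
        v = spherical_disproportion(ROIMask(cube))
        expected = 6.0 / (4 * np.pi) * (4 * np.pi / 3) ** (2 / 3)  # ~1.2407
        assert abs(v - expected) / expected < 0.03

    def test_invariant_to_uniform_spacing_scale(self):
        n = 25
        c = (n - 1) / 2
        x, y, z = np.ogrid[:n, :n, :n]
        sphere = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= 10.0**2
        v1 = spherical_disproportion(ROIMask(sphere, spacing=(1.0, 1.0, 1.0)))
        v2 = spherical_disproportion(ROIMask(sphere, spacing=(2.5, 2.5, 2.5)))
        assert v1 == pytest.approx(v2, rel=1e-6)

    def test_mask_touching_border_is_padded(self):
        cube = np.ones((10, 10, 10), dtype=bool)
        v = spherical_disproportion(ROIMask(cube))  # silent pad, no error
        assert v > 1.0


class TestExtractFeatures:
    def test_constant_phantom_degenerate_texture(self, constant_phantom):
        grid, mask, _ = constant_phantom
        feats = extract_features(grid, mask)["original"]
        assert feats["cluster_prominence"] == 0.0
        assert feats["difference_entropy"] == 0.0
        assert feats["inverse_difference_normalized"] == 1.0
        assert feats["mean"] == 100.0 and feats["skewness"] == 0.0

    def test_deterministic_repeat(self, textured_phantom):
        grid, mask, _ = textured_phantom
        a = extract_features(grid, mask)
        b = extract_features(grid, mask)
        assert a == b

    def test_all_13_features_on_original(self, textured_phantom):
        from meningrad.features import FEATURE_NAMES

        grid, mask, _ = textured_phantom
        feats = extract_features(grid, mask)["original"]
        assert set(feats) == set(FEATURE_NAMES)

    def test_rotation_robustness_of_direction_aggregated_features(self, textured_phantom):
        grid, mask, _ = textured_phantom
        rot_g = VoxelGrid(np.rot90(grid.values, axes=(0, 1)).copy(), grid.spacing)
        rot_m = ROIMask(np.rot90(mask.values, axes=(0, 1)).copy(), mask.spacing)
        a = extract_features(grid, mask)["original"]
        b = extract_features(rot_g, rot_m)["original"]
        for name in (
            "cluster_prominence",
            "difference_entropy",
            "inverse_difference_normalized",
            "run_length_nonuniformity",
            "short_run_low_gray_emphasis",
        ):
            assert a[name] == pytest.approx(b[name], rel=1e-9), name

    def test_texture_correlation_separates_cluster_prominence(self):
        highs, lows = [], []
        for seed in range(6):
            for corr, acc in ((3.0, highs), (0.5, lows)):
                grid, mask, _ = generate_phantom(
                    PhantomSpec(
                        grid_shape=(32, 32, 32),
                        tumor_radii_mm=(10, 9, 8),
                        texture_correlation_mm=corr,
                        seed=seed,
                    )
                )
                acc.append(extract_features(grid, mask)["original"]["cluster_prominence"])
        assert np.median(highs) > np.median(lows)
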