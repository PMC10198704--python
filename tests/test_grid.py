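"""Geometry, spheres, mask algebra, components, smoothing and I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ticnet.grid import (
    BinaryMask,
    GridMismatchError,
    ScalarVolume,
    VolumeGrid,
    connected_components,
    dice,
    gaussian_smooth,
    load_mask,
    load_volume,
    make_grid,
    make_sphere_seed,
    resample_mask,
    resample_scalar,
    save_mask,
    save_volume,
    union_masks,
)


class TestVolumeGrid:
    def test_mni_style_origin_maps_to_expected_voxel(self):
        # 2 mm grid whose world origin sits at voxel (45, 63, 36)
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-90.0, -126.0, -72.0]
        grid = VolumeGrid((91, 109, 91), affine)
        assert grid.world_to_voxel((0.0, 0.0, 0.0)) == (45, 63, 36)
        # the affine translation column is the world position of voxel 0
        assert grid.world_to_voxel(affine[:3, 3]) == (0, 0, 0)

    def test_out_of_bounds_coordinate_is_an_error_naming_it(self):
        grid = make_grid((8, 8, 8))
        with pytest.raises(ValueError, match="10000"):
            grid.world_to_voxel((10000.0, 0.0, 0.0))

    def test_rounding_is_half_away_from_zero(self):
        affine = np.diag([2.0, 2.0, 2.0, 1.0])
        affine[:3, 3] = [-8.0, -8.0, -8.0]
        grid = VolumeGrid((9, 9, 9), affine)
        # +/-1 mm is exactly halfway between voxel centres; the tie is broken
        # away from zero in voxel-index space (4.5 -> 5, 3.5 -> 4)
        assert grid.world_to_voxel((1.0, 0.0, 0.0)) == (5, 4, 4)
        assert grid.world_to_voxel((-1.0, 0.0, 0.0)) == (4, 4, 4)

    @settings(deadline=None)
    @given(st.tuples(st.integers(0, 8), st.integers(0, 9), st.integers(0, 10)))
    def test_world_voxel_roundtrip_is_identity(self, idx):
        grid = make_grid((9, 10, 11), voxel_mm=2.0)
        assert grid.world_to_voxel(grid.voxel_to_world(np.array(idx))) == idx

    def test_voxel_size_from_affine_columns(self):
        grid = make_grid((4, 4, 4), voxel_mm=2.5)
        assert np.allclose(grid.voxel_size_mm, 2.5)

    def test_singular_affine_rejected(self):
        bad = np.zeros((4, 4))
        bad[3, 3] = 1.0
        with pytest.raises(ValueError):
            VolumeGrid((4, 4, 4), bad)


class TestSphereSeed:
    def test_4mm_sphere_on_2mm_grid_has_33_voxels(self, grid8):
        center = grid8.voxel_to_world((4, 4, 4))
        seed = make_sphere_seed(center, 4.0, grid8)
        # offsets with (2i)^2+(2j)^2+(2k)^2 <= 16: 1 + 6 + 12 + 8 + 6 = 33
        assert seed.size == 33

    def test_tiny_radius_is_single_voxel(self, grid8):
        center = grid8.voxel_to_world((3, 3, 3))
        assert make_sphere_seed(center, 0.1, grid8).size == 1

    def test_nonpositive_radius_rejected(self, grid8):
        with pytest.raises(ValueError):
            make_sphere_seed((0, 0, 0), 0.0, grid8)

    @settings(deadline=None, max_examples=25)
    @given(
        cx=st.floats(-4, 4), cy=st.floats(-4, 4), cz=st.floats(-4, 4),
        radius=st.floats(0.5, 6.0),
    )
    def test_membership_matches_exhaustive_distance_oracle(self, cx, cy, cz, radius):
        grid = make_grid((8, 8, 8), voxel_mm=2.0)
        seed = make_sphere_seed((cx, cy, cz), radius, grid)
        world = grid.voxel_to_world(np.indices(grid.dims).reshape(3, -1).T)
        d = np.linalg.norm(world - np.array([cx, cy, cz]), axis=1)
        expected = (d <= radius).reshape(grid.dims)
        assert np.array_equal(seed.membership, expected)

    def test_membership_symmetric_about_voxel_centre(self, grid8):
        center_idx = np.array([4, 4, 4])
        seed = make_sphere_seed(grid8.voxel_to_world(center_idx), 5.0, grid8)
        m = seed.membership
        flipped = m[::-1, ::-1, ::-1]  # reflection about (3.5,)*3
        # reflect about the centre voxel instead: index arithmetic
        for idx in np.argwhere(m):
            refl = 2 * center_idx - idx
            if np.all(refl >= 0) and np.all(refl < grid8.dims):
                assert m[tuple(refl)]


class TestMaskAlgebra:
    def test_union_of_disjoint_spheres_adds_sizes(self, grid8):
        a = make_sphere_seed(grid8.voxel_to_world((2, 2, 2)), 2.0, grid8)
        b = make_sphere_seed(grid8.voxel_to_world((6, 6, 6)), 2.0, grid8)
        assert union_masks([a, b]).size == a.size + b.size

    def test_union_is_idempotent_and_matches_or_oracle(self, grid8, rng):
        masks = [BinaryMask(grid8, rng.random(grid8.dims) > 0.7) for _ in range(4)]
        u = union_masks(masks)
        expected = np.zeros(grid8.dims, bool)
        for m in masks:
            expected |= m.membership
        assert np.array_equal(u.membership, expected)
        assert np.array_equal(union_masks([u, u]).membership, u.membership)

    def test_union_rejects_grid_mismatch(self, grid8):
        other = make_grid((8, 8, 8), voxel_mm=3.0)
        a = BinaryMask(grid8, np.zeros(grid8.dims, bool))
        b = BinaryMask(other, np.zeros(other.dims, bool))
        with pytest.raises(GridMismatchError):
            union_masks([a, b])

    def test_dice_of_identical_and_disjoint_masks(self, grid8):
        a = make_sphere_seed(grid8.voxel_to_world((3, 3, 3)), 3.0, grid8)
        b = make_sphere_seed(grid8.voxel_to_world((6, 6, 6)), 1.0, grid8)
        assert dice(a, a) == 1.0
        assert dice(a, b) == 0.0


class TestConnectedComponents:
    def test_single_voxel_single_component(self, grid8):
        m = np.zeros(grid8.dims, bool)
        m[3, 3, 3] = True
        labels, sizes = connected_components(BinaryMask(grid8, m))
        assert list(sizes) == [1]

    def test_corner_touching_voxels_depend_on_connectivity(self, grid8):
        m = np.zeros(grid8.dims, bool)
        m[2, 2, 2] = True
        m[3, 3, 3] = True  # shares only a corner
        _, sizes26 = connected_components(BinaryMask(grid8, m), 26)
        _, sizes6 = connected_components(BinaryMask(grid8, m), 6)
        assert len(sizes26) == 1
        assert len(sizes6) == 2

    def test_empty_mask_has_zero_components(self, grid8):
        _, sizes = connected_components(BinaryMask(grid8, np.zeros(grid8.dims, bool)))
        assert sizes.size == 0

    def test_sizes_sum_to_mask_size(self, grid8, rng):
        m = BinaryMask(grid8, rng.random(grid8.dims) > 0.6)
        for conn in (6, 18, 26):
            _, sizes = connected_components(m, conn)
            assert sizes.sum() == m.size

    def test_invalid_connectivity_rejected(self, grid8):
        with pytest.raises(ValueError):
            connected_components(BinaryMask(grid8, np.zeros(grid8.dims, bool)), 10)


class TestGaussianSmooth:
    def test_zero_fwhm_is_identity(self, grid8, rng):
        vol = ScalarVolume(grid8, rng.standard_normal(grid8.dims))
        out = gaussian_smooth(vol, 0.0)
        assert np.array_equal(out.values, vol.values)

    def test_constant_field_unchanged_and_mass_conserved(self, grid8, rng):
        const = gaussian_smooth(ScalarVolume(grid8, np.full(grid8.dims, 3.0)), 6.0)
        assert np.allclose(const.values, 3.0)
        noisy = ScalarVolume(grid8, rng.standard_normal(grid8.dims))
        assert np.isclose(gaussian_smooth(noisy, 6.0).values.sum(),
                          noisy.values.sum(), rtol=1e-10)

    def test_impulse_half_max_at_half_fwhm(self):
        grid = make_grid((41, 41, 41), voxel_mm=1.0)
        vals = np.zeros(grid.dims)
        vals[20, 20, 20] = 1.0
        fwhm = 8.0
        sm = gaussian_smooth(ScalarVolume(grid, vals), fwhm).values
        ratio = sm[24, 20, 20] / sm[20, 20, 20]  # 4 mm = fwhm/2 away
        assert abs(ratio - 0.5) < 0.01

    def test_negative_fwhm_rejected(self, grid8):
        with pytest.raises(ValueError):
            gaussian_smooth(ScalarVolume(grid8, np.zeros(grid8.dims)), -1.0)


class TestNiftiIO:
    def test_volume_roundtrip_preserves_values_and_affine(self, grid8, rng, tmp_path):
        vol = ScalarVolume(grid8, rng.standard_normal(grid8.dims).astype(np.float32))
        save_volume(vol, tmp_path / "vol.nii.gz")
        back = load_volume(tmp_path / "vol.nii.gz")
        assert np.allclose(back.values, vol.values, atol=1e-6)
        assert back.grid.matches(grid8)

    def test_mask_roundtrip(self, grid8, rng, tmp_path):
        mask = BinaryMask(grid8, rng.random(grid8.dims) > 0.5, label="m")
        save_mask(mask, tmp_path / "mask.nii.gz")
        back = load_mask(tmp_path / "mask.nii.gz")
        assert np.array_equal(back.membership, mask.membership)


class TestResampling:
    def test_resample_to_same_grid_is_identity(self, grid8, rng):
        mask = BinaryMask(grid8, rng.random(grid8.dims) > 0.5)
        vol = ScalarVolume(grid8, rng.standard_normal(grid8.dims))
        assert np.array_equal(resample_mask(mask, grid8).membership, mask.membership)
        assert np.allclose(resample_scalar(vol, grid8).values, vol.values)

    def test_trilinear_halfway_shift_averages_neighbours(self):
        grid = make_grid((8, 1, 1), voxel_mm=2.0, centred=False)
        shifted = VolumeGrid((8, 1, 1), np.array(grid.affine) + np.diag([0.0] * 4)
                             + np.pad(np.zeros((3, 3)), ((0, 1), (0, 1))))
        affine = np.array(grid.affine)
        affine[0, 3] += 1.0  # half a voxel
        shifted = VolumeGrid((8, 1, 1), affine)
        vals = np.arange(8.0).reshape(8, 1, 1)
        out = resample_scalar(ScalarVolume(grid, vals), shifted).values.ravel()
        assert np.allclose(out[:-1], np.arange(7) + 0.5)
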