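"""Extraction, rotation and constrained correlation primitives."""

import numpy as np
import pytest
from scipy import ndimage

from conftest import central_sphere_mask, masked_corr

from arraysta.alignment import (
    AlignmentResult,
    RefinementConfig,
    Subvolume,
    UndefinedCorrelationError,
    cone_angular_search,
    constrained_ncc,
    cosine_edge_mask,
    extract_subvolume,
    rotate_volume,
    stage_masks,
    wedge_weight,
)
from arraysta.geometry import angular_distance, euler_to_matrix, matrix_to_euler
from arraysta.simulator import apply_missing_wedge, make_tilt_scheme
from arraysta.volume import TomogramVolume


@pytest.fixture(scope="module")
def motif_grid(motif):
    return motif.grid.astype(np.float32)


def as_sub(grid, wedge=None):
    return Subvolume(grid=grid, voxel_size=4.5, source_position=(0, 0, 0),
                     wedge=wedge)


class TestExtractSubvolume:
    @pytest.fixture(scope="class")
    def tomo(self):
        rng = np.random.default_rng(0)
        return TomogramVolume(grid=rng.normal(size=(40, 60, 80)).astype(np.float32),
                              voxel_size=4.48, origin=np.zeros(3))

    def test_box_573_gives_128_cube(self, tomo):
        sub = extract_subvolume(tomo, (170.0, 130.0, 90.0), 573.0)
        assert sub.grid.shape == (128, 128, 128)  # round(573 / 4.48)

    def test_delta_maps_to_centre(self):
        grid = np.zeros((32, 32, 32), dtype=np.float32)
        grid[10, 12, 14] = 1.0
        tomo = TomogramVolume(grid=grid, voxel_size=2.0)
        sub = extract_subvolume(tomo, (28.0, 24.0, 20.0), 32.0)  # 16-voxel cube
        n = sub.grid.shape[0]
        assert sub.grid[n // 2, n // 2, n // 2] == 1.0

    def test_out_of_bounds_position_raises(self, tomo):
        with pytest.raises(ValueError, match="outside"):
            extract_subvolume(tomo, (10000.0, 0.0, 0.0), 100.0)

    def test_padding_fraction_reported(self, tomo):
        sub = extract_subvolume(tomo, (4.48, 4.48, 4.48), 224.0)
        assert sub.padding_fraction > 0.5
        centred = extract_subvolume(tomo, (170.0, 130.0, 90.0), 90.0)
        assert centred.padding_fraction == 0.0

    def test_source_position_snapped(self, tomo):
        sub = extract_subvolume(tomo, (101.0, 99.0, 50.0), 90.0)
        frac = sub.source_position / 4.48
        assert np.allclose(frac, np.round(frac), atol=1e-5)
        assert np.linalg.norm(sub.source_position - (101.0, 99.0, 50.0)) < 4.48


class TestRotateVolume:
    def test_identity_bit_exact(self, motif_grid):
        assert np.array_equal(rotate_volume(motif_grid, [0, 0, 0]), motif_grid)

    def test_round_trip_correlation(self, motif_grid):
        eul = [30.0, 40.0, 50.0]
        inv = matrix_to_euler(euler_to_matrix(eul).T)
        back = rotate_volume(rotate_volume(motif_grid, eul), inv)
        mask = central_sphere_mask(motif_grid.shape[0])
        assert masked_corr(back, motif_grid, mask) > 0.99

    def test_c2_symmetry_of_motif(self, motif_grid):
        rotated = rotate_volume(motif_grid, [0, 0, 180.0])
        mask = central_sphere_mask(motif_grid.shape[0])
        assert masked_corr(rotated, motif_grid, mask) > 0.99

    def test_rotation_moves_mass_correctly(self):
        vol = np.zeros((33, 33, 33))
        vol[16, 16, 24] = 1.0  # +x offset
        out = rotate_volume(vol, [0.0, 90.0, 0.0])  # +z -> +x, so +x -> -z
        peak = np.unravel_index(np.argmax(out), out.shape)
        assert peak == (8, 16, 16)


class TestWedgeWeight:
    def test_full_sampling_all_ones(self):
        assert np.all(wedge_weight((16, 16, 16), None) == 1.0)

    def test_rotation_consistency(self, tilt60):
        """W(R k) equals rotating a wedge-filtered delta's support."""
        w0 = wedge_weight((32, 32, 32), tilt60)
        w_id = wedge_weight((32, 32, 32), tilt60, rotation=np.eye(3))
        assert np.array_equal(w0, w_id)

    def test_rotated_weight_fraction_preserved(self, tilt60):
        rot = euler_to_matrix([25.0, 40.0, 10.0])
        w = wedge_weight((32, 32, 32), tilt60, rotation=rot)
        w0 = wedge_weight((32, 32, 32), tilt60)
        # box corners make the rotated-cone fraction drift a little
        assert abs(w.mean() - w0.mean()) < 0.12


class TestConstrainedNcc:
    def test_self_score_one_zero_shift(self, motif_grid):
        res = constrained_ncc(motif_grid, as_sub(motif_grid))
        assert res.score == pytest.approx(1.0, abs=1e-6)
        assert np.allclose(res.shift, 0.0, atol=1e-6)

    def test_integer_shift_recovered_exactly(self, motif_grid):
        shifted = np.roll(motif_grid, (2, -3, 1), axis=(0, 1, 2))
        res = constrained_ncc(motif_grid, as_sub(shifted), shift_limit=60.0,
                              subvoxel=False)
        assert np.allclose(res.shift, np.array([1, -3, 2]) * 4.5, atol=1e-9)

    def test_bruteforce_shift_oracle_32cube(self, motif_grid):
        """Fast correlation argmax equals exhaustive real-space search."""
        small = motif_grid[::2, ::2, ::2][:16, :16, :16].copy()
        shifted = np.roll(small, (1, 2, -1), axis=(0, 1, 2))
        res = constrained_ncc(small, Subvolume(grid=shifted, voxel_size=9.0,
                                               source_position=(0, 0, 0)),
                              shift_limit=30.0, subvoxel=False)
        # oracle: score every shift in +-3 voxels by direct dot product
        best, best_shift = -np.inf, None
        a = small - small.mean()
        for dz in range(-3, 4):
            for dy in range(-3, 4):
                for dx in range(-3, 4):
                    cand = np.roll(shifted, (-dz, -dy, -dx), axis=(0, 1, 2))
                    c = masked_corr(a, cand)
                    if c > best:
                        best, best_shift = c, (dx, dy, dz)
        assert np.allclose(res.shift / 9.0, best_shift)

    def test_fractional_shift_recovered(self, motif_grid):
        shifted = ndimage.shift(motif_grid, (0.6, -1.4, 2.3), order=3)
        res = constrained_ncc(motif_grid, as_sub(shifted))
        assert np.allclose(res.shift / 4.5, [2.3, -1.4, 0.6], atol=0.12)

    def test_wedge_compensation_raises_score(self, motif_grid, tilt60):
        vol = TomogramVolume(grid=motif_grid, voxel_size=4.5)
        degraded = apply_missing_wedge(vol, tilt60)
        sub = as_sub(degraded.grid, wedge=tilt60)
        on = constrained_ncc(motif_grid, sub, wedge_compensate=True)
        off = constrained_ncc(motif_grid, sub, wedge_compensate=False)
        assert on.score > 0.99
        assert off.score < on.score

    def test_all_zero_under_mask_raises(self, motif_grid):
        with pytest.raises(UndefinedCorrelationError):
            constrained_ncc(motif_grid, as_sub(np.zeros_like(motif_grid)))

    def test_score_bounded(self, motif_grid, rng):
        noise = rng.normal(size=motif_grid.shape).astype(np.float32)
        res = constrained_ncc(motif_grid, as_sub(noise))
        assert -1.0 <= res.score <= 1.0

    def test_mask_out_of_range_rejected(self, motif_grid):
        bad = np.full(motif_grid.shape, 1.5)
        with pytest.raises(ValueError, match="mask"):
            constrained_ncc(motif_grid, as_sub(motif_grid), mask=bad)


class TestConeAngularSearch:
    def test_recovers_known_rotation(self, motif_grid):
        true = [10.0, 15.0, 8.0]
        sub = as_sub(rotate_volume(motif_grid, true))
        res = cone_angular_search(motif_grid, sub, prior=[0, 0, 0],
                                  cone_half_angle=25.0, angular_step=5.0,
                                  shift_limit=20.0, inplane_range=20.0)
        # grid spacing is ~step in both the axis cap and the spin sweep, so
        # the worst-case distance to a grid point is ~step/sqrt(2) per factor
        assert angular_distance(res.rotation, true) <= 0.8 * 5.0

    def test_score_at_least_prior(self, motif_grid):
        sub = as_sub(rotate_volume(motif_grid, [5.0, 5.0, 0.0]))
        prior = np.zeros(3)
        res = cone_angular_search(motif_grid, sub, prior, 10.0, 5.0,
                                  shift_limit=10.0, inplane_range=10.0)
        base = constrained_ncc(rotate_volume(motif_grid, prior), sub,
                               shift_limit=10.0)
        assert res.score >= base.score - 1e-9

    def test_degenerate_cone_spins_only(self, motif_grid):
        sub = as_sub(motif_grid)
        res = cone_angular_search(motif_grid, sub, prior=[0, 0, 0],
                                  cone_half_angle=0.0, angular_step=10.0,
                                  shift_limit=10.0, inplane_range=30.0)
        # the motif is C2 about z, so the best spin is 0 (or 180)
        assert res.rotation[1] == pytest.approx(0.0, abs=1e-9)

    def test_invalid_cone_rejected(self, motif_grid):
        with pytest.raises(ValueError):
            cone_angular_search(motif_grid, as_sub(motif_grid), [0, 0, 0],
                                cone_half_angle=200.0, angular_step=5.0)

    def test_bruteforce_so3_oracle_16cube(self, motif_grid):
        """Search equals the oracle argmax over the same candidate grid."""
        from arraysta.geometry import rotation_grid_in_cone
        small = motif_grid[::2, ::2, ::2][:16, :16, :16].copy()
        true = [0.0, 10.0, 0.0]
        sub = Subvolume(grid=rotate_volume(small, true), voxel_size=9.0,
                        source_position=(0, 0, 0))
        prior = np.zeros(3)
        res = cone_angular_search(small, sub, prior, cone_half_angle=20.0,
                                  angular_step=10.0, shift_limit=18.0,
                                  inplane_range=10.0)
        best = (-np.inf, None)
        for cand in rotation_grid_in_cone(prior, 20.0, 10.0, inplane_range=10.0):
            r = constrained_ncc(rotate_volume(small, cand), sub, shift_limit=18.0,
                                subvoxel=False)
            if r.score > best[0] + 1e-12:
                best = (r.score, cand)
        assert angular_distance(res.rotation, best[1]) < 1e-9


class TestMasks:
    def test_stage_masks_shapes_and_range(self):
        config = RefinementConfig(box_A=288.0)
        m1, m2 = stage_masks((64, 64, 64), 4.5, config)
        for m in (m1, m2):
            assert m.shape == (64, 64, 64)
            assert m.min() >= 0.0 and m.max() <= 1.0
        assert m1.sum() > m2.sum()  # stage 2 mask is tighter, membrane-free

    def test_cosine_mask_soft_edge(self):
        m = cosine_edge_mask((32, 32, 32), 4.5, 40.0)
        assert 0.0 < m[16, 16, 24] <= 1.0
        assert ((m > 0.05) & (m < 0.95)).sum() > 0
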