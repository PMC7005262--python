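"""Averaging, half-sets, FSC, local resolution/filtering, C2 symmetry."""

import numpy as np
import pytest

from conftest import central_sphere_mask, masked_corr

from arraysta.alignment import AlignmentResult, Subvolume, rotate_volume, \
    UndefinedCorrelationError, lowpass
from arraysta.geometry import euler_from_axis, fibonacci_cap
from arraysta.particles import ParticleSet
from arraysta.simulator import apply_missing_wedge, make_tilt_scheme
from arraysta.validation import (
    FSCCurve,
    HalfMapPair,
    average_subvolumes,
    compute_fsc,
    local_filter,
    local_resolution,
    LocalResolutionMap,
    resolution_at_threshold,
    split_half_sets,
    symmetrize_c2,
)
from arraysta.volume import TomogramVolume


def as_sub(grid, wedge=None):
    return Subvolume(grid=grid, voxel_size=4.5, source_position=(0, 0, 0),
                     wedge=wedge)


def identity_result(euler=(0, 0, 0)):
    return AlignmentResult(shift=(0, 0, 0), rotation=euler, score=1.0)


class TestAverageSubvolumes:
    def test_single_identity_no_wedge(self, motif):
        mg = motif.grid.astype(np.float32)
        avg = average_subvolumes([as_sub(mg)], [identity_result()])
        assert np.abs(avg.grid - mg).max() < 1e-5

    def test_duplication_invariance(self, motif, tilt60):
        mg = motif.grid.astype(np.float32)
        vol = apply_missing_wedge(TomogramVolume(grid=mg, voxel_size=4.5), tilt60)
        subs = [as_sub(vol.grid, wedge=tilt60)] * 2
        ress = [identity_result()] * 2
        once = average_subvolumes(subs[:1], ress[:1])
        twice = average_subvolumes(subs, ress)
        assert np.allclose(once.grid, twice.grid, atol=1e-5)

    def test_orientation_diversity_fills_wedge(self, motif, tilt60, rng):
        """20+ wedge-degraded views spanning orientations average back to
        the motif (wedge filled by diversity)."""
        mg = motif.grid.astype(np.float32)
        subs, ress = [], []
        for direction in fibonacci_cap(90.0, 25.0):
            eul = euler_from_axis(direction, rng.uniform(0, 360))
            rot = rotate_volume(mg, eul)
            degraded = apply_missing_wedge(
                TomogramVolume(grid=rot, voxel_size=4.5), tilt60)
            subs.append(as_sub(degraded.grid, wedge=tilt60))
            ress.append(identity_result(eul))
        assert len(subs) >= 20
        avg = average_subvolumes(subs, ress)
        mask = central_sphere_mask(mg.shape[0])
        assert masked_corr(avg.grid, mg, mask) > 0.99

    def test_mismatched_lengths_rejected(self, motif):
        with pytest.raises(ValueError):
            average_subvolumes([as_sub(motif.grid)], [])


class TestSplitHalfSets:
    def _particles(self, counts):
        tomo_ids = np.concatenate([np.full(c, t) for t, c in enumerate(counts)])
        n = len(tomo_ids)
        return ParticleSet(positions=np.random.default_rng(0).normal(size=(n, 3)),
                           eulers=np.zeros((n, 3)), tomo_ids=tomo_ids)

    def test_six_equal_tomograms_balanced(self):
        ps = self._particles([10] * 6)
        a, b = split_half_sets(ps)
        assert len(a) == len(b) == 30
        assert len(set(a.tomo_ids)) == len(set(b.tomo_ids)) == 3

    def test_unbalanced_counts_best_split(self):
        # {100, 1, 1, 1, 1, 1}: oracle over all 2^6 partitions gives {100} vs rest
        ps = self._particles([100, 1, 1, 1, 1, 1])
        a, b = split_half_sets(ps)
        big, small = (a, b) if len(a) > len(b) else (b, a)
        assert len(big) == 100 and len(small) == 5
        # exhaustive oracle: best achievable imbalance
        counts = np.array([100, 1, 1, 1, 1, 1])
        best = min(abs(counts[list(sel)].sum() - counts.sum() / 2)
                   for m in range(1, 64)
                   for sel in [[i for i in range(6) if m >> i & 1]])
        assert abs(len(big) - 105 / 2) == pytest.approx(best)

    def test_disjoint_union(self):
        ps = self._particles([7, 3, 9, 2])
        a, b = split_half_sets(ps)
        assert set(a.ids).isdisjoint(set(b.ids))
        assert set(a.ids) | set(b.ids) == set(ps.ids)
        assert set(a.tomo_ids).isdisjoint(set(b.tomo_ids))

    def test_single_tomogram_rejected(self):
        with pytest.raises(ValueError, match="tomogram"):
            split_half_sets(self._particles([10]))


class TestComputeFsc:
    def test_self_fsc_unity(self, rng):
        v = TomogramVolume(grid=rng.normal(size=(48, 48, 48)), voxel_size=4.5)
        curve = compute_fsc(HalfMapPair(map_a=v, map_b=v))
        assert np.abs(curve.correlation - 1.0).max() < 1e-9

    def test_negated_map_minus_one(self, rng):
        g = rng.normal(size=(32, 32, 32))
        pair = HalfMapPair(map_a=TomogramVolume(grid=g, voxel_size=4.5),
                           map_b=TomogramVolume(grid=-g, voxel_size=4.5))
        curve = compute_fsc(pair)
        assert np.abs(curve.correlation + 1.0).max() < 1e-9

    def test_independent_noise_within_null_bound(self, rng):
        a = TomogramVolume(grid=rng.normal(size=(64, 64, 64)), voxel_size=4.5)
        b = TomogramVolume(grid=rng.normal(size=(64, 64, 64)), voxel_size=4.5)
        curve = compute_fsc(HalfMapPair(map_a=a, map_b=b))
        bound = 3.0 / np.sqrt(np.maximum(curve.shell_counts, 1))
        ok = np.abs(curve.correlation[1:]) < bound[1:]
        assert ok.mean() >= 0.95

    def test_smooth_mask_keeps_first_shells(self, motif):
        from arraysta.alignment import cosine_edge_mask
        mg = motif.grid.astype(np.float32)
        v = TomogramVolume(grid=mg, voxel_size=4.5)
        mask = cosine_edge_mask(mg.shape, 4.5, 80.0)
        curve = compute_fsc(HalfMapPair(map_a=v, map_b=v, mask=mask))
        assert curve.correlation[1] > 0.99

    def test_all_zero_masked_raises(self):
        z = TomogramVolume(grid=np.zeros((16, 16, 16)), voxel_size=4.5)
        with pytest.raises(UndefinedCorrelationError):
            compute_fsc(HalfMapPair(map_a=z, map_b=z))

    def test_shell_freq_ascending_one_voxel_wide(self, rng):
        v = TomogramVolume(grid=rng.normal(size=(40, 40, 40)), voxel_size=2.0)
        curve = compute_fsc(HalfMapPair(map_a=v, map_b=v))
        df = np.diff(curve.shell_freq)
        assert np.allclose(df, 1.0 / (40 * 2.0))


class TestResolutionAtThreshold:
    def _curve(self, freq, corr):
        return FSCCurve(shell_freq=freq, correlation=corr,
                        shell_counts=np.ones(len(freq), int))

    def test_step_curve_at_20A(self):
        freq = np.linspace(0.0, 0.1, 51)
        corr = np.where(freq <= 0.05, 1.0, 0.0)
        res, never = resolution_at_threshold(self._curve(freq, corr), 0.5, 4.5)
        assert not never
        assert res == pytest.approx(20.0, abs=1.0)  # within one shell width

    def test_exact_crossing_at_shell(self):
        freq = np.array([0.0, 0.025, 0.05, 0.075])
        corr = np.array([1.0, 0.8, 0.5, 0.1])
        res, never = resolution_at_threshold(self._curve(freq, corr), 0.5, 4.5)
        # correlation hits exactly 0.5 at 1/20 and drops below at the next shell
        assert res == pytest.approx(20.0, abs=1e-9)

    def test_lower_threshold_crosses_later(self):
        freq = np.linspace(0.0, 0.1, 40)
        corr = np.clip(1.0 - 12.0 * freq, 0.0, 1.0)
        curve = self._curve(freq, corr)
        r143, _ = resolution_at_threshold(curve, 0.143, 4.5)
        r50, _ = resolution_at_threshold(curve, 0.5, 4.5)
        assert r143 <= r50

    def test_never_crossing_returns_nyquist_flag(self):
        freq = np.linspace(0.0, 0.1, 20)
        res, never = resolution_at_threshold(
            self._curve(freq, np.full(20, 0.9)), 0.5, 4.5)
        assert never
        assert res == pytest.approx(9.0)

    def test_bad_threshold(self):
        freq = np.linspace(0, 0.1, 5)
        with pytest.raises(ValueError):
            resolution_at_threshold(self._curve(freq, np.ones(5)), 1.5, 4.5)


class TestLocalResolution:
    def test_sampling_stride_arithmetic(self):
        # 20 A sampling on 4.48 A voxels: evaluation stride 4-5 voxels
        assert round(20.0 / 4.48) in (4, 5)

    def test_noise_free_motif_near_nyquist(self, motif):
        mg = motif.grid.astype(np.float32)
        pair = HalfMapPair(map_a=TomogramVolume(grid=mg, voxel_size=4.5),
                           map_b=TomogramVolume(grid=mg, voxel_size=4.5))
        resmap = local_resolution(pair, window=90.0, sampling=36.0)
        inside = central_sphere_mask(mg.shape[0], 0.25)
        assert np.median(resmap.grid[inside]) <= 2.5 * 4.5

    def test_clean_region_beats_noisy_region(self, motif, rng):
        mg = motif.grid.astype(np.float32)
        n = mg.shape[0]
        a = np.concatenate([mg, mg], axis=2)
        b = a.copy()
        noise_scale = 3.0 * mg.std()
        b[:, :, n:] += rng.normal(0, noise_scale, size=mg.shape)
        a2 = a.copy()
        a2[:, :, n:] += rng.normal(0, noise_scale, size=mg.shape)
        # pad to cube
        pad = ((0, n), (0, n), (0, 0))
        a2 = np.pad(a2, pad)
        b = np.pad(b, pad)
        pair = HalfMapPair(map_a=TomogramVolume(grid=a2, voxel_size=4.5),
                           map_b=TomogramVolume(grid=b, voxel_size=4.5))
        resmap = local_resolution(pair, window=90.0, sampling=45.0)
        clean = resmap.grid[n // 2, n // 2, :n]
        noisy = resmap.grid[n // 2, n // 2, n:2 * n]
        assert np.median(clean) < np.median(noisy)

    def test_window_larger_than_map_rejected(self, motif):
        mg = motif.grid.astype(np.float32)
        pair = HalfMapPair(map_a=TomogramVolume(grid=mg, voxel_size=4.5),
                           map_b=TomogramVolume(grid=mg, voxel_size=4.5))
        with pytest.raises(ValueError):
            local_resolution(pair, window=10000.0)

    def test_values_at_least_nyquist(self, motif, rng):
        mg = motif.grid.astype(np.float32) + rng.normal(0, 0.1, motif.grid.shape)
        pair = HalfMapPair(map_a=TomogramVolume(grid=mg, voxel_size=4.5),
                           map_b=TomogramVolume(grid=mg, voxel_size=4.5))
        resmap = local_resolution(pair, window=90.0, sampling=60.0)
        assert resmap.grid.min() >= 2 * 4.5 - 1e-9


class TestLocalFilter:
    def test_constant_resmap_equals_global_lowpass(self, motif):
        mg = motif.grid.astype(np.float32)
        vol = TomogramVolume(grid=mg, voxel_size=4.5)
        resmap = LocalResolutionMap(grid=np.full(mg.shape, 30.0), sampling=20.0,
                                    window=90.0, voxel_size=4.5)
        out = local_filter(vol, resmap)
        ref = lowpass(mg.astype(float), 4.5, 30.0)
        assert masked_corr(out.grid, ref) > 0.999

    def test_nyquist_resmap_identity(self, motif):
        mg = motif.grid.astype(np.float32)
        vol = TomogramVolume(grid=mg, voxel_size=4.5)
        resmap = LocalResolutionMap(grid=np.full(mg.shape, 9.0), sampling=20.0,
                                    window=90.0, voxel_size=4.5)
        out = local_filter(vol, resmap)
        assert masked_corr(out.grid, mg) > 0.999

    def test_power_beyond_cutoff_attenuated(self, motif, rng):
        from scipy.fft import fftn, fftfreq
        mg = (motif.grid + rng.normal(0, 0.5, motif.grid.shape)).astype(np.float32)
        vol = TomogramVolume(grid=mg, voxel_size=4.5)
        resmap = LocalResolutionMap(grid=np.full(mg.shape, 40.0), sampling=20.0,
                                    window=90.0, voxel_size=4.5)
        out = local_filter(vol, resmap)
        n = mg.shape[0]
        k = np.sqrt(sum(np.meshgrid(*(fftfreq(n) ** 2,) * 3, indexing="ij"))) / 4.5
        high = k > 1.2 / 40.0
        p_in = (np.abs(fftn(mg.astype(float))) ** 2)[high].sum()
        p_out = (np.abs(fftn(out.grid.astype(float))) ** 2)[high].sum()
        assert p_out < p_in / 100.0


class TestSymmetrizeC2:
    def test_symmetric_input_unchanged(self, motif):
        vol = TomogramVolume(grid=motif.grid.astype(np.float32), voxel_size=4.5)
        sym, axis, score = symmetrize_c2(vol, cone_deg=4.0, step_deg=2.0)
        mask = central_sphere_mask(vol.grid.shape[0])
        assert masked_corr(sym.grid, vol.grid, mask) > 0.999
        assert score > 0.999

    def test_output_invariant_under_c2(self, motif, rng):
        grid = (motif.grid + 0.02 * rng.normal(size=motif.grid.shape)).astype(np.float32)
        vol = TomogramVolume(grid=grid, voxel_size=4.5)
        sym, axis, _ = symmetrize_c2(vol, cone_deg=4.0, step_deg=2.0)
        rotated = rotate_volume(sym.grid.astype(float), _c2_euler(axis))
        mask = central_sphere_mask(vol.grid.shape[0])
        assert masked_corr(rotated, sym.grid, mask) > 0.999

    def test_tilted_axis_recovered_within_1deg(self, motif):
        tilt = np.radians(5.0)
        true_axis = np.array([np.sin(tilt), 0.0, np.cos(tilt)])
        tilted = rotate_volume(motif.grid.astype(np.float32),
                               euler_from_axis(true_axis))
        vol = TomogramVolume(grid=tilted, voxel_size=4.5)
        _, axis, score = symmetrize_c2(vol, cone_deg=10.0, step_deg=1.0)
        err = np.degrees(np.arccos(np.clip(abs(axis @ true_axis), -1, 1)))
        assert err < 1.0

    def test_featureless_map_aborts(self, rng):
        vol = TomogramVolume(grid=rng.normal(size=(32, 32, 32)).astype(np.float32),
                             voxel_size=4.5)
        with pytest.raises(RuntimeError, match="C2"):
            symmetrize_c2(vol, cone_deg=2.0, step_deg=2.0, min_score=0.95)


def _c2_euler(axis):
    """Euler triplet of the 180-degree rotation about an axis."""
    from scipy.spatial.transform import Rotation
    r_axis = Rotation.from_euler("ZYZ", euler_from_axis(axis), degrees=True)
    c2 = r_axis * Rotation.from_euler("z", 180.0, degrees=True) * r_axis.inv()
    import warnings as _w
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        return c2.as_euler("ZYZ", degrees=True)
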