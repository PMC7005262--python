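"""Wedge-weighted averaging, half-map FSC, local resolution and C2 symmetry.

Half-maps are built from disjoint tomogram groups (gold-standard style);
resolutions are quoted at the 0.5 and 0.143 FSC threshold crossings with
linear interpolation between one-voxel-wide shells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.fft import fftn, ifftn, fftfreq
from scipy.interpolate import RegularGridInterpolator

from .alignment import (
    Subvolume,
    AlignmentResult,
    extract_subvolume,
    rotate_volume,
    wedge_weight,
    UndefinedCorrelationError,
)
from .geometry import euler_to_matrix, matrix_to_euler, euler_from_axis, fibonacci_cap
from .particles import ParticleSet
from .volume import TomogramVolume

WEIGHT_EPSILON = 1e-3


@dataclass
class HalfMapPair:
    map_a: TomogramVolume
    map_b: TomogramVolume
    split_rule: str = ""
    mask: np.ndarray | None = None

    def __post_init__(self):
        if self.map_a.grid.shape != self.map_b.grid.shape:
            raise ValueError("half-maps must share a grid")
        if abs(self.map_a.voxel_size - self.map_b.voxel_size) > 1e-9:
            raise ValueError("half-maps must share a voxel size")


@dataclass
class FSCCurve:
    shell_freq: np.ndarray       # 1/Angstrom, ascending
    correlation: np.ndarray
    shell_counts: np.ndarray

    def __post_init__(self):
        self.shell_freq = np.asarray(self.shell_freq, float)
        self.correlation = np.asarray(self.correlation, float)
        self.shell_counts = np.asarray(self.shell_counts, int)
        if not (len(self.shell_freq) == len(self.correlation) == len(self.shell_counts)):
            raise ValueError("FSC curve field lengths disagree")


@dataclass
class LocalResolutionMap:
    grid: np.ndarray             # Angstrom per voxel
    sampling: float              # Angstrom between evaluation points
    window: float                # Angstrom window diameter
    voxel_size: float


# ---------------------------------------------------------------------------
# averaging

def transform_to_reference(sub: Subvolume, result: AlignmentResult):
    """Inverse-transform one subvolume into the reference frame.

    With ``sub(x) = ref(R^-1 (x - t))``, the estimate of ref is
    ``sub(R y + t)``; returns (real-space estimate, Fourier wedge weight in
    the reference frame).
    """
    rot = euler_to_matrix(result.rotation)
    shift_vox = result.shift / sub.voxel_size       # (x, y, z) voxels
    identity = np.allclose(result.rotation, 0.0) and np.allclose(shift_vox, 0.0)
    grid32 = np.asarray(sub.grid, np.float32)
    if identity:
        est = grid32.copy()
    else:
        from scipy import ndimage
        n = sub.grid.shape[0]
        c = n // 2
        m = rot[::-1, ::-1]  # acts on (z, y, x) index vectors
        centre = np.full(3, c, float)
        offset = centre + shift_vox[::-1] - m @ centre
        est = ndimage.affine_transform(grid32, m, offset=offset,
                                       order=1, mode="constant", cval=0.0)
    weight = wedge_weight(sub.grid.shape, sub.wedge, rotation=rot)
    return est, weight


def average_subvolumes(subvols: list, results: list, voxel_size: float | None = None
                       ) -> TomogramVolume:
    """Fourier-space wedge-weighted average of aligned subvolumes.

    Coefficients of each inverse-transformed subvolume are accumulated along
    with its (rotated) wedge weight; the sum is divided by the accumulated
    weight with an epsilon floor. Duplicating every particle leaves the
    average unchanged.
    """
    if len(subvols) == 0:
        raise ValueError("no subvolumes to average")
    if len(subvols) != len(results):
        raise ValueError("need exactly one alignment result per subvolume")
    shape = subvols[0].grid.shape
    voxel = voxel_size if voxel_size is not None else subvols[0].voxel_size
    num = np.zeros(shape, dtype=np.complex64)
    den = np.zeros(shape, dtype=np.float32)
    for sub, res in zip(subvols, results):
        if sub.grid.shape != shape:
            raise ValueError("subvolume grids must match")
        est, w = transform_to_reference(sub, res)
        num += fftn(est) * w
        den += w
    if np.any(den.ravel()[1:] <= 0):
        warnings.warn("some Fourier shells received zero total weight; "
                      "epsilon-regularised")
    avg = ifftn(num / np.maximum(den, WEIGHT_EPSILON)).real
    return TomogramVolume(grid=avg.astype(np.float32), voxel_size=voxel, wedge=None)


def average_from_particles(tomograms, particles: ParticleSet, box_A: float
                           ) -> TomogramVolume:
    """Extract every particle from its tomogram and average."""
    tomo_by_id = {t.tomo_id: t for t in tomograms}
    subs, results = [], []
    for i in range(len(particles)):
        sub = extract_subvolume(tomo_by_id[particles.tomo_ids[i]],
                                particles.positions[i], box_A)
        # residual sub-voxel offset between requested position and snapped centre
        resid = particles.positions[i] - sub.source_position
        subs.append(sub)
        results.append(AlignmentResult(shift=resid, rotation=particles.eulers[i],
                                       score=particles.scores[i]))
    return average_subvolumes(subs, results)


# ---------------------------------------------------------------------------
# half sets and FSC

def split_half_sets(particles: ParticleSet):
    """Partition tomograms into two groups with balanced particle counts.

    Greedy: tomograms in decreasing particle count are assigned to the
    lighter half. Requires >= 2 distinct tomogram ids; the two particle sets
    are disjoint and their union is the input.
    """
    ids, counts = np.unique(particles.tomo_ids, return_counts=True)
    if len(ids) < 2:
        raise ValueError("cannot split half-sets: need >= 2 distinct tomograms")
    order = np.argsort(-counts, kind="stable")
    group_a, group_b = set(), set()
    tot_a = tot_b = 0
    for k in order:
        if tot_a <= tot_b:
            group_a.add(int(ids[k]))
            tot_a += int(counts[k])
        else:
            group_b.add(int(ids[k]))
            tot_b += int(counts[k])
    in_a = np.isin(particles.tomo_ids, sorted(group_a))
    return particles.subset(np.nonzero(in_a)[0]), particles.subset(np.nonzero(~in_a)[0])


def compute_fsc(pair: HalfMapPair) -> FSCCurve:
    """Fourier shell correlation between the two (masked) half-maps.

    Shells are one Fourier voxel wide; the correlation is the normalised
    real part of the complex cross-shell inner product.
    """
    a = pair.map_a.grid.astype(float)
    b = pair.map_b.grid.astype(float)
    if pair.mask is not None:
        a = a * pair.mask
        b = b * pair.mask
    if not (np.any(a) and np.any(b)):
        raise UndefinedCorrelationError("all-zero masked map")
    fa, fb = fftn(a), fftn(b)
    shape = a.shape
    kz = fftfreq(shape[0]).reshape(-1, 1, 1)
    ky = fftfreq(shape[1]).reshape(1, -1, 1)
    kx = fftfreq(shape[2]).reshape(1, 1, -1)
    # radius in units of the fundamental frequency of the (cubic) box
    r = np.sqrt(kz**2 + ky**2 + kx**2) * shape[0]
    shell = np.round(r).astype(int)
    n_shells = shape[0] // 2 + 1
    sel = shell < n_shells
    labels = shell[sel]
    cross = np.bincount(labels, weights=(fa * np.conj(fb)).real[sel], minlength=n_shells)
    pa = np.bincount(labels, weights=(np.abs(fa) ** 2)[sel], minlength=n_shells)
    pb = np.bincount(labels, weights=(np.abs(fb) ** 2)[sel], minlength=n_shells)
    counts = np.bincount(labels, minlength=n_shells)
    denom = np.sqrt(pa * pb)
    corr = np.divide(cross, denom, out=np.zeros(n_shells), where=denom > 0)
    freq = np.arange(n_shells) / (shape[0] * pair.map_a.voxel_size)
    return FSCCurve(shell_freq=freq, correlation=corr, shell_counts=counts)


def resolution_at_threshold(curve: FSCCurve, threshold: float, voxel_size: float):
    """Resolution (Angstrom) at the first crossing below ``threshold``.

    Linear interpolation in correlation vs frequency between the bracketing
    shells. If the curve never crosses, returns Nyquist (2 * voxel) with the
    ``never_crossed`` flag set. Returns (resolution_A, never_crossed).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    freq, corr = curve.shell_freq, curve.correlation
    for i in range(1, len(corr)):
        if corr[i] < threshold:
            f0, f1 = freq[i - 1], freq[i]
            c0, c1 = corr[i - 1], corr[i]
            if c0 <= threshold:       # already below at the previous shell
                f_cross = f0 if f0 > 0 else f1
            else:
                f_cross = f0 + (c0 - threshold) / (c0 - c1) * (f1 - f0)
            if f_cross <= 0:
                continue
            return float(1.0 / f_cross), False
    return 2.0 * voxel_size, True


# ---------------------------------------------------------------------------
# local resolution

def _soft_sphere(n: int, radius_vox: float, edge_vox: float = 2.0) -> np.ndarray:
    c = n // 2
    idx = np.arange(n) - c
    z, y, x = np.meshgrid(idx, idx, idx, indexing="ij")
    r = np.sqrt(x**2 + y**2 + z**2)
    m = np.clip((radius_vox - r) / edge_vox, 0.0, 1.0)
    return 0.5 - 0.5 * np.cos(np.pi * m)


def local_resolution(pair: HalfMapPair, window: float = 112.0, sampling: float = 20.0,
                     threshold: float = 0.143) -> LocalResolutionMap:
    """Windowed-FSC local resolution on a coarse grid, interpolated to the
    full grid. ``window`` is the soft spherical window diameter (Angstrom);
    evaluation points are ``sampling`` Angstrom apart."""
    voxel = pair.map_a.voxel_size
    n = pair.map_a.grid.shape[0]
    w_vox = int(round(window / voxel))
    if w_vox < 4:
        raise ValueError("window must span at least 4 voxels")
    if w_vox > n:
        raise ValueError("window larger than the map")
    w_vox += w_vox % 2
    stride = max(1, int(round(sampling / voxel)))
    sphere = _soft_sphere(w_vox, radius_vox=0.5 * w_vox - 1.0)
    half = w_vox // 2

    centres = np.arange(half, n - half + 1, stride)
    if len(centres) == 0:
        centres = np.array([n // 2])
    res_grid = np.zeros((len(centres),) * 3)
    a, b = pair.map_a.grid.astype(float), pair.map_b.grid.astype(float)
    for iz, cz in enumerate(centres):
        for iy, cy in enumerate(centres):
            for ix, cx in enumerate(centres):
                sl = (slice(cz - half, cz - half + w_vox),
                      slice(cy - half, cy - half + w_vox),
                      slice(cx - half, cx - half + w_vox))
                wa, wb = a[sl] * sphere, b[sl] * sphere
                if not (np.any(wa) and np.any(wb)):
                    res_grid[iz, iy, ix] = window
                    continue
                sub_pair = HalfMapPair(
                    map_a=TomogramVolume(grid=wa, voxel_size=voxel),
                    map_b=TomogramVolume(grid=wb, voxel_size=voxel))
                curve = compute_fsc(sub_pair)
                res, never = resolution_at_threshold(curve, threshold, voxel)
                res_grid[iz, iy, ix] = min(res, window) if not never else 2.0 * voxel

    coords = centres.astype(float)
    interp = RegularGridInterpolator((coords, coords, coords), res_grid,
                                     bounds_error=False, fill_value=None)
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float),) * 3, indexing="ij")
    pts = np.column_stack([np.clip(c.ravel(), coords[0], coords[-1])
                           for c in (zz, yy, xx)])
    full = interp(pts).reshape(n, n, n)
    full = np.maximum(full, 2.0 * voxel)
    return LocalResolutionMap(grid=full, sampling=stride * voxel,
                              window=w_vox * voxel, voxel_size=voxel)


def local_filter(vol: TomogramVolume, resmap: LocalResolutionMap,
                 n_bands: int = 12) -> TomogramVolume:
    """Filter each voxel to its local resolution by blending band maps.

    The map is globally low-passed at a set of cutoffs spanning the resmap's
    range; each voxel linearly interpolates between the two bracketing band
    maps. A constant resmap therefore reduces to a single global low-pass.
    """
    from .alignment import lowpass

    if vol.grid.shape != resmap.grid.shape:
        raise ValueError("map and resolution-map grids must match")
    res = np.clip(resmap.grid, 2.0 * vol.voxel_size, None)
    lo, hi = float(res.min()), float(res.max())
    if hi - lo < 1e-6:
        out = lowpass(vol.grid.astype(float), vol.voxel_size, lo)
        return vol.copy_with(grid=out.astype(np.float32))
    cuts = np.linspace(lo, hi, min(n_bands, max(2, int((hi - lo) / 2.0) + 2)))
    bands = [lowpass(vol.grid.astype(float), vol.voxel_size, c) for c in cuts]
    out = np.zeros_like(bands[0])
    idx = np.clip(np.searchsorted(cuts, res) - 1, 0, len(cuts) - 2)
    frac = (res - cuts[idx]) / (cuts[idx + 1] - cuts[idx])
    for k in range(len(cuts) - 1):
        sel = idx == k
        if np.any(sel):
            out[sel] = (1.0 - frac[sel]) * bands[k][sel] + frac[sel] * bands[k + 1][sel]
    return vol.copy_with(grid=out.astype(np.float32))


# ---------------------------------------------------------------------------
# C2 symmetrisation

def _c2_score(grid: np.ndarray, axis_euler, limit_vox: int):
    """Correlation of the map with its 180-degree rotation about an axis,
    maximised over translations; returns (score, shift_zyx)."""
    from scipy.spatial.transform import Rotation

    r_axis = Rotation.from_euler("ZYZ", axis_euler, degrees=True)
    c2 = (r_axis * Rotation.from_euler("z", 180.0, degrees=True) * r_axis.inv())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # gimbal-lock note is benign here
        eul = c2.as_euler("ZYZ", degrees=True)
    rotated = rotate_volume(grid, eul)
    a = grid - grid.mean()
    b = rotated - rotated.mean()
    fa, fb = fftn(a), fftn(b)
    cc = ifftn(fb * np.conj(fa)).real
    norm = np.sqrt((np.abs(fa) ** 2).sum() * (np.abs(fb) ** 2).sum()) / a.size
    from .alignment import _peak_in_window
    shift, val = _peak_in_window(cc, limit_vox, subvoxel=False)
    return (val / norm if norm > 0 else -1.0), shift, eul


def symmetrize_c2(vol: TomogramVolume, axis_prior=(0.0, 0.0, 1.0),
                  cone_deg: float = 10.0, step_deg: float = 1.0,
                  min_score: float = 0.2) -> tuple:
    """Refine the C2 axis near the prior and average the map with its
    180-degree rotation about it.

    The axis is searched over a ~``step_deg``-spaced cap of half-angle
    ``cone_deg`` about the prior, scoring the translational-max correlation
    between the map and its rotated copy. Returns (symmetrised volume,
    refined axis unit vector, score). Aborts if the best score is below
    ``min_score``.
    """
    grid = vol.grid.astype(float)
    prior = np.asarray(axis_prior, float)
    prior = prior / np.linalg.norm(prior)
    from scipy.spatial.transform import Rotation

    base = Rotation.from_euler("ZYZ", euler_from_axis(prior), degrees=True)
    tilts = fibonacci_cap(cone_deg, step_deg)
    limit_vox = max(2, grid.shape[0] // 8)
    best = (-np.inf, None, None, None)
    for t in tilts:
        axis_vec = base.apply(t)
        axis_euler = euler_from_axis(axis_vec)
        score, shift, eul = _c2_score(grid, axis_euler, limit_vox)
        if score > best[0] + 1e-12:
            best = (score, axis_vec, shift, eul)
    score, axis_vec, shift_zyx, eul = best
    if score < min_score:
        raise RuntimeError(f"C2 alignment failed: best correlation {score:.3f} < {min_score}")
    # recentre so the C2 axis passes through the cube centre: the rotated
    # copy is offset by 'shift'; moving the map by half the offset centres it
    from scipy import ndimage
    half_shift = -0.5 * shift_zyx
    centred = ndimage.shift(grid, half_shift, order=1, mode="constant") \
        if np.any(np.abs(half_shift) > 1e-9) else grid
    rotated = rotate_volume(centred, eul)
    sym = 0.5 * (centred + rotated)
    out = vol.copy_with(grid=sym.astype(np.float32))
    return out, axis_vec, float(score)
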