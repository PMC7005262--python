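"""Subvolume extraction and constrained, wedge-compensated alignment.

Conventions
-----------
* Cube centre = voxel index ``floor(N/2)``, 0-based.
* A shift ``s`` means the subvolume content sits at ``ref`` translated by
  ``+s`` (Angstrom, (x, y, z)); the particle's refined position is the
  extraction centre plus the shift.
* An orientation ``R`` means ``sub(x) = ref(R^-1 (x - s))``: the reference
  rotated by R and translated by s reproduces the particle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.fft import fftn, ifftn, fftfreq

from .geometry import euler_to_matrix, matrix_to_euler, rotation_grid_in_cone
from .particles import ParticleSet
from .volume import TomogramVolume


class UndefinedCorrelationError(ValueError):
    """Correlation of an all-zero (under the mask) volume is undefined."""


class AlignmentDivergenceError(RuntimeError):
    pass


@dataclass
class Subvolume:
    grid: np.ndarray             # cubic, [z, y, x]
    voxel_size: float
    source_position: np.ndarray  # Angstrom (x, y, z): extraction centre in the tomogram
    tomo_id: int = 0
    wedge: object = None         # TiltScheme or None
    padding_fraction: float = 0.0

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        nz, ny, nx = self.grid.shape
        if not (nz == ny == nx):
            raise ValueError(f"subvolume must be cubic, got {self.grid.shape}")
        self.source_position = np.asarray(self.source_position, float).reshape(3)


@dataclass
class AlignmentResult:
    shift: np.ndarray            # Angstrom, (x, y, z)
    rotation: np.ndarray         # Euler ZYZ degrees
    score: float
    iteration: int = 0

    def __post_init__(self):
        self.shift = np.asarray(self.shift, float).reshape(3)
        self.rotation = np.asarray(self.rotation, float).reshape(3)


@dataclass
class RefinementConfig:
    """Two-stage masked refinement parameters.

    Stage 1 aligns inside a wide mask including the membrane slab; stage 2
    refines inside the membrane-free mask with a tighter cone. The cone and
    step defaults are desk-scale choices; ``cone_half_angle`` is the outer
    bound used for the standalone global search.
    """
    box_A: float = 573.0
    shift_limit: float = 60.0
    cone_half_angle: float = 60.0
    duplicate_threshold: float = 10.0
    cone_stage1: float = 20.0
    cone_stage2: float = 8.0
    angular_step_stage1: float = 10.0
    angular_step_stage2: float = 4.0
    inplane_range_stage1: float = 180.0   # full in-plane sweep
    inplane_range_stage2: float = 10.0
    shift_limit_refine: float = 20.0
    max_iterations: int = 8
    score_tolerance: float = 1e-4
    divergence_tolerance: float = 0.02
    lowpass_stage1: float = 40.0          # Angstrom
    lowpass_stage2: float = 25.0
    search_bin: int = 2                   # angular search at this binning
    interp_order: int = 3                 # spline order for refinement rotations
    mask_radius_A: float = 130.0          # stage 1: multi-CSU footprint
    mask_radius_stage2_A: float = 60.0    # stage 2: central unit, bias-free
    mask_stage1_z: tuple = (-110.0, 45.0)   # Angstrom about the membrane plane
    mask_stage2_z: tuple = (-100.0, -14.0)  # no membrane

    def __post_init__(self):
        for name in ("box_A", "shift_limit", "duplicate_threshold", "max_iterations"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# extraction and rotation primitives

def extract_subvolume(tomo: TomogramVolume, position, box_A: float) -> Subvolume:
    """Cube of ``round(box_A / voxel_size)`` voxels centred on ``position``.

    The centre is snapped to the nearest voxel (``source_position`` records
    the snapped centre in Angstrom); out-of-bounds voxels are zero-padded
    and reported via ``padding_fraction``.
    """
    if box_A <= 0:
        raise ValueError("box_A must be > 0")
    position = np.asarray(position, float).reshape(3)
    voxel = tomo.voxel_size
    idx_xyz = np.round((position - tomo.origin) / voxel).astype(int)
    shape_xyz = np.array(tomo.grid.shape[::-1])
    if np.any(idx_xyz < 0) or np.any(idx_xyz >= shape_xyz):
        raise ValueError(f"position {position} lies outside the volume")
    n = int(round(box_A / voxel))
    c = n // 2
    out = np.zeros((n, n, n), dtype=tomo.grid.dtype)
    lo = idx_xyz[::-1] - c                              # (z, y, x)
    hi = lo + n
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, tomo.grid.shape)
    src = tuple(slice(a, b) for a, b in zip(lo_c, hi_c))
    dst = tuple(slice(a - l, a - l + (b - a)) for a, b, l in zip(lo_c, hi_c, lo))
    out[dst] = tomo.grid[src]
    pad = 1.0 - np.prod([b - a for a, b in zip(lo_c, hi_c)]) / float(n**3)
    centre = tomo.origin + idx_xyz * voxel
    return Subvolume(grid=out, voxel_size=voxel, source_position=centre,
                     tomo_id=tomo.tomo_id, wedge=tomo.wedge, padding_fraction=float(pad))


def rotate_volume(vol: np.ndarray, euler, order: int = 1) -> np.ndarray:
    """Rotate about the cube centre (voxel floor(N/2)) with trilinear
    interpolation and zero fill; identity returns a bit-exact copy."""
    euler = np.asarray(euler, float)
    if np.allclose(euler, 0.0):
        return np.array(vol, copy=True)
    rot = euler_to_matrix(euler)
    # index space is (z, y, x): conjugate the inverse rotation by the flip
    m = rot.T[::-1, ::-1]
    c = np.array([s // 2 for s in vol.shape], float)
    offset = c - m @ c
    return ndimage.affine_transform(vol, m, offset=offset, order=order,
                                    mode="constant", cval=0.0, prefilter=(order > 1))


_WEDGE_CACHE: dict = {}


def wedge_weight(shape, scheme, rotation=None) -> np.ndarray:
    """Fourier weight of a subvolume's sampled region in the reference frame.

    ``rotation`` is the particle orientation matrix R (``sub = ref rotated by
    R``); the tomogram-frame wedge W is pulled back as W(R k). None or a
    full-sampling scheme gives all-ones. The unrotated mask is cached per
    (shape, max_angle).
    """
    if scheme is None or scheme.max_angle >= 90.0:
        return np.ones(shape, dtype=np.float32)
    if rotation is None:
        key = (tuple(shape), float(scheme.max_angle))
        cached = _WEDGE_CACHE.get(key)
        if cached is not None:
            return cached
    tan = np.tan(np.radians(scheme.max_angle))
    kz = fftfreq(shape[0]).reshape(-1, 1, 1)
    ky = fftfreq(shape[1]).reshape(1, -1, 1)
    kx = fftfreq(shape[2]).reshape(1, 1, -1)
    if rotation is None:
        kxr, kzr = kx, kz
        kxr, kzr = np.broadcast_to(kxr, shape), np.broadcast_to(kzr, shape)
    else:
        r = np.asarray(rotation, float)
        kxr = r[0, 0] * kx + r[0, 1] * ky + r[0, 2] * kz
        kzr = r[2, 0] * kx + r[2, 1] * ky + r[2, 2] * kz
    keep = np.abs(kzr) <= tan * np.abs(kxr)
    keep |= (np.abs(kxr) < 1e-12) & (np.abs(kzr) < 1e-12)
    out = keep.astype(np.float32)
    if rotation is None:
        _WEDGE_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# correlation

def _masked_zero_mean(vol: np.ndarray, mask: np.ndarray) -> np.ndarray:
    msum = mask.sum()
    if msum <= 0:
        raise UndefinedCorrelationError("mask is empty")
    mean = (vol * mask).sum() / msum
    return (vol - mean) * mask


def _local_norm_map(sub_w: np.ndarray, mask: np.ndarray):
    """Per-shift local L2 norm of the (wedge-filtered) subvolume under the
    mask: sqrt(sum_x m(x) b(x+t)^2 - (sum_x m(x) b(x+t))^2 / M).

    Computed with two mask cross-correlations; this is the denominator of
    the fast local correlation function, and it does not depend on the
    reference or candidate rotation.
    """
    m32 = mask.astype(np.float32)
    msum = float(m32.sum())
    if msum <= 0:
        raise UndefinedCorrelationError("mask is empty")
    fm = fftn(m32)
    fb = fftn(sub_w.astype(np.float32))
    fb2 = fftn((sub_w * sub_w).astype(np.float32))
    s1 = ifftn(fb * np.conj(fm)).real
    s2 = ifftn(fb2 * np.conj(fm)).real
    var = np.maximum(s2 - s1 * s1 / msum, 0.0)
    return np.sqrt(var)


def _peak_in_window(cc: np.ndarray, limit_vox: int, subvoxel: bool):
    """Argmax of a circular correlation volume over shifts within
    +-limit_vox, with optional per-axis parabolic sub-voxel refinement.
    Returns (shift_zyx_float, peak_value)."""
    n = cc.shape[0]
    limit_vox = int(min(limit_vox, n // 2 - 1))
    win = np.arange(-limit_vox, limit_vox + 1)
    idx = np.ix_(win % n, win % n, win % n)
    block = cc[idx]
    flat = int(np.argmax(block))
    pk = np.array(np.unravel_index(flat, block.shape))
    shift = win[pk].astype(float)
    val = float(block[tuple(pk)])
    if subvoxel:
        for ax in range(3):
            if 0 < pk[ax] < block.shape[ax] - 1:
                sel = list(pk)
                sel[ax] = pk[ax] - 1
                lo_v = block[tuple(sel)]
                sel[ax] = pk[ax] + 1
                hi_v = block[tuple(sel)]
                denom = lo_v - 2.0 * val + hi_v
                if denom < -1e-30:
                    shift[ax] += 0.5 * (lo_v - hi_v) / denom
    return shift, val


def _zoomed_peak(pspec: np.ndarray, centre_zyx, upsample: int = 16,
                 halfwidth: float = 1.25):
    """Refine a correlation peak by evaluating the cross-correlation on an
    upsampled grid around ``centre_zyx`` directly from the product spectrum
    (matrix DFT). Avoids the grid-locking bias of parabolic interpolation.

    Returns (refined shift [z, y, x] in voxels, peak value)."""
    steps = np.arange(-halfwidth, halfwidth + 1e-9, 1.0 / upsample)
    mats = []
    for ax, n in enumerate(pspec.shape):
        k = fftfreq(n)
        t = centre_zyx[ax] + steps
        mats.append(np.exp(2j * np.pi * np.outer(t, k)).astype(np.complex64))
    tmp = np.tensordot(mats[0], pspec, axes=(1, 0))          # (tz, Ny, Nx)
    tmp = np.tensordot(mats[1], tmp, axes=(1, 1))            # (ty, tz, Nx)
    tmp = np.tensordot(mats[2], tmp, axes=(1, 2))            # (tx, ty, tz)
    cc = tmp.real.transpose(2, 1, 0) / pspec.size            # (tz, ty, tx)
    pk = np.array(np.unravel_index(int(np.argmax(cc)), cc.shape))
    shift = np.asarray(centre_zyx, float) + steps[pk]
    return shift, float(cc[tuple(pk)])


def constrained_ncc(
    ref: np.ndarray,
    sub: Subvolume,
    mask: np.ndarray | None = None,
    shift_limit: float = 60.0,
    wedge_compensate: bool = True,
    subvoxel: bool = True,
    zoomed: bool = True,
    rotation=None,
) -> AlignmentResult:
    """Missing-wedge-compensated, masked, FFT-based normalised cross
    correlation over translations within ``+-shift_limit`` Angstrom.

    ``ref`` must already be in the subvolume's orientation frame (use
    :func:`cone_angular_search` to search rotations); ``rotation`` is
    reported in the result. The wedge of the subvolume is applied to both
    volumes in Fourier space before normalisation, so missing-wedge zeros
    do not dilute the score.
    """
    ref = np.asarray(ref, float)
    if ref.shape != sub.grid.shape:
        raise ValueError("ref and subvolume grids must match")
    if mask is None:
        mask = np.ones(ref.shape)
    mask = np.asarray(mask, float)
    if mask.min() < -1e-6 or mask.max() > 1 + 1e-6:
        raise ValueError("mask values must lie in [0, 1]")
    mask = np.clip(mask, 0.0, 1.0)

    a = _masked_zero_mean(ref, mask).astype(np.float32)
    b = _masked_zero_mean(np.asarray(sub.grid, float), mask).astype(np.float32)
    if not (np.any(a) and np.any(b)):
        raise UndefinedCorrelationError("all-zero volume under the mask")
    w = (wedge_weight(ref.shape, sub.wedge) if wedge_compensate
         else np.ones(ref.shape, dtype=np.float32))
    faw = fftn(a) * w
    fbw = fftn(b) * w
    norm = np.sqrt((np.abs(faw) ** 2).sum() * (np.abs(fbw) ** 2).sum()) / a.size
    if norm <= 0:
        raise UndefinedCorrelationError("all-zero volume under the mask/wedge")
    pspec = fbw * np.conj(faw)
    cc = ifftn(pspec).real / norm
    limit_vox = int(np.floor(shift_limit / sub.voxel_size))
    if subvoxel and zoomed and limit_vox > 0:
        # upsampled matrix-DFT refinement around the integer peak: parabolic
        # interpolation alone locks onto the voxel grid
        shift_zyx, score = _peak_in_window(cc, limit_vox, subvoxel=False)
        shift_zyx, val = _zoomed_peak(pspec, shift_zyx)
        score = val / norm
    else:
        shift_zyx, score = _peak_in_window(cc, limit_vox, subvoxel=subvoxel)
    shift_xyz = shift_zyx[::-1] * sub.voxel_size
    rot = np.zeros(3) if rotation is None else np.asarray(rotation, float)
    return AlignmentResult(shift=shift_xyz, rotation=rot,
                           score=float(np.clip(score, -1.0, 1.0)))


def cone_angular_search(
    ref: np.ndarray,
    sub: Subvolume,
    prior,
    cone_half_angle: float = 60.0,
    angular_step: float = 10.0,
    shift_limit: float = 60.0,
    mask: np.ndarray | None = None,
    inplane_range: float = 180.0,
    wedge_compensate: bool = True,
    subvoxel: bool = True,
) -> AlignmentResult:
    """Exhaustive search over a quasi-uniform rotation grid inside a cone
    about the prior orientation (plus in-plane sweep), each candidate scored
    by :func:`constrained_ncc` on the candidate-rotated reference.

    Candidates are visited in order of angular distance from the prior and a
    new best requires a strictly higher score, so ties resolve to the
    smallest angular move.
    """
    if not 0.0 <= cone_half_angle <= 180.0:
        raise ValueError("cone_half_angle must be in [0, 180]")
    if angular_step <= 0:
        raise ValueError("angular_step must be > 0")
    prior = np.asarray(prior, float)
    if cone_half_angle > 0.0 and angular_step > cone_half_angle and inplane_range <= 0:
        warnings.warn("angular grid is empty beyond the prior; returning the prior")
    candidates = rotation_grid_in_cone(prior, cone_half_angle, angular_step,
                                       inplane_range=inplane_range)
    best = None
    for cand in candidates:
        rotated = rotate_volume(ref, cand)
        res = constrained_ncc(rotated, sub, mask=mask, shift_limit=shift_limit,
                              wedge_compensate=wedge_compensate, subvoxel=subvoxel,
                              rotation=cand)
        if best is None or res.score > best.score + 1e-12:
            best = res
    return best


# ---------------------------------------------------------------------------
# masks

def cosine_edge_mask(shape, voxel_size: float, radius_A: float,
                     z_range_A=None, soft_edge_vox: float = 3.0) -> np.ndarray:
    """Soft cylindrical mask about the cube centre (axis = z), optionally
    cropped to a z range in Angstrom about the centre plane."""
    n = shape[0]
    c = n // 2
    idx = (np.arange(n) - c) * voxel_size
    z, y, x = np.meshgrid(idx, idx, idx, indexing="ij")
    edge = soft_edge_vox * voxel_size
    r = np.sqrt(x**2 + y**2)
    mask = np.clip((radius_A - r) / edge, 0.0, 1.0)
    mask = 0.5 - 0.5 * np.cos(np.pi * mask)
    if z_range_A is not None:
        zmin, zmax = z_range_A
        zmask = np.minimum(np.clip((z - zmin) / edge, 0, 1), np.clip((zmax - z) / edge, 0, 1))
        mask *= 0.5 - 0.5 * np.cos(np.pi * zmask)
    return mask


def stage_masks(shape, voxel_size: float, config: RefinementConfig):
    """(stage-1 mask with membrane slab, stage-2 membrane-free mask).

    Stage 1 spans the multi-CSU footprint plus the membrane slab; stage 2 is
    a tighter membrane-free cylinder (the extended membrane correlates into
    a shift bias along the wedge-damaged normal if left in at this stage).
    """
    r1 = min(config.mask_radius_A, 0.47 * shape[0] * voxel_size)
    r2 = min(config.mask_radius_stage2_A, 0.47 * shape[0] * voxel_size)
    m1 = cosine_edge_mask(shape, voxel_size, r1, config.mask_stage1_z)
    m2 = cosine_edge_mask(shape, voxel_size, r2, config.mask_stage2_z)
    return m1, m2


def fsc_mask(shape, voxel_size: float, config: RefinementConfig) -> np.ndarray:
    """Membrane-free mask over the full multi-CSU footprint, for FSC and
    local-resolution estimation."""
    r = min(config.mask_radius_A, 0.47 * shape[0] * voxel_size)
    return cosine_edge_mask(shape, voxel_size, r, config.mask_stage2_z)


def lowpass(vol: np.ndarray, voxel_size: float, resolution_A: float,
            soft_vox: float = 2.0) -> np.ndarray:
    """Cosine-edged spherical low-pass at 1/resolution_A."""
    if resolution_A <= 2.0 * voxel_size:
        return np.asarray(vol, float)
    shape = vol.shape
    k = np.sqrt(
        fftfreq(shape[0]).reshape(-1, 1, 1) ** 2
        + fftfreq(shape[1]).reshape(1, -1, 1) ** 2
        + fftfreq(shape[2]).reshape(1, 1, -1) ** 2
    ) / voxel_size
    cut = 1.0 / resolution_A
    width = soft_vox / (shape[0] * voxel_size)
    filt = np.clip((cut + width - k) / width, 0.0, 1.0)
    filt = 0.5 - 0.5 * np.cos(np.pi * filt)
    return ifftn(fftn(np.asarray(vol, float)) * filt).real


# ---------------------------------------------------------------------------
# iterative two-stage refinement

def _bin_volume(vol: np.ndarray, factor: int) -> np.ndarray:
    if factor <= 1:
        return vol
    n = (vol.shape[0] // factor) * factor
    v = vol[:n, :n, :n]
    return v.reshape(n // factor, factor, n // factor, factor, n // factor, factor).mean(
        axis=(1, 3, 5))


def _anchor_reference(reference: np.ndarray, anchor: np.ndarray, voxel: float,
                      mask: np.ndarray, lowpass_A: float = 40.0) -> np.ndarray:
    """Translationally register an evolving average onto the fixed anchor
    template, cancelling the lattice-phase gauge drift of self-consistent
    alignment (the average is only defined up to a rigid offset)."""
    from scipy import ndimage

    ref_lp = lowpass(reference, voxel, lowpass_A)
    sub = Subvolume(grid=ref_lp, voxel_size=voxel, source_position=(0, 0, 0))
    try:
        res = constrained_ncc(anchor, sub, mask=mask, shift_limit=8.0 * voxel)
    except UndefinedCorrelationError:
        return reference
    shift_vox = res.shift[::-1] / voxel        # (z, y, x)
    if np.all(np.abs(shift_vox) < 1e-3):
        return reference
    return ndimage.shift(reference, -shift_vox, order=1, mode="constant")


def iterative_refine(
    particles: ParticleSet,
    tomograms: list,
    config: RefinementConfig,
    initial_reference: np.ndarray | None = None,
    template_renderer=None,
    verbose: bool = False,
):
    """Two-stage masked iterative alignment.

    Stage 1 searches a wide cone with a full in-plane sweep inside the
    membrane-containing mask; stage 2 refines inside the membrane-free mask
    with a tighter cone and finer step. The angular search runs on
    ``search_bin``-binned volumes; translations are then refined at full
    sampling with sub-voxel interpolation. Returns ``(refined ParticleSet,
    final average volume, history)`` where history holds per-iteration mean
    scores. Aborts with :class:`AlignmentDivergenceError` if the mean score
    drops by more than the divergence tolerance.
    """
    from .validation import average_from_particles  # deferred: avoids import cycle

    tomo_by_id = {t.tomo_id: t for t in tomograms}
    voxel = tomograms[0].voxel_size
    n_box = int(round(config.box_A / voxel))
    current = particles.subset(np.arange(len(particles)))
    bin_f = max(1, int(config.search_bin)) if n_box // max(1, int(config.search_bin)) >= 16 else 1

    stages = [
        dict(stage=1, cone=config.cone_stage1, step=config.angular_step_stage1,
             inplane=config.inplane_range_stage1, lowpass_A=config.lowpass_stage1),
        dict(stage=2, cone=config.cone_stage2, step=config.angular_step_stage2,
             inplane=config.inplane_range_stage2, lowpass_A=config.lowpass_stage2,
             polish=True),
    ]
    history = []
    anchor = None if initial_reference is None else np.asarray(initial_reference, float)
    reference = initial_reference
    avg = None
    for st in stages:
        prev_mean = -np.inf
        for it in range(config.max_iterations):
            if reference is None:
                avg = average_from_particles(tomo_by_id.values(), current, config.box_A)
                reference = avg.grid.astype(float)
                if anchor is not None:
                    _, m2_anchor = stage_masks(reference.shape, voxel, config)
                    reference = _anchor_reference(reference, anchor, voxel, m2_anchor)
            ref_f = lowpass(reference, voxel, st["lowpass_A"])
            mask1, mask2 = stage_masks(ref_f.shape, voxel, config)
            mask = mask1 if st["stage"] == 1 else mask2
            if it > 0 and st["inplane"] > 3.0 * st["step"]:
                # the full in-plane sweep is only needed once; later
                # iterations refine locally
                st = dict(st, inplane=3.0 * st["step"])
            previous = current
            current = _refine_pass(current, tomo_by_id, ref_f, mask, config, st, voxel,
                                   bin_f, renderer_factory=template_renderer)
            mean_score = float(np.mean(current.scores))
            if verbose:
                print(f"stage {st['stage']} iter {it}: mean score {mean_score:.5f}")
            if mean_score < prev_mean - config.divergence_tolerance:
                raise AlignmentDivergenceError(
                    f"mean score dropped {prev_mean:.4f} -> {mean_score:.4f} "
                    f"at stage {st['stage']} iteration {it}")
            if mean_score < prev_mean:
                # small dip: keep the better table, stop the stage
                current = previous
                reference = None
                break
            history.append(dict(stage=st["stage"], iteration=it, mean_score=mean_score))
            converged = mean_score - prev_mean < config.score_tolerance
            prev_mean = mean_score
            reference = None  # recompute from the refined particles
            if converged:
                break
    avg = average_from_particles(tomo_by_id.values(), current, config.box_A)
    return current, avg, history


def matched_refine(
    renderer,
    sub: Subvolume,
    euler0,
    mask: np.ndarray,
    shift_limit: float = 20.0,
    steps=(2.0, 0.7, 0.25, 0.1),
    offset0=None,
) -> AlignmentResult:
    """Local pose refinement against matched-rendered templates.

    ``renderer(euler, offset_A)`` must return a reference volume with the
    motif rendered at that orientation and sub-voxel offset through the same
    forward model as the data. Matching the fractional offset matters: a
    template splatted at the integer box centre carries a different
    interpolation pattern than the data particle and displaces the optimum
    by a fraction of a voxel. Parabolic coordinate descent over the three
    rotation axes with shrinking steps, refreshing the offset estimate from
    the correlation peak after each sweep; coarse sweeps are scored on
    2x-binned volumes, the final sweep and evaluation at full sampling. The
    mask is fixed at the entry orientation (soft, and the search spans only
    a few degrees); the data-side spectra are computed once per level.
    """
    from scipy.spatial.transform import Rotation

    euler0 = np.asarray(euler0, float)
    offset = np.zeros(3) if offset0 is None else np.asarray(offset0, float).copy()
    mask_rot = np.clip(rotate_volume(mask, euler0), 0.0, 1.0)
    levels = {}
    for level, bf in (("full", 1),):
        grid = _bin_volume(np.asarray(sub.grid, float), bf)
        m = _bin_volume(mask_rot, bf)
        w = wedge_weight(grid.shape, sub.wedge)
        b = _masked_zero_mean(grid, m).astype(np.float32)
        fbw = fftn(b) * w
        nb2 = (np.abs(fbw) ** 2).sum()
        if nb2 <= 0:
            raise UndefinedCorrelationError("all-zero subvolume under the mask")
        levels[level] = (bf, m, w, fbw, nb2, b.size,
                         int(np.floor(shift_limit / (sub.voxel_size * bf))))
    cache = {}

    def evaluate(rot: "Rotation", off, level="full", fine: bool = False):
        key = (tuple(np.round(rot.as_quat(), 7)), tuple(np.round(off, 4)),
               level, fine)
        if key in cache:
            return cache[key]
        bf, m, w, fbw, nb2, size, limit_vox = levels[level]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            euler = rot.as_euler("ZYZ", degrees=True)
        tmpl = _bin_volume(renderer(euler, off).astype(float), bf)
        a = _masked_zero_mean(tmpl, m).astype(np.float32)
        faw = fftn(a) * w
        norm = np.sqrt((np.abs(faw) ** 2).sum() * nb2) / size
        if norm <= 0:
            out = (-1.0, np.zeros(3))
        else:
            pspec = fbw * np.conj(faw)
            cc = ifftn(pspec).real
            shift0, _ = _peak_in_window(cc, limit_vox, subvoxel=False)
            if fine:
                shift, val = _zoomed_peak(pspec, shift0, upsample=16)
            else:
                shift, val = _zoomed_peak(pspec, shift0, upsample=4, halfwidth=1.0)
            out = (val / norm, shift * bf)     # shift in full-grid voxels
        cache[key] = out
        return out

    current = Rotation.from_euler("ZYZ", euler0, degrees=True)
    best_score, best_rot = evaluate(current, offset, "full")[0], current
    prev_level = "full"
    for si, s in enumerate(steps):
        # binned scoring was evaluated and rejected: the coarse offset
        # refresh costs ~2x in final precision for a ~15% speed gain
        level = "full"
        if level != prev_level:
            # scores are not comparable across levels; restart the incumbent
            current = best_rot
            best_score = evaluate(current, offset, level)[0]
            prev_level = level
        for axis in ("x", "y", "z"):
            trio = [current * Rotation.from_euler(axis, d, degrees=True)
                    for d in (-s, 0.0, s)]
            f0, f1, f2 = (evaluate(r, offset, level)[0] for r in trio)
            den = f0 - 2.0 * f1 + f2
            if den < -1e-12:
                delta = float(np.clip(0.5 * s * (f0 - f2) / den, -s, s))
            else:
                delta = s * (int(np.argmax([f0, f1, f2])) - 1)
            if delta != 0.0:
                current = current * Rotation.from_euler(axis, delta, degrees=True)
            score = evaluate(current, offset, level)[0]
            if score > best_score:
                best_score, best_rot = score, current
        # fold the measured residual into the rendering offset so the
        # template's interpolation pattern tracks the data particle's
        _, shift_zyx = evaluate(best_rot, offset, level)
        offset = offset + shift_zyx[::-1] * sub.voxel_size
    score, shift_zyx = evaluate(best_rot, offset, "full", fine=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        eul_best = best_rot.as_euler("ZYZ", degrees=True)
    total_shift = offset + shift_zyx[::-1] * sub.voxel_size
    return AlignmentResult(shift=total_shift, rotation=eul_best,
                           score=float(np.clip(score, -1.0, 1.0)))


def _polish_rotation(score_of, d_eul, step_deg: float) -> np.ndarray:
    """Parabolic coordinate descent on the three rotation axes.

    Starting from the discrete-grid winner, each round perturbs the relative
    rotation about x, y and z in turn by +-s, fits a parabola through the
    three scores and jumps to its vertex (clamped to +-s); the step then
    shrinks. Gives sub-grid angular accuracy on a smooth correlation
    landscape.
    """
    from scipy.spatial.transform import Rotation

    d_rot = Rotation.from_euler("ZYZ", d_eul, degrees=True)
    for s in (0.6 * step_deg, 0.2 * step_deg):
        for axis in ("x", "y", "z"):
            scores = []
            for delta in (-s, 0.0, s):
                cand = d_rot * Rotation.from_euler(axis, delta, degrees=True)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scores.append(score_of(cand.as_euler("ZYZ", degrees=True)))
            f0, f1, f2 = scores
            den = f0 - 2.0 * f1 + f2
            if den < -1e-12:
                delta_star = float(np.clip(0.5 * s * (f0 - f2) / den, -s, s))
            else:
                delta_star = s * (int(np.argmax(scores)) - 1)
            if delta_star != 0.0:
                d_rot = d_rot * Rotation.from_euler(axis, delta_star, degrees=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return d_rot.as_euler("ZYZ", degrees=True)


def _refine_pass(particles, tomo_by_id, reference, mask, config, st, voxel, bin_f,
                 renderer_factory=None):
    """One alignment sweep over all particles against a fixed reference."""
    n = reference.shape[0]
    ref_b = _bin_volume(reference, bin_f)
    mask_b = _bin_volume(mask, bin_f)
    # shared candidate grid about identity, ordered by angular distance
    candidates = rotation_grid_in_cone(np.zeros(3), st["cone"], st["step"],
                                       inplane_range=st["inplane"])
    interp = getattr(config, "interp_order", 3)
    cand_f = []
    for cand in candidates:
        a = _masked_zero_mean(rotate_volume(ref_b, cand, order=interp),
                              mask_b).astype(np.float32)
        cand_f.append((cand, fftn(a)))

    limit_vox_b = int(np.floor(config.shift_limit_refine / (voxel * bin_f)))
    new_pos = np.zeros_like(particles.positions)
    new_eul = np.zeros_like(particles.eulers)
    new_score = np.zeros(len(particles))
    for i in range(len(particles)):
        tomo = tomo_by_id[particles.tomo_ids[i]]
        sub = extract_subvolume(tomo, particles.positions[i], config.box_A)
        r_cur = euler_to_matrix(particles.eulers[i])
        # bring the subvolume into the reference frame
        inv_eul = matrix_to_euler(r_cur.T)
        sub_rot = rotate_volume(sub.grid.astype(np.float32), inv_eul, order=interp)
        sub_b = _bin_volume(sub_rot, bin_f)
        b = _masked_zero_mean(sub_b, mask_b).astype(np.float32)
        w = wedge_weight(b.shape, sub.wedge, rotation=r_cur)
        fbw = fftn(b) * w
        nb = np.sqrt((np.abs(fbw) ** 2).sum() / b.size)

        def score_of(d_euler):
            a = _masked_zero_mean(rotate_volume(ref_b, d_euler, order=interp),
                                  mask_b).astype(np.float32)
            faw = fftn(a) * w
            na = np.sqrt((np.abs(faw) ** 2).sum() / b.size)
            if na <= 0 or nb <= 0:
                return -np.inf
            cc = ifftn(fbw * np.conj(faw)).real / (na * nb)
            _, score = _peak_in_window(cc, limit_vox_b, subvoxel=True)
            return score

        best = (-np.inf, np.zeros(3), np.zeros(3))
        for cand, fa in cand_f:
            faw = fa * w
            na = np.sqrt((np.abs(faw) ** 2).sum() / b.size)
            if na <= 0 or nb <= 0:
                continue
            cc = ifftn(fbw * np.conj(faw)).real / (na * nb)
            shift_zyx, score = _peak_in_window(cc, limit_vox_b, subvoxel=True)
            if score > best[0] + 1e-12:
                best = (score, cand, shift_zyx)
        _, d_eul, _ = best
        degenerate_search = st["cone"] <= 0 and st["inplane"] <= 0
        if st.get("polish") and not degenerate_search:
            d_eul = _polish_rotation(score_of, d_eul, st["step"])
        r_new = r_cur @ euler_to_matrix(d_eul)
        eul_new = matrix_to_euler(r_new)
        if renderer_factory is not None and st.get("polish") and not degenerate_search:
            # matched-template pose polish: removes the rotational flatness
            # of grid-rotated references near the optimum
            renderer = renderer_factory(particles, i, sub)
            res = matched_refine(renderer, sub, eul_new, mask,
                                 shift_limit=config.shift_limit_refine,
                                 steps=(0.6 * st["step"], 0.25 * st["step"],
                                        0.1 * st["step"], 0.04 * st["step"]),
                                 offset0=particles.positions[i] - sub.source_position)
            eul_new = res.rotation
        else:
            # full-resolution translational refinement at the new
            # orientation; the mask lives in the reference frame, so rotate
            # it along
            ref_rot = rotate_volume(reference, eul_new, order=interp)
            mask_rot = rotate_volume(mask, eul_new)
            res = constrained_ncc(ref_rot, sub, mask=mask_rot,
                                  shift_limit=config.shift_limit_refine,
                                  subvoxel=True, rotation=eul_new)
        if config.shift_limit_refine < voxel:
            # degenerate window: keep the prior position (null refinement)
            new_pos[i] = particles.positions[i]
        else:
            new_pos[i] = sub.source_position + res.shift
        new_eul[i] = eul_new
        new_score[i] = res.score
    return ParticleSet(positions=new_pos, eulers=new_eul, tomo_ids=particles.tomo_ids,
                       scores=new_score, ids=particles.ids)
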