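"""Forward rendering of ground-truth arrays and tomogram degradation.

Axis conventions: arrays are [z, y, x]; the single tilt axis is y, so the
missing wedge is the double-cone about the z (beam) axis in the (kx, kz)
plane.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage
from scipy.fft import fftn, ifftn, fftfreq

from ..geometry import euler_to_matrix
from ..volume import TomogramVolume
from .lattice import GroundTruthArray
from .motif import DensityMotif
from .tilt import TiltScheme


def render_tomogram(
    truth: GroundTruthArray,
    motif: DensityMotif,
    voxel_size: float,
    box,
    origin=None,
    membrane_weight: float = 1.0,
    membrane_sd: float = 14.0,
) -> TomogramVolume:
    """Sum of the motif rotated/translated to every ground-truth particle,
    plus a Gaussian membrane shell along the surface.

    ``box`` is the output grid shape in voxels (scalar -> cube, or (nz, ny,
    nx)). ``origin`` is the Angstrom position of voxel (0,0,0); by default
    the grid is centred on the particle centroid (or the surface centre for
    an empty array). Particles whose support leaves the box are clipped and
    counted in a warning.
    """
    box = np.broadcast_to(np.asarray(box, int), (3,)).copy()  # (nz, ny, nx)
    if np.any(box < 2):
        raise ValueError("box must be >= 2 voxels in each axis")
    if origin is None:
        centre = (truth.positions.mean(axis=0) if len(truth) else
                  truth.surface.project(truth.surface.center + [0, 0, 1e-9]))
        origin = centre - 0.5 * box[::-1] * voxel_size
    origin = np.asarray(origin, float)

    grid = np.zeros(tuple(box), dtype=np.float64)
    half_support = 0.5 * motif.box_A
    clipped = 0
    for pos, euler in zip(truth.positions, truth.eulers):
        ok = _splat_motif(grid, motif, pos - origin, euler, voxel_size)
        clipped += 0 if ok else 1
    if clipped:
        warnings.warn(f"{clipped} particle(s) extended outside the box and were clipped")

    if membrane_weight > 0.0 and len(truth):
        zc = (origin[2] + np.arange(box[0]) * voxel_size).astype(np.float32)
        yc = (origin[1] + np.arange(box[1]) * voxel_size).astype(np.float32)
        xc = (origin[0] + np.arange(box[2]) * voxel_size).astype(np.float32)
        surf = truth.surface
        chart_r = surf.chart_radius() + half_support
        if surf.kind == "plane":
            dist = np.abs(zc - surf.center[2]).reshape(-1, 1, 1)
            shell = membrane_weight * np.exp(-0.5 * (dist / membrane_sd) ** 2)
            lat = np.maximum(np.abs(xc - surf.center[0]).reshape(1, 1, -1),
                             np.abs(yc - surf.center[1]).reshape(1, -1, 1))
            grid += shell * (lat <= chart_r)
        else:
            dz2 = ((zc - surf.center[2]) ** 2).reshape(-1, 1, 1)
            dy2 = ((yc - surf.center[1]) ** 2).reshape(1, -1, 1)
            dx2 = ((xc - surf.center[0]) ** 2).reshape(1, 1, -1)
            r = np.sqrt(dz2 + dy2 + dx2)
            dist = np.abs(r - surf.radius)
            shell = membrane_weight * np.exp(-0.5 * (dist / membrane_sd) ** 2)
            cos_pol = (zc - surf.center[2]).reshape(-1, 1, 1) / np.maximum(r, 1e-9)
            arc = surf.radius * np.arccos(np.clip(cos_pol, -1.0, 1.0))
            grid += shell * (arc <= chart_r)

    return TomogramVolume(grid=grid.astype(np.float32), voxel_size=float(voxel_size),
                          origin=origin, wedge=None)


def _splat_motif(grid, motif: DensityMotif, rel_pos, euler, voxel_size) -> bool:
    """Add the rotated motif at a position (Angstrom, relative to origin).

    Returns False if any part of the motif's bounding cube was clipped.
    """
    rot = euler_to_matrix(euler)
    m = motif.grid.shape[0]
    mc = m // 2
    half = 0.5 * m * motif.voxel_size * np.sqrt(3.0)  # rotated bounding radius
    lo = np.floor((rel_pos[::-1] - half) / voxel_size).astype(int)      # (z, y, x)
    hi = np.ceil((rel_pos[::-1] + half) / voxel_size).astype(int) + 1
    lo_c = np.maximum(lo, 0)
    hi_c = np.minimum(hi, grid.shape)
    if np.any(lo_c >= hi_c):
        return False
    zz, yy, xx = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo_c, hi_c)), indexing="ij")
    # Angstrom offsets from the particle position, (x, y, z) component order
    rel = np.asarray(rel_pos, float)
    dx = np.stack([xx, yy, zz], axis=0) * voxel_size - rel.reshape(3, 1, 1, 1)
    local = np.tensordot(rot.T, dx, axes=(1, 0)) / motif.voxel_size  # (x,y,z) comps
    coords = np.stack([local[2] + mc, local[1] + mc, local[0] + mc])  # [z,y,x] index
    vals = ndimage.map_coordinates(motif.grid, coords.reshape(3, -1), order=1,
                                   mode="constant", cval=0.0)
    grid[zz, yy, xx] += vals.reshape(zz.shape)
    return bool(np.all(lo >= 0) and np.all(hi <= grid.shape))


def render_motif_at(motif: DensityMotif, euler, n_box: int, voxel_size: float,
                    offset_A=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Render the motif at a given orientation, centred on the cube centre
    voxel (floor(n/2)), through the same splat path as full tomograms.

    Used for matched-template scoring: a template produced this way shares
    the forward model (and its interpolation pattern) with simulated data,
    so the correlation optimum sits exactly at the true pose.
    """
    grid = np.zeros((n_box,) * 3, dtype=np.float64)
    centre = np.full(3, (n_box // 2) * voxel_size) + np.asarray(offset_A, float)
    _splat_motif(grid, motif, centre, np.asarray(euler, float), voxel_size)
    return grid.astype(np.float32)


def make_matched_renderer_factory(motif: DensityMotif, scheme=None,
                                  surface=None, membrane_weight: float = 0.0,
                                  membrane_sd: float = 14.0):
    """Factory of per-particle matched-template renderers for pose polish.

    For particle ``i`` the renderer adds (a) a fixed context — the currently
    estimated neighbouring particles (and optionally the membrane shell)
    splatted at their poses and degraded by the missing wedge — and (b) the
    central motif rendered at the candidate orientation, wedge-degraded the
    same way. Because the data's wedge acted before any masking, streaks
    from out-of-mask neighbours leak under the alignment mask; a context-
    aware pre-wedged template reproduces them and keeps the correlation
    optimum at the true pose.
    """
    from scipy.fft import fftn as _fftn, ifftn as _ifftn

    def factory(particles, i, sub):
        n_box = sub.grid.shape[0]
        voxel = sub.voxel_size
        origin = sub.source_position - (n_box // 2) * voxel
        w = None
        if scheme is not None and scheme.max_angle < 90.0:
            w = wedge_mask((n_box,) * 3, scheme.max_angle)

        ctx = np.zeros((n_box,) * 3, dtype=np.float64)
        pos_i = particles.positions[i]
        reach = 0.5 * n_box * voxel + 0.5 * motif.box_A * np.sqrt(3.0)
        dist = np.linalg.norm(particles.positions - pos_i, axis=1)
        same_tomo = particles.tomo_ids == particles.tomo_ids[i]
        for j in np.nonzero((dist > 1e-6) & (dist < reach) & same_tomo)[0]:
            _splat_motif(ctx, motif, particles.positions[j] - origin,
                         particles.eulers[j], voxel)
        if membrane_weight > 0.0 and surface is not None:
            zc = (origin[2] + np.arange(n_box) * voxel).astype(np.float32)
            yc = (origin[1] + np.arange(n_box) * voxel).astype(np.float32)
            xc = (origin[0] + np.arange(n_box) * voxel).astype(np.float32)
            dz2 = ((zc - surface.center[2]) ** 2).reshape(-1, 1, 1)
            dy2 = ((yc - surface.center[1]) ** 2).reshape(1, -1, 1)
            dx2 = ((xc - surface.center[0]) ** 2).reshape(1, 1, -1)
            if surface.kind == "sphere-cap":
                d = np.abs(np.sqrt(dz2 + dy2 + dx2) - surface.radius)
            else:
                d = np.abs(zc - surface.center[2]).reshape(-1, 1, 1) + 0.0 * (dy2 + dx2)
            ctx += membrane_weight * np.exp(-0.5 * (d / membrane_sd) ** 2)
        if w is not None:
            ctx = _ifftn(_fftn(ctx.astype(np.float32)) * w).real
        ctx32 = ctx.astype(np.float32)

        def renderer(euler, offset_A=(0.0, 0.0, 0.0)):
            central = render_motif_at(motif, euler, n_box, voxel, offset_A=offset_A)
            if w is not None:
                central = _ifftn(_fftn(central) * w).real.astype(np.float32)
            return ctx32 + central

        return renderer

    return factory


def wedge_mask(shape, max_angle: float) -> np.ndarray:
    """Boolean Fourier mask of the sampled region for a +-max_angle tilt
    about the y axis (True = sampled). Unshifted (fftn) layout."""
    if max_angle >= 90.0:
        return np.ones(shape, dtype=bool)
    kz = fftfreq(shape[0]).reshape(-1, 1, 1)
    kx = fftfreq(shape[2]).reshape(1, 1, -1)
    tan = np.tan(np.radians(max_angle))
    return (np.abs(kz) <= tan * np.abs(kx)) | ((np.abs(kz) == 0) & (np.abs(kx) == 0))


def apply_missing_wedge(vol: TomogramVolume, scheme: TiltScheme) -> TomogramVolume:
    """Zero all Fourier coefficients outside the sampled double-cone."""
    if scheme.max_angle > 90.0:
        raise ValueError("max_angle must be <= 90 degrees")
    if scheme.max_angle >= 90.0:
        return vol.copy_with(grid=vol.grid.copy(), wedge=scheme)  # fully sampled
    mask = wedge_mask(vol.grid.shape, scheme.max_angle)
    spec = fftn(vol.grid.astype(np.float32))
    out = ifftn(spec * mask).real
    return vol.copy_with(grid=out.astype(np.float32), wedge=scheme)


def add_noise(vol: TomogramVolume, snr: float, seed: int = 0) -> TomogramVolume:
    """Additive white Gaussian noise with variance var(signal)/snr."""
    if snr <= 0:
        raise ValueError("snr must be > 0")
    rng = np.random.default_rng(seed)
    sigma = float(np.std(vol.grid)) / np.sqrt(snr)
    noisy = vol.grid + rng.normal(0.0, sigma, size=vol.grid.shape)
    return vol.copy_with(grid=noisy.astype(np.float32))


def project_and_wbp(vol: TomogramVolume, scheme: TiltScheme, bin: int = 1) -> TomogramVolume:
    """Parallel-beam projection at the scheme's angles, ramp-weighted
    back-projection, then block-mean binning.

    Slower but more faithful than the direct Fourier wedge; the two must
    agree inside a central mask (cross-validated in tests).
    """
    if int(bin) != bin or bin < 1:
        raise ValueError("bin must be a positive integer")
    grid = vol.grid.astype(np.float64)
    nz, ny, nx = grid.shape
    angles = np.asarray(scheme.angles, float)

    ramp = np.abs(fftfreq(nx)).reshape(1, 1, nx)
    recon = np.zeros_like(grid)
    for ang in angles:
        tilted = ndimage.rotate(grid, ang, axes=(0, 2), reshape=False, order=1)
        proj = tilted.sum(axis=0, keepdims=True)                    # (1, ny, nx)
        filt = ifftn(fftn(proj, axes=(2,)) * ramp, axes=(2,)).real
        smear = np.broadcast_to(filt, grid.shape)
        recon += ndimage.rotate(smear, -ang, axes=(0, 2), reshape=False, order=1)
    recon *= np.pi / (2.0 * len(angles))

    if bin > 1:
        nzb, nyb, nxb = (s // bin for s in recon.shape)
        recon = recon[:nzb * bin, :nyb * bin, :nxb * bin]
        recon = recon.reshape(nzb, bin, nyb, bin, nxb, bin).mean(axis=(1, 3, 5))
    return TomogramVolume(grid=recon.astype(np.float32), voxel_size=vol.voxel_size * bin,
                          origin=vol.origin.copy(), wedge=scheme, tomo_id=vol.tomo_id)
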