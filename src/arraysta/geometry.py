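"""Rotation conventions shared by every stage.

Euler angles are ZYZ, intrinsic, in degrees. The reference principal axis
is +z: a particle with orientation ``(a, b, c)`` has its principal axis at
polar angle ``b`` and azimuth ``a``; ``c`` is the in-plane (spin) angle.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "euler_to_matrix",
    "matrix_to_euler",
    "euler_from_axis",
    "principal_axis",
    "angular_distance",
    "axis_angle_error",
    "fibonacci_cap",
    "rotation_grid_in_cone",
]

EULER_CONVENTION = "ZYZ"  # intrinsic (capital letters in scipy)


def euler_to_matrix(euler: np.ndarray) -> np.ndarray:
    """3x3 rotation matrix (or Nx3x3) from ZYZ intrinsic Euler degrees."""
    return Rotation.from_euler(EULER_CONVENTION, np.asarray(euler, float), degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> np.ndarray:
    """ZYZ intrinsic Euler degrees from a rotation matrix."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # gimbal-lock note is benign here
        return Rotation.from_matrix(matrix).as_euler(EULER_CONVENTION, degrees=True)


def principal_axis(euler: np.ndarray) -> np.ndarray:
    """Unit vector the orientation maps the reference +z axis onto."""
    mat = euler_to_matrix(euler)
    return mat @ np.array([0.0, 0.0, 1.0]) if mat.ndim == 2 else mat[..., :, 2]


def euler_from_axis(axis: np.ndarray, inplane_deg: float = 0.0) -> np.ndarray:
    """Euler triplet whose principal axis equals ``axis`` (unit-normalised).

    The triplet is ``(azimuth, polar, inplane)``; at the pole the azimuth is
    defined as 0 so the mapping stays deterministic.
    """
    ax = np.asarray(axis, float)
    ax = ax / np.linalg.norm(ax)
    polar = np.degrees(np.arccos(np.clip(ax[2], -1.0, 1.0)))
    azim = 0.0 if abs(ax[2]) > 1.0 - 1e-14 else np.degrees(np.arctan2(ax[1], ax[0]))
    return np.array([azim, polar, float(inplane_deg)])


def angular_distance(euler_a: np.ndarray, euler_b: np.ndarray) -> float:
    """Geodesic SO(3) distance in degrees between two orientations."""
    ra = Rotation.from_euler(EULER_CONVENTION, euler_a, degrees=True)
    rb = Rotation.from_euler(EULER_CONVENTION, euler_b, degrees=True)
    return float((ra.inv() * rb).magnitude() * 180.0 / np.pi)


def axis_angle_error(euler_a: np.ndarray, euler_b: np.ndarray) -> float:
    """Angle in degrees between the two principal axes (spin ignored)."""
    va, vb = principal_axis(euler_a), principal_axis(euler_b)
    return float(np.degrees(np.arccos(np.clip(np.dot(va, vb), -1.0, 1.0))))


def fibonacci_cap(half_angle_deg: float, step_deg: float) -> np.ndarray:
    """Quasi-uniform unit vectors within ``half_angle_deg`` of +z.

    The golden-angle spiral is generated at an areal density matching one
    point per ``step_deg``-sized cell; the exact +z direction is always the
    first entry.
    """
    if half_angle_deg <= 0:
        return np.array([[0.0, 0.0, 1.0]])
    cap = np.radians(half_angle_deg)
    step = np.radians(step_deg)
    # one point per (step x step) patch of the cap area 2*pi*(1-cos cap)
    n = max(1, int(np.ceil(2.0 * np.pi * (1.0 - np.cos(cap)) / (step * step))))
    k = np.arange(n)
    z = 1.0 - (1.0 - np.cos(cap)) * (k + 0.5) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([s * np.cos(phi), s * np.sin(phi), z])
    return np.vstack([[0.0, 0.0, 1.0], pts])


def rotation_grid_in_cone(
    prior_euler: np.ndarray,
    cone_half_angle: float,
    angular_step: float,
    inplane_range: float = 180.0,
) -> list[np.ndarray]:
    """Euler triplets covering a cone around a prior orientation.

    Axis directions are sampled quasi-uniformly within the cone about the
    prior's principal axis; the in-plane angle is swept in ``angular_step``
    increments over ``+-inplane_range`` about the prior's spin. The prior
    itself is element 0. Candidates are ordered by angular distance from
    the prior so that score ties resolve toward the smallest move.
    """
    prior_euler = np.asarray(prior_euler, float)
    r_prior = Rotation.from_euler(EULER_CONVENTION, prior_euler, degrees=True)
    tilts = fibonacci_cap(cone_half_angle, angular_step)
    if inplane_range <= 0:
        spins = np.array([0.0])
    else:
        spins = np.arange(-inplane_range, inplane_range - 1e-9, angular_step)
        if 0.0 not in spins:
            spins = np.sort(np.append(spins, 0.0))
    cands = []
    for tilt_axis in tilts:
        # minimal-twist rotation taking +z to tilt_axis: Rz(a) Ry(b) Rz(-a)
        azim, polar, _ = euler_from_axis(tilt_axis)
        d_tilt = Rotation.from_euler(
            EULER_CONVENTION, [azim, polar, -azim], degrees=True
        )
        for spin in spins:
            d_spin = Rotation.from_euler("z", spin, degrees=True)
            cand = r_prior * d_tilt * d_spin
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # gimbal-lock note is benign here
                cands.append(cand.as_euler(EULER_CONVENTION, degrees=True))
    cands_arr = np.asarray(cands)
    dist = np.array([angular_distance(prior_euler, c) for c in cands_arr])
    order = np.argsort(dist, kind="stable")
    return [cands_arr[i] for i in order]
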