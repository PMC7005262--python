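"""Ground-truth honeycomb arrays on membrane surfaces.

Trimer-of-dimer axes sit on honeycomb vertices: a triangular Bravais lattice
with constant ``a = sqrt(3) * tod_spacing`` carrying two sites per cell, so
the nearest-neighbour separation is ``tod_spacing`` (3 first-shell
neighbours, 6 second-shell neighbours at ``sqrt(3) * tod_spacing``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ..geometry import euler_from_axis
from .surface import MembraneSurface

SQRT3 = np.sqrt(3.0)


@dataclass
class GroundTruthArray:
    surface: MembraneSurface
    tod_spacing: float           # Angstrom, nearest-neighbour axis separation
    jitter_sd: float             # Angstrom
    positions: np.ndarray        # (n, 3) Angstrom
    eulers: np.ndarray           # (n, 3) ZYZ degrees, principal axis = local normal

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float).reshape(-1, 3)
        self.eulers = np.asarray(self.eulers, float).reshape(-1, 3)

    @property
    def lattice_constant(self) -> float:
        """Hexagon-centre spacing of the underlying triangular lattice."""
        return SQRT3 * self.tod_spacing

    def __len__(self) -> int:
        return len(self.positions)


def honeycomb_points_2d(spacing: float, chart_radius: float) -> np.ndarray:
    """All honeycomb vertices with NN distance ``spacing`` inside a disc."""
    a1 = np.array([1.5 * spacing, 0.5 * SQRT3 * spacing])
    a2 = np.array([1.5 * spacing, -0.5 * SQRT3 * spacing])
    basis = np.array([[0.0, 0.0], [spacing, 0.0]])
    n_max = int(np.ceil(chart_radius / spacing)) + 2
    ij = np.mgrid[-n_max:n_max + 1, -n_max:n_max + 1].reshape(2, -1).T
    cells = ij[:, :1] * a1 + ij[:, 1:] * a2
    pts = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 2)
    keep = np.linalg.norm(pts, axis=1) <= chart_radius
    return pts[keep]


def triangular_points_2d(spacing: float, chart_radius: float) -> np.ndarray:
    """Bravais points of the honeycomb, shifted onto the bond midpoints.

    These are the two-ToD unit-cell (CSU) centres: a triangular lattice of
    constant ``sqrt(3) * spacing`` (6 nearest neighbours), positioned so a
    motif carrying sites at ``+- spacing/2`` along x reproduces the
    honeycomb exactly.
    """
    a1 = np.array([1.5 * spacing, 0.5 * SQRT3 * spacing])
    a2 = np.array([1.5 * spacing, -0.5 * SQRT3 * spacing])
    n_max = int(np.ceil(chart_radius / spacing)) + 2
    ij = np.mgrid[-n_max:n_max + 1, -n_max:n_max + 1].reshape(2, -1).T
    pts = ij[:, :1] * a1 + ij[:, 1:] * a2 + np.array([0.5 * spacing, 0.0])
    keep = np.linalg.norm(pts, axis=1) <= chart_radius
    return pts[keep]


def place_hex_array(
    surface: MembraneSurface,
    tod_spacing: float,
    jitter_sd: float = 0.0,
    seed: int = 0,
    random_inplane: bool = False,
    placement: str = "honeycomb",
) -> GroundTruthArray:
    """Place array sites over the surface.

    ``placement="honeycomb"`` puts trimer-of-dimer axes on honeycomb
    vertices (3 neighbours at ``tod_spacing``); ``"triangular"`` puts
    two-ToD unit-cell (CSU) centres on the underlying Bravais lattice
    (6 neighbours at ``sqrt(3) * tod_spacing``). Positions lie exactly on
    the surface (jitter is applied in the 2D chart and re-embedded);
    orientations have the principal axis along the local outward normal,
    with in-plane angle 0 or uniformly random per particle.
    """
    if tod_spacing <= 0:
        raise ValueError("tod_spacing must be > 0")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    if placement not in ("honeycomb", "triangular"):
        raise ValueError(f"unknown placement '{placement}'")
    rng = np.random.default_rng(seed)
    chart_r = surface.chart_radius()
    if chart_r < tod_spacing:
        warnings.warn("tod_spacing exceeds surface extent; returning an empty array")
        return GroundTruthArray(surface=surface, tod_spacing=tod_spacing, jitter_sd=jitter_sd,
                                positions=np.zeros((0, 3)), eulers=np.zeros((0, 3)))
    points_2d = (honeycomb_points_2d if placement == "honeycomb"
                 else triangular_points_2d)
    pts2 = points_2d(tod_spacing, chart_r)
    if jitter_sd > 0:
        pts2 = pts2 + rng.normal(0.0, jitter_sd, size=pts2.shape)
        pts2 = pts2[np.linalg.norm(pts2, axis=1) <= chart_r]
    pos = surface.embed(pts2)
    normals = surface.normal(pos)
    inplane = rng.uniform(0.0, 360.0, size=len(pos)) if random_inplane else np.zeros(len(pos))
    eulers = np.array([euler_from_axis(n, ip) for n, ip in zip(normals, inplane)])
    if len(eulers) == 0:
        eulers = np.zeros((0, 3))
    return GroundTruthArray(surface=surface, tod_spacing=tod_spacing, jitter_sd=jitter_sd,
                            positions=pos, eulers=eulers)
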