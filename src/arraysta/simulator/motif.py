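"""Parametric pseudo-CSU density motif.

A stand-in repeating unit with the gross shape of a transmembrane signalling
particle: a baseplate disc at the cytoplasmic end, a pair of receptor-like
cylinders rising through the membrane plane (local z = 0), and a pair of
periplasmic knobs. The pair arrangement makes the motif exactly C2-symmetric
about its central +z axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class DensityMotif:
    grid: np.ndarray         # [z, y, x], small cube
    voxel_size: float        # Angstrom
    symmetry: str = "C2"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, float)
        if not np.all(np.isfinite(self.grid)):
            raise ValueError("motif grid must be finite")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        if self.symmetry not in ("C1", "C2"):
            raise ValueError(f"unsupported symmetry '{self.symmetry}'")

    @property
    def box_A(self) -> float:
        return self.grid.shape[0] * self.voxel_size


def _soft_step(distance: np.ndarray, edge: float) -> np.ndarray:
    # 1 inside (distance<0), smooth roll-off over ~edge Angstrom
    return 0.5 * (1.0 - np.tanh(distance / max(edge, 1e-6)))


def pseudo_csu_motif(
    voxel_size: float = 4.5,
    box_A: float = 190.0,
    pair_offset: float = 26.0,
    cyl_radius: float = 13.0,
    cyl_slant_deg: float = 10.0,
    edge: float = 4.0,
) -> DensityMotif:
    """Build the two-bundle + baseplate + crossbar pseudo-CSU.

    The membrane plane sits at local z = 0 (the motif's nominal particle
    position); density spans roughly z in [-95, +60] Angstrom. The receptor
    bundles are slanted outward by ``cyl_slant_deg`` and the baseplate
    carries a transverse bar, so small template tilts are not degenerate
    with lateral shifts during alignment (parallel vertical cylinders
    would make that a flat valley).
    """
    n = int(round(box_A / voxel_size))
    n += n % 2  # even grid, centre voxel n//2
    c = n // 2
    idx = (np.arange(n) - c) * voxel_size
    z, y, x = np.meshgrid(idx, idx, idx, indexing="ij")

    grid = np.zeros((n, n, n))
    # baseplate disc, cytoplasmic end
    r_xy = np.sqrt(x**2 + y**2)
    d_disc = np.maximum(r_xy - 0.85 * (pair_offset + cyl_radius),
                        np.abs(z + 84.0) - 8.0)
    grid += 1.0 * _soft_step(d_disc, edge)
    # transverse kinase-like bar under the baseplate (C2 about z)
    d_bar = np.maximum.reduce([
        np.abs(y) - (pair_offset + 8.0), np.abs(x) - 10.0, np.abs(z + 66.0) - 9.0])
    grid += 1.1 * _soft_step(d_bar, edge)
    slant = np.radians(cyl_slant_deg)
    for sgn in (+1.0, -1.0):
        # receptor bundle slanted outward in the xz-plane
        base = np.array([sgn * pair_offset, 0.0, -78.0])
        axis = np.array([sgn * np.sin(slant), 0.0, np.cos(slant)])
        px, py, pz = x - base[0], y - base[1], z - base[2]
        t = px * axis[0] + py * axis[1] + pz * axis[2]
        d2 = px**2 + py**2 + pz**2 - t**2
        r_ax = np.sqrt(np.maximum(d2, 0.0))
        d_cyl = np.maximum(r_ax - cyl_radius,
                           np.maximum(t - 106.0, -t))
        grid += 1.2 * _soft_step(d_cyl, edge)
        # periplasmic knob at the bundle tip
        tip = base + 122.0 * axis
        d_knob = np.sqrt((x - tip[0]) ** 2 + (y - tip[1]) ** 2
                         + (z - tip[2]) ** 2) - 17.0
        grid += 0.9 * _soft_step(d_knob, edge)
    return DensityMotif(grid=grid, voxel_size=voxel_size, symmetry="C2")
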