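"""Tomogram volume container shared across all stages."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import mrc


@dataclass
class TomogramVolume:
    """3D scalar density grid.

    ``grid`` is indexed [z, y, x]; ``voxel_size`` in Angstrom; ``origin`` is
    the (x, y, z) Angstrom position of voxel (0, 0, 0)'s centre. ``wedge``
    holds the TiltScheme that degraded the volume, or None for full sampling.
    """

    grid: np.ndarray
    voxel_size: float
    origin: np.ndarray = None
    wedge: Optional[object] = None
    tomo_id: int = 0

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 2:
            raise ValueError(f"grid must be 3D with all dims >= 2, got {self.grid.shape}")
        if self.voxel_size <= 0:
            raise ValueError(f"voxel_size must be > 0, got {self.voxel_size}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, float).reshape(3)

    @property
    def shape(self):
        return self.grid.shape

    def copy_with(self, grid: np.ndarray, **kw) -> "TomogramVolume":
        fields = dict(voxel_size=self.voxel_size, origin=self.origin.copy(),
                      wedge=self.wedge, tomo_id=self.tomo_id)
        fields.update(kw)
        return TomogramVolume(grid=grid, **fields)

    def write(self, path) -> None:
        mrc.write_mrc(path, self.grid, self.voxel_size, origin=tuple(self.origin))

    @staticmethod
    def read(path, wedge=None, tomo_id: int = 0) -> "TomogramVolume":
        grid, voxel, origin = mrc.read_mrc(path)
        return TomogramVolume(grid=grid, voxel_size=voxel, origin=np.asarray(origin),
                              wedge=wedge, tomo_id=tomo_id)
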