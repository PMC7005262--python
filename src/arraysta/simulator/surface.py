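"""Membrane surface models: sphere-cap and plane.

A sphere-cap is centred at ``center`` with its cap pole towards +z and an
angular ``extent`` (max polar angle from the pole, degrees). A plane is the
z = center_z plane with lateral half-extent in x and y. Outward normals
point away from the sphere centre / towards +z.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateGeometryError(ValueError):
    """Input geometry does not determine the requested surface."""


@dataclass(frozen=True)
class MembraneSurface:
    kind: str                 # "sphere-cap" | "plane"
    center: np.ndarray        # Angstrom (x, y, z); for plane, a point on it
    radius: float = 0.0       # Angstrom, sphere-cap only
    extent: float = 0.0       # degrees (sphere-cap) or lateral half-extent A (plane)
    residual_rms: float = 0.0  # fit residual when produced by fit_sphere

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        if self.kind not in ("sphere-cap", "plane"):
            raise ValueError(f"unknown surface kind '{self.kind}'")
        if self.kind == "sphere-cap" and self.radius <= 0:
            raise ValueError("sphere-cap radius must be > 0")

    def normal(self, points: np.ndarray) -> np.ndarray:
        """Outward unit normal at (the surface point nearest to) each point."""
        pts = np.atleast_2d(np.asarray(points, float))
        if self.kind == "plane":
            out = np.tile([0.0, 0.0, 1.0], (len(pts), 1))
        else:
            d = pts - self.center
            norms = np.linalg.norm(d, axis=1, keepdims=True)
            if np.any(norms < 1e-12):
                raise DegenerateGeometryError("point coincides with sphere centre")
            out = d / norms
        return out if np.asarray(points).ndim == 2 else out[0]

    def project(self, points: np.ndarray) -> np.ndarray:
        """Nearest point on the surface for each input point."""
        pts = np.atleast_2d(np.asarray(points, float))
        if self.kind == "plane":
            out = pts.copy()
            out[:, 2] = self.center[2]
        else:
            out = self.center + self.normal(pts) * self.radius
        return out if np.asarray(points).ndim == 2 else out[0]

    def distance(self, points: np.ndarray) -> np.ndarray:
        """Unsigned distance to the surface."""
        pts = np.atleast_2d(np.asarray(points, float))
        if self.kind == "plane":
            d = np.abs(pts[:, 2] - self.center[2])
        else:
            d = np.abs(np.linalg.norm(pts - self.center, axis=1) - self.radius)
        return d if np.asarray(points).ndim == 2 else float(d[0])

    def embed(self, plane_xy: np.ndarray) -> np.ndarray:
        """Map 2D chart coordinates (Angstrom) onto the surface in 3D.

        Plane: identity into z = const. Sphere-cap: azimuthal-equidistant
        projection about the +z pole, so chart distances from the origin are
        preserved as arc lengths.
        """
        xy = np.atleast_2d(np.asarray(plane_xy, float))
        if self.kind == "plane":
            return np.column_stack([xy[:, 0] + self.center[0],
                                    xy[:, 1] + self.center[1],
                                    np.full(len(xy), self.center[2])])
        r = np.linalg.norm(xy, axis=1)
        theta = r / self.radius
        phi = np.arctan2(xy[:, 1], xy[:, 0])
        s = np.sin(theta)
        unit = np.column_stack([s * np.cos(phi), s * np.sin(phi), np.cos(theta)])
        return self.center + self.radius * unit

    def chart_radius(self) -> float:
        """Half-extent of the 2D chart covered by the surface, Angstrom."""
        if self.kind == "plane":
            return float(self.extent)
        return float(self.radius * np.radians(self.extent))


def plane_surface(center=(0.0, 0.0, 0.0), half_extent: float = 1000.0) -> MembraneSurface:
    return MembraneSurface(kind="plane", center=np.asarray(center, float), extent=half_extent)


def sphere_cap_surface(center, radius: float, extent_deg: float = 90.0) -> MembraneSurface:
    return MembraneSurface(kind="sphere-cap", center=np.asarray(center, float),
                           radius=float(radius), extent=float(extent_deg))
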