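"""Particle tables: the record set every pipeline stage transforms.

Serialised as tab-separated text with ``#``-prefixed metadata lines. All
positions are Angstrom internally; files declaring ``# units: nm`` are
converted on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import EULER_CONVENTION

COLUMNS = ["id", "tomo_id", "x_A", "y_A", "z_A", "eul1_deg", "eul2_deg", "eul3_deg", "score"]


class ParticleTableError(ValueError):
    """Schema problem in a particle table file."""


@dataclass
class ParticleSet:
    """Positions (Angstrom), ZYZ intrinsic Euler orientations (degrees),
    per-particle correlation scores and source-tomogram ids."""

    positions: np.ndarray            # (n, 3) float, Angstrom, (x, y, z)
    eulers: np.ndarray               # (n, 3) float, degrees
    tomo_ids: np.ndarray             # (n,) int
    scores: np.ndarray = None        # (n,) float
    ids: np.ndarray = None           # (n,) int, unique

    def __post_init__(self):
        self.positions = np.atleast_2d(np.asarray(self.positions, float)).reshape(-1, 3)
        n = len(self.positions)
        self.eulers = np.atleast_2d(np.asarray(self.eulers, float)).reshape(-1, 3)
        self.tomo_ids = np.asarray(self.tomo_ids, int).reshape(-1)
        if self.scores is None:
            self.scores = np.zeros(n)
        self.scores = np.asarray(self.scores, float).reshape(-1)
        if self.ids is None:
            self.ids = np.arange(n)
        self.ids = np.asarray(self.ids, int).reshape(-1)
        if not (len(self.eulers) == len(self.tomo_ids) == len(self.scores) == len(self.ids) == n):
            raise ParticleTableError("field lengths disagree")
        if len(np.unique(self.ids)) != n:
            raise ParticleTableError("particle ids must be unique")
        if n and not np.all(np.isfinite(self.positions)):
            raise ParticleTableError("positions must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    @staticmethod
    def empty() -> "ParticleSet":
        return ParticleSet(
            positions=np.zeros((0, 3)), eulers=np.zeros((0, 3)),
            tomo_ids=np.zeros(0, int), scores=np.zeros(0), ids=np.zeros(0, int),
        )

    def subset(self, index) -> "ParticleSet":
        index = np.asarray(index)
        return ParticleSet(
            positions=self.positions[index], eulers=self.eulers[index],
            tomo_ids=self.tomo_ids[index], scores=self.scores[index], ids=self.ids[index],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "tomo_id": self.tomo_ids,
            "x_A": self.positions[:, 0], "y_A": self.positions[:, 1], "z_A": self.positions[:, 2],
            "eul1_deg": self.eulers[:, 0], "eul2_deg": self.eulers[:, 1],
            "eul3_deg": self.eulers[:, 2], "score": self.scores,
        })


def write_particles(path, particles: ParticleSet) -> None:
    with open(path, "w") as fh:
        fh.write("# units: angstrom\n")
        fh.write(f"# euler: {EULER_CONVENTION} intrinsic degrees, principal axis +z\n")
        particles.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_particles(path) -> ParticleSet:
    """Read a particle table; nm-unit files are converted to Angstrom (x10)."""
    unit_scale = 1.0
    body = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                meta = line[1:].strip().lower()
                if meta.startswith("units:"):
                    unit = meta.split(":", 1)[1].strip()
                    if unit in ("nm", "nanometre", "nanometer"):
                        unit_scale = 10.0
                    elif unit not in ("angstrom", "a", "å", "ang"):
                        raise ParticleTableError(f"unknown unit declaration '{unit}'")
            else:
                body.append(line)
    if not body:
        raise ParticleTableError("no header row found")
    frame = pd.read_csv(io.StringIO("".join(body)), sep="\t")
    required = [c for c in COLUMNS if c != "score"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ParticleTableError(f"missing column(s): {', '.join(missing)}")
    scores = frame["score"].to_numpy(float) if "score" in frame.columns else None
    return ParticleSet(
        positions=frame[["x_A", "y_A", "z_A"]].to_numpy(float) * unit_scale,
        eulers=frame[["eul1_deg", "eul2_deg", "eul3_deg"]].to_numpy(float),
        tomo_ids=frame["tomo_id"].to_numpy(int),
        scores=scores,
        ids=frame["id"].to_numpy(int),
    )
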