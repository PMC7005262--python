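"""Pipeline configuration: one flat, strictly-validated parameter block.

Round-trips losslessly through YAML; unknown keys are rejected so a typo in
a config file cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, asdict

import yaml


@dataclass
class PipelineConfig:
    # reproducibility / paths
    rng_seed: int = 1
    out_dir: str = "pipeline_out"
    write_volumes: bool = False

    # simulator
    n_tomograms: int = 6
    sphere_radius: float = 1500.0      # Angstrom
    cap_extent_deg: float = 35.0
    # ToD-axis spacing; CSU centres then sit sqrt(3) x this apart (120 A)
    tod_spacing: float = 69.282        # Angstrom
    jitter_sd: float = 2.0
    snr: float = 0.3
    max_tilt: float = 60.0             # degrees
    tilt_step: float = 2.0
    tilt_group: int = 5
    voxel_size: float = 4.5            # Angstrom (desk-scale default)
    random_inplane: bool = True
    membrane_weight: float = 1.0

    # seeding / picking
    seed_spacing: float = 30.0         # Angstrom
    box_A: float = 288.0               # subvolume side (desk-scale default)
    shift_limit: float = 60.0          # picking translational freedom
    initial_lowpass: float = 40.0

    # curation; the expected neighbour distance defaults to the lattice
    # constant sqrt(3) * tod_spacing when left as None (picked motifs sit on
    # honeycomb vertices, whose > 3-neighbour shell is the second one)
    dup_threshold: float = 10.0
    neighbor_expected: float | None = None
    neighbor_tol: float = 20.0
    min_neighbors: int = 3

    # refinement
    cone_half_angle: float = 60.0
    cone_stage1: float = 20.0
    cone_stage2: float = 8.0
    angular_step_stage1: float = 10.0
    angular_step_stage2: float = 4.0
    inplane_range_stage1: float = 180.0
    inplane_range_stage2: float = 10.0
    shift_limit_refine: float = 20.0
    max_iterations: int = 2
    search_bin: int = 2

    # validation
    fsc_threshold_a: float = 0.5
    fsc_threshold_b: float = 0.143
    localres_sampling: float = 20.0    # Angstrom
    localres_window: float = 100.0
    c2_cone_deg: float = 10.0
    c2_step_deg: float = 1.0

    def __post_init__(self):
        positive = ("sphere_radius", "tod_spacing", "snr", "voxel_size", "seed_spacing",
                    "box_A", "shift_limit", "dup_threshold",
                    "max_iterations", "n_tomograms")
        if self.neighbor_expected is not None and self.neighbor_expected <= 0:
            raise ValueError("neighbor_expected must be positive or None")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.fsc_threshold_b < self.fsc_threshold_a < 1):
            raise ValueError("FSC thresholds must satisfy 0 < b < a < 1")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {', '.join(sorted(unknown))}")
        return cls(**data)
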