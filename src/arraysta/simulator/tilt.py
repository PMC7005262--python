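"""Grouped dose-symmetric tilt schemes.

Acquisition order starts at 0 and walks outward in alternating side-groups:
0, +s..+g*s, then g negative angles, then g positive, and so on until both
sides reach the maximum tilt. For (60, 2, 5) this gives
0, +2..+10, -2..-10, +12..+20, -12..-20, ...
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TiltScheme:
    max_angle: float          # degrees
    step: float               # degrees
    group_size: int
    order: tuple              # signed degrees, acquisition order

    @property
    def angles(self) -> np.ndarray:
        """All sampled angles, ascending."""
        return np.sort(np.asarray(self.order, float))

    def __len__(self) -> int:
        return len(self.order)


FULL_SAMPLING = TiltScheme(max_angle=90.0, step=1.0, group_size=1,
                           order=tuple(range(-90, 91)))


def make_tilt_scheme(max_angle: float, step: float, group_size: int) -> TiltScheme:
    """Build the grouped dose-symmetric acquisition order.

    The first group is the zero tilt plus ``group_size`` positive angles;
    subsequent side-groups of ``group_size`` angles alternate sign with
    increasing magnitude. Every multiple of ``step`` in [-max, +max] appears
    exactly once.
    """
    if max_angle <= 0 or step <= 0:
        raise ValueError("max_angle and step must be positive")
    n_per_side = max_angle / step
    if abs(n_per_side - round(n_per_side)) > 1e-9:
        raise ValueError(f"step {step} does not divide max_angle {max_angle}")
    n_per_side = int(round(n_per_side))
    if group_size < 1:
        raise ValueError("group_size must be >= 1")
    if group_size > n_per_side:
        raise ValueError(
            f"group_size {group_size} exceeds the {n_per_side} angles available per side"
        )

    magnitudes = [step * k for k in range(1, n_per_side + 1)]
    groups = [magnitudes[i:i + group_size] for i in range(0, n_per_side, group_size)]
    order: list[float] = [0.0]
    order += [+a for a in groups[0]]
    pending_negative = groups[0]
    for grp in groups[1:]:
        order += [-a for a in pending_negative]
        order += [+a for a in grp]
        pending_negative = grp
    order += [-a for a in pending_negative]

    out = tuple(float(a) for a in order)
    assert len(out) == 2 * n_per_side + 1
    assert len(set(out)) == len(out)
    return TiltScheme(max_angle=float(max_angle), step=float(step),
                      group_size=int(group_size), order=out)
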