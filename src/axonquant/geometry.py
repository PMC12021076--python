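"""Coordinate frames for nerves and the optic chiasm.

All coordinates are physical micrometres. The convention throughout the
package is: crush plane at x = 0, regeneration toward +x, the nerve's
longitudinal axis is the +x unit vector. Image stacks are 0-based voxel
grids carrying metadata that maps voxel indices back to this frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = ["Region", "ChiasmLandmarks", "NerveGeometry"]


@dataclass(frozen=True)
class Region:
    """Axis-aligned box in the nerve frame (µm), used for chiasm fate regions."""

    xmin: float
    xmax: float
    ymin: float
    ymax: float
    zmin: float = -np.inf
    zmax: float = np.inf

    def contains(self, point) -> bool:
        x, y, z = np.asarray(point, dtype=float)[:3]
        return (
            self.xmin <= x <= self.xmax
            and self.ymin <= y <= self.ymax
            and self.zmin <= z <= self.zmax
        )

    def sample(self, rng: np.random.Generator, margin: float = 0.0) -> np.ndarray:
        """Uniform point inside the box, shrunk by `margin` on each side."""
        zmin = self.zmin if np.isfinite(self.zmin) else -10.0
        zmax = self.zmax if np.isfinite(self.zmax) else 10.0
        lo = np.array([self.xmin + margin, self.ymin + margin, zmin])
        hi = np.array([self.xmax - margin, self.ymax - margin, zmax])
        return rng.uniform(lo, hi)


@dataclass(frozen=True)
class ChiasmLandmarks:
    """Landmark planes and regions for chiasm fate classification.

    The injured optic nerve runs along +x at lateral offset ``nerve_y``;
    the OCTZ (optic nerve-chiasm transition zone) is the plane
    x = ``octz_x``; the brain midline is the plane y = ``midline_y``.
    Post-chiasmic fates are decided by which region contains an axon's
    terminal point: the ipsilateral optic tract, the contralateral optic
    tract (past the midline), or the contralateral (uninjured) optic nerve.
    """

    octz_x: float = 500.0
    midline_y: float = 0.0
    nerve_y: float = -100.0
    ipsi_tract: Region = field(
        default_factory=lambda: Region(700.0, 950.0, -250.0, -10.0)
    )
    contra_tract: Region = field(
        default_factory=lambda: Region(700.0, 950.0, 10.0, 250.0)
    )
    contra_nerve: Region = field(
        default_factory=lambda: Region(100.0, 480.0, 50.0, 150.0)
    )

    FATES = ("pre_chiasmic", "ipsi_tract", "contra_tract", "contra_nerve")

    def region_for(self, fate: str) -> Region:
        if fate == "ipsi_tract":
            return self.ipsi_tract
        if fate == "contra_tract":
            return self.contra_tract
        if fate == "contra_nerve":
            return self.contra_nerve
        raise KeyError(f"no region for fate {fate!r}")


@dataclass(frozen=True)
class NerveGeometry:
    """Coordinate frame of one nerve.

    Parameters
    ----------
    crush_position : (3,) µm
        A point on the crush plane. Regeneration distance of a point p is
        ``dot(p - crush_position, axis)``.
    axis : (3,) unit vector
        Longitudinal axis, pointing distal (away from the eye).
    nerve_length, nerve_radius : µm
        Extent of the modelled nerve segment distal to the crush.
    chiasm : optional chiasm landmarks for fate classification.
    """

    crush_position: tuple = (0.0, 0.0, 0.0)
    axis: tuple = (1.0, 0.0, 0.0)
    nerve_length: float = 2000.0
    nerve_radius: float = 150.0
    chiasm: Optional[ChiasmLandmarks] = None

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(ax)
        if not np.isfinite(n) or n == 0:
            raise ValueError("axis must be a nonzero finite vector")
        object.__setattr__(self, "axis", tuple(ax / n))
        object.__setattr__(
            self, "crush_position", tuple(np.asarray(self.crush_position, dtype=float))
        )
        if self.nerve_length <= 0 or self.nerve_radius <= 0:
            raise ValueError("nerve_length and nerve_radius must be positive")

    @property
    def axis_vector(self) -> np.ndarray:
        return np.asarray(self.axis, dtype=float)

    @property
    def crush(self) -> np.ndarray:
        return np.asarray(self.crush_position, dtype=float)

    def axial_distance(self, points) -> np.ndarray:
        """Signed distance of point(s) along the axis from the crush plane."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d = (pts - self.crush) @ self.axis_vector
        return d if d.size > 1 else float(d[0])

    def translated(self, offset) -> "NerveGeometry":
        off = np.asarray(offset, dtype=float)
        return NerveGeometry(
            crush_position=tuple(self.crush + off),
            axis=self.axis,
            nerve_length=self.nerve_length,
            nerve_radius=self.nerve_radius,
            chiasm=self.chiasm,
        )
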