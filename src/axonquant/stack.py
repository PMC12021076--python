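"""Image stack container with physical voxel metadata and TIFF I/O."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack"]


@dataclass
class ImageStack:
    """3D fluorescence volume, indexed ``data[z, y, x]``.

    ``pixel_size_xy`` and ``z_spacing`` are µm per voxel; ``origin`` is the
    µm position (x, y, z) of the centre of voxel (0, 0, 0) in the nerve
    frame, so stack and :class:`~axonquant.geometry.NerveGeometry` share one
    coordinate system.
    """

    data: np.ndarray
    pixel_size_xy: float
    z_spacing: float = 2.0
    origin: tuple = (0.0, 0.0, 0.0)
    channel: str = "CTB-Alexa-594"

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise ValueError("stack data must be 2D or 3D")
        if self.pixel_size_xy <= 0 or self.z_spacing <= 0:
            raise ValueError("voxel sizes must be positive")
        self.origin = tuple(float(v) for v in self.origin)

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_size(self) -> np.ndarray:
        """(z, y, x) voxel edge lengths in µm."""
        return np.array([self.z_spacing, self.pixel_size_xy, self.pixel_size_xy])

    def um_to_voxel(self, points_um) -> np.ndarray:
        """Map µm points (x, y, z) to fractional voxel indices (z, y, x)."""
        pts = np.atleast_2d(np.asarray(points_um, dtype=float))
        rel = pts - np.asarray(self.origin)
        vox = np.stack(
            [
                rel[:, 2] / self.z_spacing,
                rel[:, 1] / self.pixel_size_xy,
                rel[:, 0] / self.pixel_size_xy,
            ],
            axis=1,
        )
        return vox

    def voxel_to_um(self, indices_zyx) -> np.ndarray:
        """Map (z, y, x) voxel indices to µm points (x, y, z)."""
        idx = np.atleast_2d(np.asarray(indices_zyx, dtype=float))
        out = np.stack(
            [
                idx[:, 2] * self.pixel_size_xy + self.origin[0],
                idx[:, 1] * self.pixel_size_xy + self.origin[1],
                idx[:, 0] * self.z_spacing + self.origin[2],
            ],
            axis=1,
        )
        return out

    # -- persistence ------------------------------------------------------
    def save_tiff(self, path) -> None:
        meta = {
            "axes": "ZYX",
            "pixel_size_xy_um": self.pixel_size_xy,
            "z_spacing_um": self.z_spacing,
            "origin_um": list(self.origin),
            "channel": self.channel,
        }
        tifffile.imwrite(
            Path(path),
            self.data,
            metadata=meta,
            resolution=(1.0 / self.pixel_size_xy, 1.0 / self.pixel_size_xy),
        )

    @classmethod
    def load_tiff(cls, path) -> "ImageStack":
        with tifffile.TiffFile(Path(path)) as tf:
            data = tf.asarray()
            meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
        return cls(
            data=data,
            pixel_size_xy=float(meta.get("pixel_size_xy_um", 1.0)),
            z_spacing=float(meta.get("z_spacing_um", 2.0)),
            origin=tuple(meta.get("origin_um", (0.0, 0.0, 0.0))),
            channel=str(meta.get("channel", "")),
        )
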