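"""In-memory image container with physical geometry.

All volumes in this package carry their voxel spacing in millimetres and,
for dynamic (4-D) series, the frame interval in seconds.  Axis order is
(x, y, z[, t]); voxel indices are 0-based and world coordinates are
``index * spacing`` with the first voxel centre at the origin (identity /
RAS orientation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["ImageVolume"]


@dataclass
class ImageVolume:
    """N-D intensity array with anisotropic voxel spacing.

    Parameters
    ----------
    data : ndarray
        Intensity array, axis order (x, y, z[, t]).
    spacing : tuple of float
        Voxel spacing in mm for each *spatial* axis. Must be positive.
    frame_interval : float, optional
        Seconds between frames for a 4-D series.
    """

    data: np.ndarray
    spacing: tuple
    frame_interval: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacings must be > 0, got {self.spacing}")
        n_spatial = self.data.ndim - (1 if self.frame_interval is not None else 0)
        if len(self.spacing) != n_spatial:
            # allow 4-D arrays passed with 3 spacings and no frame interval
            if self.data.ndim == 4 and len(self.spacing) == 3:
                pass
            else:
                raise ValueError(
                    f"{len(self.spacing)} spacings for a {self.data.ndim}-D array"
                )
        if self.frame_interval is not None and self.frame_interval <= 0:
            raise ValueError("frame_interval must be > 0")

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def n_frames(self):
        if self.data.ndim < 4:
            return 1
        return self.data.shape[-1]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def frame_times(self) -> np.ndarray:
        """Acquisition time (s) of each frame of a 4-D series."""
        if self.frame_interval is None:
            raise ValueError("not a timed 4-D series")
        return np.arange(self.n_frames) * self.frame_interval

    def world_coordinates(self) -> tuple:
        """Per-axis world coordinates (mm) of voxel centres."""
        return tuple(
            np.arange(n) * s for n, s in zip(self.shape[: len(self.spacing)], self.spacing)
        )

    def copy(self, data: np.ndarray | None = None) -> "ImageVolume":
        return ImageVolume(
            data=self.data.copy() if data is None else np.asarray(data),
            spacing=self.spacing,
            frame_interval=self.frame_interval,
            meta=dict(self.meta),
        )

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path) -> None:
        """Write as NIfTI-1 with correct pixdim (and frame timing for 4-D)."""
        affine = np.diag(list(self.spacing) + [1.0] * (4 - len(self.spacing)))
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)
        zooms = list(self.spacing)
        if self.data.ndim == 4:
            zooms = zooms + [self.frame_interval or 1.0]
            img.header.set_xyzt_units("mm", "sec")
        img.header.set_zooms(zooms)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path, frame_interval: float | None = None) -> "ImageVolume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()
        data = np.asarray(img.dataobj)
        spacing = tuple(float(z) for z in zooms[:3])[: min(3, data.ndim)]
        if data.ndim == 4 and frame_interval is None and len(zooms) > 3 and zooms[3] > 0:
            frame_interval = float(zooms[3])
        return cls(data=data, spacing=spacing, frame_interval=frame_interval)
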