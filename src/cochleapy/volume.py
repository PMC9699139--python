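"""In-memory 3D image container shared by every pipeline stage.

All modules use one world-coordinate convention: physical millimetre
coordinates with axis order (x, y, z), 0-based voxel indices, and voxel
centers at ``index * spacing + origin``.  Arrays are indexed ``[ix, iy, iz]``
to match.  SimpleITK handles on-disk formats; conversion helpers below take
care of its (z, y, x) array layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk

#: Padding value marking voxels that carry no measured intensity
#: (out-of-bounds after cropping, declared invalid on ingest).
INVALID_HU = -2048.0


@dataclass
class Volume:
    """A 3D scalar volume with physical geometry.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values, indexed ``[ix, iy, iz]``.
    spacing : array-like of 3 floats
        Voxel spacing in mm along (x, y, z).
    origin : array-like of 3 floats
        World position (mm) of the center of voxel (0, 0, 0).
    metadata : dict
        Free-form header metadata (already PII-stripped on ingest).
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("Volume data must be 3D")
        if self.spacing.shape != (3,) or self.origin.shape != (3,):
            raise ValueError("spacing and origin must be length-3")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def index_to_world(self, idx) -> np.ndarray:
        """World coordinates (mm) of voxel center(s) ``idx`` (..., 3)."""
        return np.asarray(idx, dtype=float) * self.spacing + self.origin

    def world_to_index(self, point) -> np.ndarray:
        """Continuous voxel index of world point(s) (..., 3)."""
        return (np.asarray(point, dtype=float) - self.origin) / self.spacing

    def contains(self, point) -> bool:
        idx = self.world_to_index(point)
        return bool(np.all(idx >= -0.5) and np.all(idx <= np.array(self.shape) - 0.5))

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of all voxel centers, optionally masked.

        Returns an (N, 3) array; with ``mask`` only voxels where it is true.
        """
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.index_to_world(idx)

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing.copy(), self.origin.copy(),
                      dict(self.metadata))


def to_sitk(volume: Volume) -> sitk.Image:
    """Convert to a SimpleITK image (which stores arrays as [z, y, x])."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(volume.data, (2, 1, 0))))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    return img


def from_sitk(img: sitk.Image, metadata: dict | None = None) -> Volume:
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    return Volume(data, np.array(img.GetSpacing()), np.array(img.GetOrigin()),
                  metadata or {})
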