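"""3D scalar volumes in Hounsfield units with physical geometry.

A :class:`VolumeImage` is the unit every perturbation and extraction step
operates on: a dense ``(nx, ny, nz)`` grid of HU values plus voxel spacing
and origin in millimetres.  Axis order is (x, y, z); NIfTI I/O goes through
nibabel with an RAS affine built from spacing and origin.
"""

from __future__ import annotations

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage"]


class VolumeImage:
    """A 3D HU grid with voxel spacing and origin (both mm).

    The origin is the physical coordinate of the centre of voxel
    ``(0, 0, 0)``.  Spacing components must be positive and the grid
    non-empty.
    """

    def __init__(self, values, spacing, origin=(0.0, 0.0, 0.0)):
        values = np.asarray(values)
        if values.ndim != 3 or values.size == 0:
            raise ValueError("values must be a non-empty 3D array")
        spacing = tuple(float(s) for s in spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"spacing components must be positive, got {spacing}")
        self.values = values
        self.spacing = spacing
        self.origin = tuple(float(o) for o in origin)

    def __repr__(self):  # pragma: no cover
        return (f"VolumeImage(shape={self.shape}, spacing={self.spacing}, "
                f"origin={self.origin})")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def physical_extent(self) -> tuple[float, float, float]:
        """Edge-to-edge physical size of the grid in mm."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical coordinates of voxel centres along one axis."""
        return self.origin[axis] + self.spacing[axis] * np.arange(self.shape[axis])

    # ------------------------------------------------------------------ I/O

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing) + [1.0])
        aff[:3, 3] = self.origin
        return aff

    def to_nifti(self, path) -> None:
        """Write as NIfTI-1 (RAS orientation, spacing in the header)."""
        img = nib.Nifti1Image(np.asanyarray(self.values), self.affine())
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "VolumeImage":
        img = nib.load(str(path))
        aff = img.affine
        spacing = tuple(float(np.linalg.norm(aff[:3, i])) for i in range(3))
        origin = tuple(float(v) for v in aff[:3, 3])
        return cls(np.asanyarray(img.dataobj), spacing, origin)
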