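"""Fixed-bin-width gray-level discretization.

The level of a voxel with value x is ``floor((x - min) / bin_width) + 1``,
so the minimum always maps to level 1 and the number of gray levels Ng is
the maximum assigned level.  Bin edges move with the ROI minimum, which
makes all discretized-texture features invariant to adding a constant to
the HU values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["discretize", "DiscretizedRoi", "discretize_roi"]


def discretize(values, bin_width: float) -> np.ndarray:
    """Map raw values to integer gray levels 1..Ng (fixed bin width)."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        raise ValueError("cannot discretize an empty ROI")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    levels = np.floor((values - values.min()) / bin_width).astype(np.int64) + 1
    return levels


@dataclass
class DiscretizedRoi:
    """Discretized ROI on a 3D grid.

    ``levels`` is a dense int array over the ROI bounding box with 0
    marking voxels outside the ROI and 1..Ng inside.
    """

    levels: np.ndarray
    ng: int
    spacing: tuple[float, float, float]

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.levels))


def discretize_roi(values3d: np.ndarray, mask: np.ndarray, bin_width: float,
                   spacing=(1.0, 1.0, 1.0)) -> DiscretizedRoi:
    """Discretize a masked sub-volume, cropping to the mask bounding box."""
    mask = np.asarray(mask, bool)
    if mask.shape != values3d.shape:
        raise ValueError("mask and values must share a shape")
    if not mask.any():
        raise ValueError("empty ROI mask")
    ii, jj, kk = np.nonzero(mask)
    sl = tuple(slice(int(a.min()), int(a.max()) + 1) for a in (ii, jj, kk))
    sub_vals = np.asarray(values3d[sl], dtype=np.float64)
    sub_mask = mask[sl]
    levels = np.zeros(sub_mask.shape, dtype=np.int64)
    levels[sub_mask] = discretize(sub_vals[sub_mask], bin_width)
    return DiscretizedRoi(levels=levels, ng=int(levels.max()),
                          spacing=tuple(float(s) for s in spacing))
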