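"""Whole-ROI feature extraction: settings, the 93-name schema and the
feature-vector container."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass

import numpy as np

from ..volume import VolumeImage
from .discretize import discretize_roi
from .families import (GLCM_NAMES, GLDM_NAMES, GLRLM_NAMES, GLSZM_NAMES,
                       NGTDM_NAMES, glcm_features, gldm_features,
                       glrlm_features, glszm_features, ngtdm_features)
from .firstorder import FIRSTORDER_NAMES, first_order_features

__all__ = ["ExtractionSettings", "FeatureVector", "FEATURE_NAMES",
           "FAMILY_SIZES", "extract_feature_vector"]

FAMILY_SIZES = {"firstorder": 18, "glcm": 24, "glrlm": 16, "glszm": 16,
                "gldm": 14, "ngtdm": 5}

#: Fixed column order of the 93 features: family prefix + reference name.
FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"firstorder_{n}" for n in FIRSTORDER_NAMES]
    + [f"glcm_{n}" for n in GLCM_NAMES]
    + [f"glrlm_{n}" for n in GLRLM_NAMES]
    + [f"glszm_{n}" for n in GLSZM_NAMES]
    + [f"gldm_{n}" for n in GLDM_NAMES]
    + [f"ngtdm_{n}" for n in NGTDM_NAMES]
)
assert len(FEATURE_NAMES) == 93


@dataclass(frozen=True)
class ExtractionSettings:
    """Extraction parameters.

    No pre-processing (resampling, normalization, filtering) is applied
    before extraction; the fixed bin width is the only discretization
    control, and texture matrices are computed in 3D with direction
    averaging by default.
    """

    bin_width: float = 25.0          # HU
    glcm_distance: int = 1           # voxels
    gldm_alpha: int = 0              # gray levels
    gldm_distance: int = 1           # voxels
    ngtdm_distance: int = 1          # voxels
    aggregation: str = "average_over_directions"
    dimensionality: str = "threeD"   # threeD | twoD_per_slice

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("bin_width must be > 0")
        if min(self.glcm_distance, self.gldm_distance,
               self.ngtdm_distance) < 1:
            raise ValueError("distances must be >= 1")
        if self.dimensionality not in ("threeD", "twoD_per_slice"):
            raise ValueError(f"unknown dimensionality {self.dimensionality!r}")

    @property
    def three_d(self) -> bool:
        return self.dimensionality == "threeD"

    def settings_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class FeatureVector:
    """93 named feature values with family tags and degeneracy flags."""

    def __init__(self, values: dict, degenerate: set):
        missing = set(FEATURE_NAMES) - set(values)
        extra = set(values) - set(FEATURE_NAMES)
        if missing or extra:
            raise ValueError(f"feature schema mismatch: missing={missing}, "
                             f"extra={extra}")
        self._values = {name: float(values[name]) for name in FEATURE_NAMES}
        self.degenerate = frozenset(degenerate)

    def __getitem__(self, name: str) -> float:
        return self._values[name]

    def __len__(self) -> int:
        return len(self._values)

    def __iter__(self):
        return iter(FEATURE_NAMES)

    def __eq__(self, other):
        return (isinstance(other, FeatureVector)
                and self._values == other._values)

    @staticmethod
    def family_of(name: str) -> str:
        return name.split("_", 1)[0]

    def as_dict(self) -> dict:
        return dict(self._values)

    def as_array(self) -> np.ndarray:
        return np.array([self._values[n] for n in FEATURE_NAMES])

    def is_degenerate(self, name: str) -> bool:
        return name in self.degenerate


def extract_feature_vector(image: VolumeImage, mask: np.ndarray,
                           settings: ExtractionSettings | None = None
                           ) -> FeatureVector:
    """Extract the 93-feature vector from one ROI of an image.

    ``mask`` is a boolean array on the image grid.  The raw HU values feed
    the first-order features; the texture families operate on the
    fixed-bin-width discretized ROI.  No resampling, normalization or
    filtering is applied, and no shape features are computed (the ROI
    geometry is fixed by design).  Deterministic.
    """
    settings = settings or ExtractionSettings()
    mask = np.asarray(mask, bool)
    if mask.shape != image.shape:
        raise ValueError("mask shape does not match the image grid")
    if not mask.any():
        raise ValueError("empty ROI mask")

    raw = np.asarray(image.values)[mask]
    droi = discretize_roi(np.asarray(image.values), mask, settings.bin_width,
                          spacing=image.spacing)
    three_d = settings.three_d

    values: dict[str, float] = {}
    degenerate: set[str] = set()

    fo, fo_deg = first_order_features(raw, voxel_volume=image.voxel_volume(),
                                      bin_width=settings.bin_width)
    values.update({f"firstorder_{k}": v for k, v in fo.items()})
    degenerate |= {f"firstorder_{k}" for k in fo_deg}

    for prefix, (feats, deg) in (
        ("glcm", glcm_features(droi, distance=settings.glcm_distance,
                               three_d=three_d)),
        ("glrlm", glrlm_features(droi, three_d=three_d)),
        ("glszm", glszm_features(droi, three_d=three_d)),
        ("gldm", gldm_features(droi, alpha=settings.gldm_alpha,
                               distance=settings.gldm_distance,
                               three_d=three_d)),
        ("ngtdm", ngtdm_features(droi, distance=settings.ngtdm_distance,
                                 three_d=three_d)),
    ):
        values.update({f"{prefix}_{k}": v for k, v in feats.items()})
        degenerate |= {f"{prefix}_{k}" for k in deg}

    return FeatureVector(values, degenerate)
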