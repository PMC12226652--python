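"""Acquisition/reconstruction protocol definitions and surrogate parameters.

Thirteen protocols form the study matrix: a reference abdomen-pelvis
protocol plus twelve variants that each change one influencing factor
(reposition, high-pitch scan mode, tube voltage, slice thickness, four
radiation dose levels, two iterative-reconstruction strengths, two
reconstruction kernels).  The scanner chain itself is replaced downstream
by declared image-domain surrogates (blur / correlated noise / denoising /
contrast scaling); this module only declares the factor values and the
surrogate parameter tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "ProtocolSpec",
    "RigidTransform",
    "SurrogateParams",
    "default_protocol_suite",
    "reference_protocol",
    "PROTOCOL_IDS",
]

KERNELS = ("Qr40", "Qr44", "Qr48")

PROTOCOL_IDS = (
    "reference", "reposition", "high_pitch", "kvp140", "slice04",
    "dose05", "dose10", "dose30", "dose50", "qir0", "qir2", "qr44", "qr48",
)


@dataclass(frozen=True)
class RigidTransform:
    """In-plane-dominant rigid motion: translation (mm) and z-rotation (deg)."""

    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    rotation_z: float = 0.0

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @property
    def is_identity(self) -> bool:
        return self.rotation_z == 0.0 and all(t == 0.0 for t in self.translation)

    def apply(self, points):
        """Map physical points (..., 3) phantom -> scanner frame."""
        import numpy as np
        pts = np.asarray(points, float)
        th = math.radians(self.rotation_z)
        c, s = math.cos(th), math.sin(th)
        out = pts.copy()
        out[..., 0] = c * pts[..., 0] - s * pts[..., 1]
        out[..., 1] = s * pts[..., 0] + c * pts[..., 1]
        out += np.asarray(self.translation, float)
        return out

    def inverse(self) -> "RigidTransform":
        import numpy as np
        th = math.radians(-self.rotation_z)
        c, s = math.cos(th), math.sin(th)
        tx, ty, tz = self.translation
        return RigidTransform(
            translation=(-(c * tx - s * ty), -(s * tx + c * ty), -tz),
            rotation_z=-self.rotation_z,
        )


# Default reposition motion between the reference and reposition scans.
DEFAULT_REPOSITION = RigidTransform(translation=(3.0, -2.0, 1.0), rotation_z=2.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """One row of the acquisition/reconstruction factor matrix."""

    id: str
    scan_mode: str = "standard"          # standard | high_pitch
    kvp: float = 120.0
    mas: float = 127.0
    slice_thickness: float = 1.0         # mm (increment equals thickness)
    matrix: int = 512
    fov: float = 400.0                   # mm
    rotation_time: float = 0.5           # s
    pitch: float = 0.8
    ctdivol: float = 10.00               # mGy
    qir_level: int = 4                   # 0..4
    kernel: str = "Qr40"

    def __post_init__(self):
        if self.ctdivol <= 0:
            raise ValueError("ctdivol must be > 0")
        if self.slice_thickness <= 0:
            raise ValueError("slice_thickness must be > 0")
        if self.scan_mode not in ("standard", "high_pitch"):
            raise ValueError(f"unknown scan mode {self.scan_mode!r}")
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if not 0 <= self.qir_level <= 4:
            raise ValueError("qir_level must be in 0..4")

    @property
    def pixel_spacing(self) -> float:
        """In-plane pixel pitch, mm (= fov / matrix)."""
        return self.fov / self.matrix


@dataclass(frozen=True)
class SurrogateParams:
    """Parameters of the image-domain scanner surrogates.

    ``sigma_ref`` is the pre-denoising noise SD (HU) at the reference dose
    (10 mGy) and slice thickness (1 mm) with the Qr40 kernel; the noise law
    scales it by sqrt(ctdi_ref/ctdi), sqrt(thickness_ref/thickness), a
    scan-mode multiplier, the kernel noise amplification and the
    iterative-reconstruction (QIR) reduction factor.
    """

    sigma_ref: float = 10.0
    ctdi_ref: float = 10.0
    thickness_ref: float = 1.0
    pitch_noise: dict = field(default_factory=lambda: {
        "standard": 1.0, "high_pitch": 1.15})
    kernel_fwhm_px: dict = field(default_factory=lambda: {
        "Qr40": 1.2, "Qr44": 0.9, "Qr48": 0.7})
    kernel_noise_amp: dict = field(default_factory=lambda: {
        "Qr40": 1.0, "Qr44": 1.35, "Qr48": 1.8})
    qir_noise_factor: dict = field(default_factory=lambda: {
        0: 1.0, 1: 0.85, 2: 0.7, 3: 0.55, 4: 0.45})
    # correlation of the noise field before denoising, px (sigma of the
    # Gaussian used to correlate white noise); QIR adds further smoothing.
    noise_corr_px: float = 0.6
    qir_extra_corr_px: dict = field(default_factory=lambda: {
        0: 0.0, 1: 0.15, 2: 0.3, 3: 0.45, 4: 0.6})

    def noise_sd(self, protocol: ProtocolSpec) -> float:
        """Target noise SD (HU) of the final image for a protocol."""
        return (self.sigma_ref
                * math.sqrt(self.ctdi_ref / protocol.ctdivol)
                * math.sqrt(self.thickness_ref / protocol.slice_thickness)
                * self.pitch_noise[protocol.scan_mode]
                * self.kernel_noise_amp[protocol.kernel]
                * self.qir_noise_factor[protocol.qir_level])


def reference_protocol(matrix: int = 512, fov: float = 400.0) -> ProtocolSpec:
    return ProtocolSpec(id="reference", matrix=matrix, fov=fov)


def default_protocol_suite(matrix: int = 512,
                           fov: float = 400.0) -> list[ProtocolSpec]:
    """The 13-protocol study matrix.

    With default arguments this reproduces the full-scale factor table
    (512 matrix, 400 mm FOV standard / 350 mm high-pitch).  ``matrix`` and
    ``fov`` may be scaled jointly for compact studies; the high-pitch FOV
    keeps the 350/400 ratio so pixel pitches are preserved.
    """
    ref = reference_protocol(matrix=matrix, fov=fov)
    hp_fov = fov * 350.0 / 400.0
    return [
        ref,
        replace(ref, id="reposition"),
        replace(ref, id="high_pitch", scan_mode="high_pitch", fov=hp_fov,
                rotation_time=0.25, pitch=3.2),
        replace(ref, id="kvp140", kvp=140.0, mas=87.0),
        replace(ref, id="slice04", slice_thickness=0.4),
        replace(ref, id="dose05", mas=6.0, ctdivol=0.47),
        replace(ref, id="dose10", mas=13.0, ctdivol=1.03),
        replace(ref, id="dose30", mas=38.0, ctdivol=3.00),
        replace(ref, id="dose50", mas=63.0, ctdivol=4.98),
        replace(ref, id="qir0", qir_level=0),
        replace(ref, id="qir2", qir_level=2),
        replace(ref, id="qr44", kernel="Qr44"),
        replace(ref, id="qr48", kernel="Qr48"),
    ]
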