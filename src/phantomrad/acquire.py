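"""Image-domain acquisition surrogate and ROI construction.

The scanner/reconstruction chain (spectral detection, virtual
monochromatic synthesis, iterative denoising, reconstruction kernels) is
replaced by phenomenological image-domain operations applied to the fine
ground truth, in order:

1. rigid repositioning (identity for all protocols except reposition);
2. per-material contrast scaling when imaging at 140 kVp;
3. resampling to the protocol grid (in-plane pitch fov/matrix, axial
   pitch = slice thickness) by local averaging + trilinear interpolation;
4. reconstruction-kernel PSF: in-plane Gaussian blur with a
   kernel-specific FWHM;
5. correlated Gaussian noise whose SD follows the quantum-noise law
   sigma_ref * sqrt(ctdi_ref/ctdi) * sqrt(t_ref/t) * pitch multiplier,
   amplified by the kernel and reduced by the QIR strength factor.

The analysis downstream depends only on the resulting image statistics,
and these surrogates make every influencing factor independently
controllable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import PhantomLayout
from .protocols import ProtocolSpec, RigidTransform, SurrogateParams
from .volume import VolumeImage

__all__ = [
    "ResolutionError",
    "GeometryError",
    "RoiSet",
    "protocol_grid",
    "simulate_acquisition",
    "build_rois",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class ResolutionError(ValueError):
    """Protocol grid is finer than the available ground-truth grid."""


class GeometryError(ValueError):
    """ROI or grid geometry is inconsistent (e.g. ROI outside the grid)."""


def protocol_grid(protocol: ProtocolSpec,
                  extent: tuple[float, float, float]):
    """Grid (shape, spacing, origin) of a protocol over a physical extent.

    In-plane the grid has pitch ``fov/matrix`` and at most ``matrix``
    pixels (fewer when the extent is smaller than the FOV); axially the
    pitch is the slice thickness.  The grid is centred on the isocentre.
    """
    psp = protocol.pixel_spacing
    spacing = (psp, psp, protocol.slice_thickness)
    shape = (
        min(protocol.matrix, int(extent[0] / psp + 1e-6)),
        min(protocol.matrix, int(extent[1] / psp + 1e-6)),
        int(extent[2] / protocol.slice_thickness + 1e-6),
    )
    if any(n <= 0 for n in shape):
        raise GeometryError("physical extent too small for the protocol grid")
    origin = tuple(-(n - 1) / 2 * s for n, s in zip(shape, spacing))
    return shape, spacing, origin


def _contrast_scaled(truth: VolumeImage, labels: VolumeImage,
                     layout: PhantomLayout) -> np.ndarray:
    lut = np.ones(int(labels.values.max()) + 1, dtype=np.float32)
    for m in layout.materials:
        if m.label < lut.size:
            lut[m.label] = m.kvp_contrast_factor
    return truth.values * lut[labels.values]


def simulate_acquisition(truth: VolumeImage,
                         protocol: ProtocolSpec,
                         transform: RigidTransform = RigidTransform(),
                         seed: int = 0,
                         params: SurrogateParams | None = None,
                         labels: VolumeImage | None = None,
                         layout: PhantomLayout | None = None) -> VolumeImage:
    """Simulate one protocol's image from the ground truth.

    ``labels`` and ``layout`` are required when ``protocol.kvp != 120``
    (they supply the per-material contrast factors).  The output is a pure
    function of ``(truth, protocol, transform, seed, params)``.
    """
    params = params or SurrogateParams()
    if (protocol.pixel_spacing < truth.spacing[0] - 1e-9
            or protocol.pixel_spacing < truth.spacing[1] - 1e-9
            or protocol.slice_thickness < truth.spacing[2] - 1e-9):
        raise ResolutionError(
            f"protocol grid ({protocol.pixel_spacing:.3f}/"
            f"{protocol.slice_thickness:.3f} mm) is finer than the truth grid "
            f"{truth.spacing}")

    # (2) tube-voltage contrast surrogate (on the fine grid, phantom frame)
    if protocol.kvp != 120.0:
        if labels is None or layout is None:
            raise ValueError("labels and layout are required for kvp != 120")
        values = _contrast_scaled(truth, labels, layout)
    else:
        values = truth.values
    values = np.ascontiguousarray(values, dtype=np.float32)

    # (3a) local averaging: anti-alias blur matched to the coarser grid
    out_shape, out_spacing, out_origin = protocol_grid(
        protocol, truth.physical_extent())
    sigma_vox = []
    for ax in range(3):
        ratio = out_spacing[ax] / truth.spacing[ax]
        sigma_vox.append(0.42 * ratio if ratio > 1.001 else 0.0)
    if any(s > 0 for s in sigma_vox):
        values = ndimage.gaussian_filter(values, sigma=sigma_vox, mode="nearest")

    # (1)+(3b) rigid transform folded into trilinear sampling: output voxel
    # centres (scanner frame) are pulled back to the phantom frame.
    inv = transform.inverse()
    axes = [out_origin[ax] + out_spacing[ax] * np.arange(out_shape[ax],
                                                         dtype=np.float64)
            for ax in range(3)]
    px, py, pz = np.meshgrid(*axes, indexing="ij", copy=False)
    pts = np.stack([px, py, pz], axis=-1)
    q = inv.apply(pts) if not transform.is_identity else pts
    coords = np.empty((3,) + out_shape, dtype=np.float32)
    for ax in range(3):
        coords[ax] = (q[..., ax] - truth.origin[ax]) / truth.spacing[ax]
    del pts, q, px, py, pz
    out = ndimage.map_coordinates(values, coords, order=1, mode="nearest",
                                  output=np.float32)

    # (4) reconstruction-kernel PSF (in-plane)
    fwhm = params.kernel_fwhm_px[protocol.kernel]
    out = ndimage.gaussian_filter(
        out, sigma=(fwhm * _FWHM_TO_SIGMA, fwhm * _FWHM_TO_SIGMA, 0.0),
        mode="nearest")

    # (5)+(6) correlated noise at the protocol's target SD; the QIR
    # denoising surrogate smooths the noise field further and rescales it
    # so the final SD equals the declared noise law exactly.
    sd_target = params.noise_sd(protocol)
    if sd_target > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(out_shape).astype(np.float32)
        corr = np.hypot(params.noise_corr_px,
                        params.qir_extra_corr_px[protocol.qir_level])
        if corr > 0:
            noise = ndimage.gaussian_filter(noise, sigma=(corr, corr, 0.0),
                                            mode="wrap")
        noise *= sd_target / max(float(noise.std()), 1e-12)
        out += noise

    return VolumeImage(out, out_spacing, out_origin)


@dataclass
class RoiSet:
    """Cylindrical per-material ROIs on one protocol's grid.

    Stored as a single label volume (0 = outside any ROI); the per-material
    masks are disjoint by construction.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    diameter_px: int
    n_layers: int
    centers_vox: dict
    protocol_id: str = ""

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    @property
    def material_labels(self) -> list[int]:
        return sorted(self.centers_vox)

    def to_volume(self) -> VolumeImage:
        return VolumeImage(self.labels, self.spacing, self.origin)


def build_rois(protocol: ProtocolSpec,
               layout: PhantomLayout,
               transform: RigidTransform = RigidTransform(),
               diameter_px: int = 35,
               n_layers: int = 25,
               snap_grid: ProtocolSpec | None = None) -> RoiSet:
    """Place one cylindrical ROI per insert on a protocol's grid.

    The ROI diameter is defined in pixels, so its physical size follows
    the protocol's pixel pitch (it shrinks on the reduced high-pitch FOV).
    Each ROI centre is the insert centre snapped to the placement grid
    (``snap_grid``, default the protocol itself — emulating manual pixel-
    aligned placement on the reference scan) and then carried through the
    rigid ``transform`` into the scanner frame, so ROIs track a
    repositioned phantom exactly.  The disk is replicated over ``n_layers``
    slices centred on the insert's axial position.
    """
    if diameter_px < 3 or diameter_px % 2 == 0:
        raise ValueError("diameter_px must be odd and >= 3")
    if n_layers < 1:
        raise ValueError("n_layers must be >= 1")

    extent = (layout.fov, layout.fov, layout.slab_mm)
    shape, spacing, origin = protocol_grid(protocol, extent)
    if n_layers > shape[2]:
        raise GeometryError(
            f"n_layers={n_layers} exceeds the protocol slab of {shape[2]} slices")

    snap = snap_grid or protocol
    s_shape, s_spacing, s_origin = protocol_grid(snap, extent)

    labels = np.zeros(shape, dtype=np.uint8)
    centers_vox: dict[int, tuple[float, float, float]] = {}
    r = (diameter_px - 1) / 2.0
    insert_r = layout.insert_diameter / 2.0
    ix = np.arange(shape[0], dtype=np.float64)
    iy = np.arange(shape[1], dtype=np.float64)

    for spec, (cx, cy) in zip(layout.materials, layout.insert_centers):
        # snap the placement to the placement grid's pixel lattice
        sx = s_origin[0] + s_spacing[0] * round((cx - s_origin[0]) / s_spacing[0])
        sy = s_origin[1] + s_spacing[1] * round((cy - s_origin[1]) / s_spacing[1])
        center_phys = np.array([sx, sy, 0.0])
        c = transform.apply(center_phys)
        cvx = (c[0] - origin[0]) / spacing[0]
        cvy = (c[1] - origin[1]) / spacing[1]
        cvz = (c[2] - origin[2]) / spacing[2]
        if not (0 <= cvx < shape[0] and 0 <= cvy < shape[1]
                and 0 <= cvz < shape[2]):
            raise GeometryError(f"ROI centre for material {spec.label} is "
                                f"outside the protocol grid")
        disk = ((ix[:, None] - cvx) ** 2 + (iy[None, :] - cvy) ** 2
                <= r * r + 1e-9)
        z0 = int(round(cvz - (n_layers - 1) / 2.0))
        z1 = z0 + n_layers
        if z0 < 0 or z1 > shape[2]:
            raise GeometryError(f"ROI for material {spec.label} exceeds the "
                                f"axial grid extent")
        region = labels[:, :, z0:z1]
        if np.any(region[disk, :]):
            raise GeometryError("ROI masks overlap; inserts too close for "
                                "the requested diameter")
        region[disk, :] = spec.label
        centers_vox[spec.label] = (cvx, cvy, cvz)

        # warn when the ROI spills out of its insert (physical check via
        # the inverse transform back to the phantom frame)
        ii, jj = np.nonzero(disk)
        pts = np.stack([origin[0] + spacing[0] * ii,
                        origin[1] + spacing[1] * jj], axis=-1)
        pts3 = np.concatenate([pts, np.zeros((len(pts), 1))], axis=1)
        back = transform.inverse().apply(pts3)
        inside = ((back[:, 0] - cx) ** 2 + (back[:, 1] - cy) ** 2
                  <= insert_r ** 2 + 1e-9)
        frac = float(inside.mean()) if len(inside) else 0.0
        if frac < 1.0 - 1e-9:
            warnings.warn(
                f"ROI for material {spec.label} ({spec.name}) exceeds its "
                f"insert: overlap fraction {frac:.3f}", stacklevel=2)

    return RoiSet(labels=labels, spacing=spacing, origin=origin,
                  diameter_px=diameter_px, n_layers=n_layers,
                  centers_vox=centers_vox, protocol_id=protocol.id)
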