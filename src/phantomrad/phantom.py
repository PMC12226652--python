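"""Synthetic texture phantom: materials, layout and ground-truth generation.

The physical phantom being emulated is a foam box holding 28 inserts (wood
blocks and bottles filled with granular or porous household materials, plus
water) that differ in mean attenuation and spatial texture.  Here each
insert is a cylinder filled with a stationary Gaussian-random-field texture
whose mean (HU), marginal SD (HU) and correlation length (mm) are declared
per material; the texture family selects a qualitative post-transform
(granular = isotropic field, fibrous = anisotropic/elongated, porous =
saturated/blobby, homogeneous = white or constant).

The ground truth lives on a fine isotropic grid (default 0.25 mm) and is
generated once per study seed; every simulated protocol resamples from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import VolumeImage

__all__ = [
    "MaterialSpec",
    "PhantomLayout",
    "build_default_layout",
    "material_texture",
    "generate_ground_truth",
]

TEXTURE_FAMILIES = ("homogeneous", "granular", "fibrous", "porous")


@dataclass(frozen=True)
class MaterialSpec:
    """One insert material.

    Parameters
    ----------
    label : int
        Unique integer label, 1..28 in the default layout.
    name : str
        Material name (e.g. ``"water"``, ``"rice"``).
    texture_family : str
        One of ``homogeneous``, ``granular``, ``fibrous``, ``porous``.
    mean_hu : float
        Mean attenuation at the reference tube voltage, HU.
    texture_sd : float
        Marginal SD of the texture, HU (0 = perfectly uniform).
    correlation_length : float
        Gaussian kernel scale of the spatial autocorrelation, mm.
        Ignored for the homogeneous family.
    kvp_contrast_factor : float
        Multiplier applied to the material's HU values when imaging at
        140 kVp instead of 120 kVp (near 1; 70 keV virtual monochromatic
        images are nearly kVp-invariant).
    """

    label: int
    name: str
    texture_family: str
    mean_hu: float
    texture_sd: float
    correlation_length: float = 1.0
    kvp_contrast_factor: float = 1.0

    def __post_init__(self):
        if self.texture_family not in TEXTURE_FAMILIES:
            raise ValueError(f"unknown texture family {self.texture_family!r}")
        if self.texture_sd < 0:
            raise ValueError("texture_sd must be >= 0")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")


# Declared default material table.  Names follow the insert list of the
# physical phantom; attenuation and texture parameters are package defaults
# chosen to span the plausible HU range of these materials (air-filled
# sponges near -850 HU up to salts and sand near +1000 HU) with distinct
# texture scales.  All values are configurable through the layout.
_DEFAULT_MATERIALS: tuple[tuple[int, str, str, float, float, float], ...] = (
    (1, "cat litter", "granular", 450.0, 120.0, 1.5),
    (2, "coix seed", "granular", -150.0, 90.0, 3.0),
    (3, "rice", "granular", -250.0, 80.0, 1.8),
    (4, "iodize free salt", "granular", 900.0, 60.0, 1.2),
    (5, "buckwheat", "granular", -300.0, 85.0, 2.2),
    (6, "flour", "granular", -350.0, 25.0, 0.8),
    (7, "soybean", "granular", -120.0, 100.0, 3.5),
    (8, "quinoa", "granular", -280.0, 70.0, 1.2),
    (9, "rosewood", "fibrous", 550.0, 90.0, 2.5),
    (10, "chicken wing wood", "fibrous", 400.0, 80.0, 2.0),
    (11, "beechwood", "fibrous", 250.0, 60.0, 2.2),
    (12, "zebra wood", "fibrous", 480.0, 110.0, 3.0),
    (13, "basswood", "fibrous", -150.0, 50.0, 2.0),
    (14, "mung bean", "granular", -100.0, 95.0, 2.8),
    (15, "mesoporous sponge", "porous", -700.0, 60.0, 1.5),
    (16, "millet", "granular", -220.0, 75.0, 1.5),
    (17, "microporous sponge", "porous", -850.0, 30.0, 0.8),
    (18, "red bean", "granular", -80.0, 100.0, 3.2),
    (19, "sand", "granular", 1100.0, 90.0, 1.0),
    (20, "nutritive soil", "porous", -400.0, 130.0, 2.0),
    (21, "granulated sugar", "granular", -500.0, 45.0, 1.0),
    (22, "water", "homogeneous", 0.0, 0.0, 1.0),
    (23, "iodized salt", "granular", 950.0, 65.0, 1.2),
    (24, "sago", "granular", -200.0, 80.0, 2.5),
    (25, "chia seed", "granular", -180.0, 85.0, 1.4),
    (26, "oat", "granular", -320.0, 75.0, 2.5),
    (27, "coarse-pore sponge", "porous", -600.0, 110.0, 3.0),
    (28, "sawdust", "porous", -450.0, 70.0, 1.2),
)

# Ring layout (radius fraction of a 400 mm FOV, insert count); 1+8+9+10 = 28.
_RING_PLAN = ((0.0, 1), (55.0, 8), (105.0, 9), (155.0, 10))


class LayoutError(ValueError):
    """Invalid phantom geometry (overlapping or out-of-FOV inserts)."""


@dataclass(frozen=True)
class PhantomLayout:
    """Geometric arrangement of the insert materials inside the FOV.

    ``insert_centers`` are (x, y) mm relative to isocentre; every insert is
    a cylinder of ``insert_diameter`` mm spanning the full ``slab_mm`` axial
    extent.  ``fine_spacing`` is the isotropic ground-truth grid pitch.
    """

    materials: tuple[MaterialSpec, ...]
    insert_centers: tuple[tuple[float, float], ...]
    insert_diameter: float
    fov: float = 400.0
    fine_spacing: float = 0.25
    slab_mm: float = 32.0
    background_hu: float = -800.0

    def __post_init__(self):
        if len(self.materials) != len(self.insert_centers):
            raise LayoutError("insert count must equal material count")
        labels = [m.label for m in self.materials]
        if len(set(labels)) != len(labels):
            raise LayoutError("material labels must be unique")
        centers = np.asarray(self.insert_centers, float)
        # pairwise non-overlap
        for i in range(len(centers)):
            for j in range(i + 1, len(centers)):
                if np.linalg.norm(centers[i] - centers[j]) < self.insert_diameter:
                    raise LayoutError(
                        f"inserts {labels[i]} and {labels[j]} overlap")
        radii = np.linalg.norm(centers, axis=1)
        if np.any(radii + self.insert_diameter / 2 > self.fov / 2):
            raise LayoutError("an insert extends outside the FOV circle")

    @property
    def n_materials(self) -> int:
        return len(self.materials)

    def material_by_label(self, label: int) -> MaterialSpec:
        for m in self.materials:
            if m.label == label:
                return m
        raise KeyError(label)


def _default_kvp_factor(label: int, amplitude: float = 0.03) -> float:
    # deterministic per-material contrast shift in [1-amp, 1+amp]
    return 1.0 + amplitude * math.sin(float(label))


def build_default_layout(fov: float = 400.0,
                         insert_diameter: float = 32.0,
                         fine_spacing: float = 0.25,
                         slab_mm: float = 32.0,
                         kvp_amplitude: float = 0.03) -> PhantomLayout:
    """Build the default 28-material layout.

    Deterministic: inserts sit on concentric rings (1 + 8 + 9 + 10) whose
    radii scale with the requested FOV, leaving enough margin that the
    whole arrangement also fits the reduced high-pitch FOV (350/400 of
    the standard one).  ``insert_diameter`` is taken literally (mm).
    """
    scale = fov / 400.0
    centers: list[tuple[float, float]] = []
    for radius, count in _RING_PLAN:
        r = radius * scale
        for k in range(count):
            theta = 2 * math.pi * k / count + (0.25 if radius else 0.0)
            centers.append((r * math.cos(theta), r * math.sin(theta)))
    materials = tuple(
        MaterialSpec(label, name, family, mean_hu, sd, corr,
                     kvp_contrast_factor=_default_kvp_factor(label, kvp_amplitude))
        for label, name, family, mean_hu, sd, corr in _DEFAULT_MATERIALS
    )
    return PhantomLayout(
        materials=materials,
        insert_centers=tuple(centers),
        insert_diameter=insert_diameter,
        fov=fov,
        fine_spacing=fine_spacing,
        slab_mm=slab_mm,
    )


def material_texture(spec: MaterialSpec,
                     shape: tuple[int, int, int],
                     spacing: tuple[float, float, float],
                     seed: int | np.random.SeedSequence) -> VolumeImage:
    """Generate a stationary random texture volume for one material.

    The field has sample mean exactly ``mean_hu`` and sample SD exactly
    ``texture_sd`` over the generated grid, with a spatial autocorrelation
    scale set by ``correlation_length`` (Gaussian kernel sigma, mm).  The
    texture family shapes the field qualitatively:

    - ``homogeneous``: white noise (or a constant when texture_sd = 0);
    - ``granular``: isotropic correlated Gaussian field;
    - ``fibrous``: anisotropic field elongated along z (grain direction);
    - ``porous``: saturated (tanh-compressed) field producing plateau-like
      pores and walls.
    """
    shape = tuple(int(n) for n in shape)
    if any(n <= 0 for n in shape):
        raise ValueError("shape must be non-empty")
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing components must be positive, got {spacing}")

    if spec.texture_sd == 0:
        return VolumeImage(np.full(shape, spec.mean_hu, dtype=np.float32), spacing)

    rng = np.random.default_rng(seed)
    u = rng.standard_normal(shape).astype(np.float32)

    if spec.texture_family != "homogeneous":
        sigma_vox = [spec.correlation_length / s for s in spacing]
        if spec.texture_family == "fibrous":
            # fibres run along z: long correlation axially, short across
            sigma_vox = [0.6 * sigma_vox[0], 0.6 * sigma_vox[1], 3.0 * sigma_vox[2]]
        u = ndimage.gaussian_filter(u, sigma=sigma_vox, mode="reflect")
        if spec.texture_family == "porous":
            u = np.tanh(2.5 * u / max(u.std(), 1e-12)).astype(np.float32)

    sd = float(u.std())
    if sd < 1e-12:
        values = np.full(shape, spec.mean_hu, dtype=np.float32)
    else:
        values = (u - float(u.mean())) * (spec.texture_sd / sd) + spec.mean_hu
    return VolumeImage(values.astype(np.float32), spacing)


def generate_ground_truth(layout: PhantomLayout,
                          seed: int) -> tuple[VolumeImage, VolumeImage]:
    """Rasterize the phantom on the fine grid: (HU volume, label mask).

    Each insert cylinder is filled with its material texture; the
    background is uniform foam.  The label mask holds 0 for background and
    the material label inside each insert.  The ground truth is a pure
    function of (layout, seed); it is generated once per study seed and
    shared by all simulated protocols.
    """
    sp = layout.fine_spacing
    n_xy = int(round(layout.fov / sp))
    n_z = int(round(layout.slab_mm / sp))
    spacing = (sp, sp, sp)
    origin = (-(n_xy - 1) / 2 * sp, -(n_xy - 1) / 2 * sp, -(n_z - 1) / 2 * sp)

    values = np.full((n_xy, n_xy, n_z), layout.background_hu, dtype=np.float32)
    labels = np.zeros((n_xy, n_xy, n_z), dtype=np.uint8)

    xs = origin[0] + sp * np.arange(n_xy)
    ys = origin[1] + sp * np.arange(n_xy)
    radius = layout.insert_diameter / 2.0

    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    child_seeds = ss.spawn(layout.n_materials)
    for spec, (cx, cy), sub in zip(layout.materials, layout.insert_centers,
                                   child_seeds):
        i0 = max(0, int(np.searchsorted(xs, cx - radius)) - 1)
        i1 = min(n_xy, int(np.searchsorted(xs, cx + radius)) + 1)
        j0 = max(0, int(np.searchsorted(ys, cy - radius)) - 1)
        j1 = min(n_xy, int(np.searchsorted(ys, cy + radius)) + 1)
        dx = xs[i0:i1] - cx
        dy = ys[j0:j1] - cy
        disk = (dx[:, None] ** 2 + dy[None, :] ** 2) <= radius ** 2
        mask = np.broadcast_to(disk[:, :, None], (i1 - i0, j1 - j0, n_z))
        if np.any(labels[i0:i1, j0:j1, :][mask]):
            raise LayoutError(f"insert {spec.label} overlaps a previous insert")
        tex = material_texture(spec, (i1 - i0, j1 - j0, n_z), spacing, sub)
        region_vals = values[i0:i1, j0:j1, :]
        region_vals[mask] = tex.values[mask]
        region_lab = labels[i0:i1, j0:j1, :]
        region_lab[mask] = spec.label

    vol = VolumeImage(values, spacing, origin)
    lab = VolumeImage(labels, spacing, origin)
    return vol, lab
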