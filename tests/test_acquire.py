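"""Acquisition surrogate and ROI construction."""

import numpy as np
import pytest

from phantomrad.acquire import (GeometryError, ResolutionError, build_rois,
                                simulate_acquisition)
from phantomrad.phantom import build_default_layout, generate_ground_truth
from phantomrad.protocols import (ProtocolSpec, RigidTransform,
                                  SurrogateParams, default_protocol_suite)
from phantomrad.volume import VolumeImage


@pytest.fixture(scope="module")
def compact_world():
    """Compact phantom ground truth + matching protocol suite."""
    layout = build_default_layout(fov=100.0, insert_diameter=8.0,
                                  slab_mm=16.0)
    truth, labels = generate_ground_truth(layout, seed=42)
    suite = {p.id: p for p in default_protocol_suite(matrix=128, fov=100.0)}
    return layout, truth, labels, suite


@pytest.fixture(scope="module")
def flat_truth():
    """A homogeneous 40 mm water cube on a 0.25 mm grid."""
    n = 160
    vals = np.zeros((n, n, n // 2), dtype=np.float32)
    sp = 0.25
    origin = tuple(-(s - 1) / 2 * sp for s in vals.shape)
    return VolumeImage(vals, (sp, sp, sp), origin)


class TestSimulateAcquisition:
    def test_deterministic_for_fixed_seed(self, compact_world):
        layout, truth, labels, suite = compact_world
        a = simulate_acquisition(truth, suite["reference"], seed=5,
                                 labels=labels, layout=layout)
        b = simulate_acquisition(truth, suite["reference"], seed=5,
                                 labels=labels, layout=layout)
        assert np.array_equal(a.values, b.values)

    def test_output_grid_geometry(self, compact_world):
        layout, truth, labels, suite = compact_world
        for pid in ("reference", "high_pitch", "slice04"):
            p = suite[pid]
            img = simulate_acquisition(truth, p, seed=1, labels=labels,
                                       layout=layout)
            assert img.spacing == pytest.approx(
                (p.pixel_spacing, p.pixel_spacing, p.slice_thickness))

    def test_slice04_axial_spacing(self, compact_world):
        layout, truth, labels, suite = compact_world
        img = simulate_acquisition(truth, suite["slice04"], seed=1,
                                   labels=labels, layout=layout)
        assert img.spacing[2] == pytest.approx(0.4)
        # 0.4 mm slices over the same slab -> 2.5x as many slices
        ref = simulate_acquisition(truth, suite["reference"], seed=1,
                                   labels=labels, layout=layout)
        assert img.shape[2] == int(ref.shape[2] * 2.5)

    def test_protocol_finer_than_truth_rejected(self, compact_world):
        layout, truth, labels, suite = compact_world
        too_fine = ProtocolSpec(id="x", slice_thickness=0.1)
        with pytest.raises(ResolutionError):
            simulate_acquisition(truth, too_fine, seed=1)

    def test_kvp140_requires_material_labels(self, compact_world):
        _, truth, _, suite = compact_world
        with pytest.raises(ValueError):
            simulate_acquisition(truth, suite["kvp140"], seed=1)

    def test_kvp140_scales_contrast_per_material(self, compact_world):
        layout, truth, labels, suite = compact_world
        ref = simulate_acquisition(truth, suite["reference"], seed=3,
                                   labels=labels, layout=layout)
        kv = simulate_acquisition(truth, suite["kvp140"], seed=3,
                                  labels=labels, layout=layout)
        # sand (label 19, ~1100 HU): contrast factor shifts its mean
        spec = layout.material_by_label(19)
        rois = build_rois(suite["reference"], layout, diameter_px=9,
                          n_layers=7)
        m = rois.mask(19)
        observed = kv.values[m].mean() / ref.values[m].mean()
        assert observed == pytest.approx(spec.kvp_contrast_factor, abs=0.01)

    def test_noise_sd_follows_dose_law(self, flat_truth):
        suite = {p.id: p for p in default_protocol_suite()}
        params = SurrogateParams()
        reps = 12
        stacks = {}
        for pid in ("reference", "dose05"):
            imgs = [simulate_acquisition(flat_truth, suite[pid],
                                         seed=1000 + r, params=params)
                    for r in range(reps)]
            stacks[pid] = np.stack([im.values for im in imgs])
        # per-voxel SD across replicates, averaged over a central region
        def mean_sd(stack):
            core = stack[:, 10:-10, 10:-10, 2:-2]
            return core.std(axis=0, ddof=1).mean()

        ratio = mean_sd(stacks["dose05"]) / mean_sd(stacks["reference"])
        assert ratio == pytest.approx(np.sqrt(10.00 / 0.47), rel=0.10)

    def test_measured_noise_matches_declared_sigma(self, flat_truth):
        suite = {p.id: p for p in default_protocol_suite()}
        params = SurrogateParams()
        img = simulate_acquisition(flat_truth, suite["reference"], seed=7,
                                   params=params)
        measured = img.values[5:-5, 5:-5, 1:-1].std()
        assert measured == pytest.approx(params.noise_sd(suite["reference"]),
                                         rel=0.05)


class TestBuildRois:
    def test_reference_masks_are_35px_by_25_layers(self):
        layout = build_default_layout()
        ref = default_protocol_suite()[0]
        rois = build_rois(ref, layout)  # defaults: 35 px, 25 layers
        for label in (1, 14, 28):
            m = rois.mask(label)
            xs = np.nonzero(m.any(axis=(1, 2)))[0]
            ys = np.nonzero(m.any(axis=(0, 2)))[0]
            zs = np.nonzero(m.any(axis=(0, 1)))[0]
            assert xs.max() - xs.min() + 1 == 35
            assert ys.max() - ys.min() + 1 == 35
            assert zs.max() - zs.min() + 1 == 25

    def test_masks_disjoint_and_complete(self):
        layout = build_default_layout()
        ref = default_protocol_suite()[0]
        rois = build_rois(ref, layout)
        assert rois.material_labels == list(range(1, 29))
        # label volume encodes disjointness; every ROI has the full size
        sizes = np.bincount(rois.labels.ravel())[1:]
        assert len(sizes) == 28
        assert np.all(sizes == sizes[0])

    def test_identity_propagation_reproduces_reference_masks(self):
        layout = build_default_layout(fov=100.0, insert_diameter=8.0,
                                      slab_mm=16.0)
        suite = default_protocol_suite(matrix=128, fov=100.0)
        a = build_rois(suite[0], layout, diameter_px=9, n_layers=7)
        b = build_rois(suite[0], layout, RigidTransform.identity(),
                       diameter_px=9, n_layers=7)
        assert np.array_equal(a.labels, b.labels)

    def test_high_pitch_physical_diameter_shrinks(self):
        layout = build_default_layout()
        suite = {p.id: p for p in default_protocol_suite()}
        rois = build_rois(suite["high_pitch"], layout,
                          snap_grid=suite["reference"])
        assert rois.diameter_px == 35
        phys = rois.diameter_px * suite["high_pitch"].pixel_spacing
        assert phys == pytest.approx(23.9, abs=0.1)

    def test_reposition_tracking_overlap(self):
        """ROIs built with the scan's transform must cover the same
        physical cylinder as the reference ROIs (>= 99% overlap)."""
        layout = build_default_layout(fov=100.0, insert_diameter=8.0,
                                      slab_mm=16.0)
        suite = default_protocol_suite(matrix=128, fov=100.0)
        ref_p = suite[0]
        t = RigidTransform(translation=(3.0, -2.0, 1.0), rotation_z=2.0)
        ref_rois = build_rois(ref_p, layout, diameter_px=9, n_layers=7)
        rep_rois = build_rois(ref_p, layout, t, diameter_px=9, n_layers=7,
                              snap_grid=ref_p)
        r_mm = (9 - 1) / 2 * ref_p.pixel_spacing
        inv = t.inverse()
        for label in (1, 10, 28):
            m = rep_rois.mask(label)
            ii, jj, kk = np.nonzero(m)
            pts = np.stack([
                rep_rois.origin[0] + rep_rois.spacing[0] * ii,
                rep_rois.origin[1] + rep_rois.spacing[1] * jj,
                rep_rois.origin[2] + rep_rois.spacing[2] * kk], axis=-1)
            back = inv.apply(pts)
            # membership in the continuous reference cylinder
            cx, cy, cz = ref_rois.centers_vox[label]
            ccx = ref_rois.origin[0] + ref_rois.spacing[0] * cx
            ccy = ref_rois.origin[1] + ref_rois.spacing[1] * cy
            inside = ((back[:, 0] - ccx) ** 2 + (back[:, 1] - ccy) ** 2
                      <= r_mm ** 2 + 1e-6)
            assert inside.mean() >= 0.99

    def test_even_or_tiny_diameter_rejected(self):
        layout = build_default_layout()
        ref = default_protocol_suite()[0]
        with pytest.raises(ValueError):
            build_rois(ref, layout, diameter_px=34)
        with pytest.raises(ValueError):
            build_rois(ref, layout, diameter_px=1)

    def test_too_many_layers_rejected(self):
        layout = build_default_layout()  # 32 mm slab -> 32 slices at 1 mm
        ref = default_protocol_suite()[0]
        with pytest.raises(GeometryError):
            build_rois(ref, layout, n_layers=40)

    def test_roi_larger_than_insert_warns_with_overlap_fraction(self):
        layout = build_default_layout(fov=100.0, insert_diameter=8.0,
                                      slab_mm=16.0)
        p = default_protocol_suite(matrix=128, fov=100.0)[0]
        with pytest.warns(UserWarning, match="overlap fraction"):
            build_rois(p, layout, diameter_px=11, n_layers=7)
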