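import numpy as np
import pytest

from rssi_nwu import PhantomSpec, RigidTransform, generate_phantom
from rssi_nwu.errors import EmptySelectionError, ValidationError
from rssi_nwu.images import SegmentationMask, VolumeImage, dice
from rssi_nwu.spatial import (
    default_template,
    extract_brain,
    mirror_mask_across_midline,
    normalize_to_template,
    register_rigid,
    resample_mask,
    segment_lesion_dwi,
    shrink_mask,
)
from rssi_nwu.transforms import AffineTransform


def _sphere_mask(n=25, r2=100, spacing=1.0):
    c = (n - 1) / 2
    x, y, z = np.meshgrid(*[np.arange(n)] * 3, indexing="ij")
    data = ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= r2).astype(np.uint8)
    aff = np.diag([spacing, spacing, spacing, 1.0])
    return SegmentationMask(data, aff, "lesion")


class TestExtractBrain:
    def test_covers_phantom_brain_and_excludes_skull(self, default_bundle):
        mask = extract_brain(default_bundle.ct, 0.0, 100.0)
        truth = default_bundle.truth_brain_mask_ct
        covered = np.logical_and(mask.boolean(), truth.boolean()).sum()
        assert covered / truth.count >= 0.99
        assert not np.any(mask.boolean() & (default_bundle.ct.data > 500.0))

    def test_all_air_volume_raises(self):
        img = VolumeImage(np.full((10, 10, 10), -1000.0), np.eye(4))
        with pytest.raises(EmptySelectionError):
            extract_brain(img)

    def test_interior_hole_is_filled(self):
        data = np.full((20, 20, 20), -1000.0)
        c = 9.5
        x, y, z = np.meshgrid(*[np.arange(20)] * 3, indexing="ij")
        inside = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= 49
        data[inside] = 30.0
        data[9:11, 9:11, 9:11] = -1000.0  # interior cavity outside HU range
        mask = extract_brain(VolumeImage(data, np.eye(4)))
        assert np.all(mask.data[inside])


class TestSegmentLesionDwi:
    def test_recovers_phantom_lesion(self):
        spec = PhantomSpec(
            dwi_voxel_size_mm=(1.0, 1.0, 1.0),
            lesion_volume_cm3=1.5,
            dwi_noise_sd=5.0,
            dwi_lesion_intensity=125.0,  # lesion at +5 SD over brain signal
            seed=3,
        )
        b = generate_phantom(spec)
        brain = extract_brain(b.dwi, 50.0, float("inf"))
        seg = segment_lesion_dwi(b.dwi, brain, k_sd=3.0)
        assert dice(seg, b.truth_lesion_mask_dwi) >= 0.7
        assert np.all(seg.data <= b.truth_lesion_mask_dwi.data | seg.data)  # binary

    def test_uniform_dwi_raises(self):
        img = VolumeImage(np.full((12, 12, 12), 100.0), np.eye(4), "DWI")
        brain = SegmentationMask(np.ones((12, 12, 12)), np.eye(4), "brain")
        with pytest.raises(EmptySelectionError):
            segment_lesion_dwi(img, brain, 3.0)

    def test_interior_hole_removed(self):
        rng = np.random.default_rng(0)
        data = 100.0 + rng.normal(0, 1.0, (24, 24, 24))
        c = 11.5
        x, y, z = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
        sphere = (x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2 <= 20
        data[sphere] = 200.0
        data[12, 12, 12] = 100.0  # one-voxel hole
        brain = SegmentationMask(np.ones((24, 24, 24)), np.eye(4), "brain")
        seg = segment_lesion_dwi(VolumeImage(data, np.eye(4), "DWI"), brain, 3.0)
        from scipy import ndimage

        filled = ndimage.binary_fill_holes(seg.boolean())
        assert np.array_equal(filled, seg.boolean())
        assert seg.data[12, 12, 12] == 1


class TestShrinkMask:
    def test_sphere_shrinks_within_band(self):
        m = _sphere_mask()
        s = shrink_mask(m, 0.9)
        ratio = s.count / m.count
        assert 0.80 <= ratio <= 0.90
        assert np.all(s.data <= m.data)  # anti-extensive
        assert s.count < m.count

    def test_target_one_is_identity(self):
        m = _sphere_mask(n=11, r2=16)
        s = shrink_mask(m, 1.0)
        assert np.array_equal(s.data, m.data)

    def test_single_voxel_cannot_shrink(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 1
        m = SegmentationMask(data, np.eye(4), "lesion")
        with pytest.raises(ValidationError, match="larger target_fraction"):
            shrink_mask(m, 0.9)

    def test_anisotropic_spacing_peels_thin_axis_last(self):
        # a slab 3 voxels thick along z with 3 mm spacing should lose its
        # in-plane rim (1 mm spacing) before its top/bottom faces
        data = np.zeros((20, 20, 5))
        data[2:18, 2:18, 1:4] = 1
        aff = np.diag([1.0, 1.0, 3.0, 1.0])
        m = SegmentationMask(data, aff, "lesion")
        s = shrink_mask(m, 0.9)
        assert np.array_equal(np.unique(np.argwhere(s.data)[:, 2]), [1, 2, 3])


class TestResampleMask:
    def test_identity_same_grid_bit_identical(self, default_bundle):
        mask = default_bundle.truth_lesion_mask_ct
        out = resample_mask(mask, AffineTransform.identity(), default_bundle.ct)
        assert np.array_equal(out.data, mask.data)

    def test_truth_transform_maps_dwi_lesion_onto_ct(self, default_bundle):
        out = resample_mask(
            default_bundle.truth_lesion_mask_dwi,
            default_bundle.truth_transform,
            default_bundle.ct,
        )
        assert dice(out, default_bundle.truth_lesion_mask_ct) >= 0.8

    def test_mask_outside_field_of_view_raises(self, default_bundle):
        far = RigidTransform(translation_mm=(500.0, 0.0, 0.0))
        with pytest.raises(EmptySelectionError):
            resample_mask(default_bundle.truth_lesion_mask_dwi, far, default_bundle.ct)


class TestRegisterRigid:
    def test_self_registration_recovers_identity(self, noise_free_bundle):
        ct = noise_free_bundle.ct
        t = register_rigid(ct, ct)
        rot, trans = t.deviation_from(RigidTransform.identity())
        assert rot <= 0.5 and trans <= 0.5

    def test_translation_only_offset_recovered(self):
        b = generate_phantom(
            PhantomSpec(misalignment=RigidTransform(translation_mm=(10.0, 0.0, 0.0)), seed=8)
        )
        t = register_rigid(b.ct, b.dwi)
        rot, trans = t.deviation_from(b.truth_transform)
        assert trans <= 1.0


class TestNormalizeToTemplate:
    def test_template_registers_to_itself_as_identity(self):
        a = normalize_to_template(default_template())
        assert np.abs(a.matrix - np.eye(4)).max() < 0.05

    def test_recovers_isotropic_scale(self):
        template = default_template()
        scaled_affine = template.affine.copy()
        scaled_affine[:3, :] *= 1.1  # head 10% larger in every direction
        subject = VolumeImage(template.data, scaled_affine, "CT")
        a = normalize_to_template(subject)
        scale = float(np.abs(np.linalg.det(np.linalg.inv(a.matrix)[:3, :3])) ** (1 / 3))
        assert scale == pytest.approx(1.1, abs=0.02)

    def test_rotated_subject_midline_maps_onto_template_plane(self):
        from scipy import ndimage

        template = default_template()
        rot = RigidTransform(rotation_deg=(0.0, 0.0, 8.0))
        # subject(p) = template(R^-1 p): anatomy rotated by +8 degrees
        inv = np.linalg.inv(template.affine) @ rot.inverse().matrix @ template.affine
        idx = np.indices(template.shape, dtype=float).reshape(3, -1)
        coords = inv[:3, :3] @ idx + inv[:3, 3:4]
        data = ndimage.map_coordinates(
            template.data, coords.reshape(3, *template.shape), order=1, cval=-1000.0
        )
        subject = VolumeImage(data, template.affine, "CT")
        a = normalize_to_template(subject)
        midline_pts = rot.apply(
            np.array([[0.0, y, z] for y in (-40, 0, 40) for z in (-20, 0, 20)])
        )
        mapped_x = a.apply(midline_pts)[:, 0]
        assert np.abs(mapped_x).max() <= 2.0


class TestMirrorAcrossMidline:
    def test_involution_recovers_original(self, default_bundle, default_to_template):
        lesion = default_bundle.truth_lesion_mask_ct
        once = mirror_mask_across_midline(lesion, default_to_template)
        twice = mirror_mask_across_midline(once, default_to_template)
        assert dice(twice, lesion) >= 0.95

    def test_symmetric_mask_is_fixed_point(self, default_bundle, default_to_template):
        brain = default_bundle.truth_brain_mask_ct
        mirrored = mirror_mask_across_midline(brain, default_to_template)
        assert dice(mirrored, brain) >= 0.95

    def test_lesion_maps_onto_contralateral_truth(self, default_bundle, default_to_template):
        contra = mirror_mask_across_midline(
            default_bundle.truth_lesion_mask_ct, default_to_template
        )
        assert contra.role == "contralateral"
        assert dice(contra, default_bundle.truth_contralateral_mask_ct) >= 0.85
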