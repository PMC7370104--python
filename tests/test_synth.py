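"""Phantom generation and simulated-segmentation behaviour."""

import numpy as np
import pytest
from scipy import stats as sps

from condylometry.core import MeshError
from condylometry.deviation import mesh_volume, signed_deviation
from condylometry.register import RigidTransform, invert
from condylometry.stats import icc
from condylometry.synth import (
    PhantomSpec,
    SegmentationSimSpec,
    apply_rigid,
    make_condyle_phantom,
    make_rating_table,
    offset_for_threshold,
    perturb_surface,
    phantom_section_volume,
    simulate_segmentation,
    threshold_for_offset,
    voxelize,
)

from .conftest import icosphere


class TestPhantom:
    def test_watertight_genus_zero(self, phantom):
        mesh, _ = phantom
        assert mesh.is_watertight()
        assert mesh.euler_characteristic() == 2

    def test_volume_in_condylar_range(self, phantom):
        mesh, _ = phantom
        assert 1384.0 <= mesh_volume(mesh) <= 1915.0

    def test_mesh_volume_matches_profile_quadrature(self, phantom, phantom_spec):
        mesh, _ = phantom
        analytic = phantom_section_volume(phantom_spec)
        assert mesh_volume(mesh) == pytest.approx(analytic, rel=0.005)

    def test_deterministic_given_seed(self):
        a, _ = make_condyle_phantom(PhantomSpec(seed=7))
        b, _ = make_condyle_phantom(PhantomSpec(seed=7))
        assert (a.vertices == b.vertices).all()
        assert (a.faces == b.faces).all()

    def test_different_seeds_differ(self):
        a, _ = make_condyle_phantom(PhantomSpec(seed=1))
        b, _ = make_condyle_phantom(PhantomSpec(seed=2))
        assert not np.allclose(a.vertices, b.vertices)

    def test_too_coarse_refinement_rejected(self):
        with pytest.raises(ValueError, match="refinement"):
            make_condyle_phantom(PhantomSpec(refinement=0))

    def test_landmarks_present_and_separated(self, phantom):
        _, lms = phantom
        for name in (
            "mental_foramen_L",
            "mental_foramen_R",
            "lingula_L",
            "lingula_R",
            "Sg_L",
            "Li_L",
        ):
            assert name in lms
        assert np.linalg.norm(lms["Sg_L"] - lms["Li_L"]) > 1.0


class TestVoxelize:
    def test_sphere_inside_count(self):
        mesh = icosphere(5.0, 3)
        vol = voxelize(mesh, spacing=0.3)
        inside = (vol.data > 50).sum() * 0.3**3
        assert inside == pytest.approx(4 / 3 * np.pi * 125, rel=0.05)

    def test_no_blur_keeps_two_intensities(self):
        mesh = icosphere(4.0, 2)
        vol = voxelize(mesh, spacing=0.5, blur_sigma=0.0)
        assert set(np.unique(vol.data)) == {0.0, 100.0}

    def test_doubling_spacing_scales_count(self):
        mesh = icosphere(5.0, 3)
        fine = (voxelize(mesh, spacing=0.3).data > 50).sum()
        coarse = (voxelize(mesh, spacing=0.6).data > 50).sum()
        assert fine / coarse == pytest.approx(8.0, rel=0.1)

    def test_non_watertight_rejected(self):
        from condylometry.core import TriangleMesh

        open_tri = TriangleMesh(np.eye(3), np.array([[0, 1, 2]]))
        with pytest.raises(MeshError, match="watertight"):
            voxelize(open_tri)


@pytest.fixture(scope="module")
def volume(phantom):
    mesh, _ = phantom
    return voxelize(mesh, spacing=0.3)


class TestSimulatedSegmentation:
    def test_midpoint_threshold_unbiased(self, volume, phantom):
        mesh, _ = phantom
        seg = simulate_segmentation(
            volume, SegmentationSimSpec(threshold=50.0, blur_sigma=0.45)
        )
        field = signed_deviation(seg, mesh)
        assert abs(field.raw_distances.mean()) < 0.03  # spacing / 10

    @pytest.mark.parametrize("offset", [0.2, -0.2])
    def test_threshold_offset_recovered(self, volume, phantom, offset):
        mesh, _ = phantom
        thr = threshold_for_offset(offset, blur_sigma=0.45)
        seg = simulate_segmentation(
            volume, SegmentationSimSpec(threshold=thr, blur_sigma=0.45)
        )
        field = signed_deviation(seg, mesh)
        assert field.raw_distances.mean() == pytest.approx(offset, abs=0.05)

    def test_bias_monotone_in_threshold(self, volume, phantom):
        mesh, _ = phantom
        means = []
        for thr in (30.0, 45.0, 55.0, 70.0):
            seg = simulate_segmentation(
                volume,
                SegmentationSimSpec(threshold=thr, blur_sigma=0.45,
                                    noise_sigma=4.0, seed=5),
            )
            means.append(signed_deviation(seg, mesh).raw_distances.mean())
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_deterministic(self, volume):
        spec = SegmentationSimSpec(threshold=45.0, noise_sigma=5.0, seed=3)
        a = simulate_segmentation(volume, spec)
        b = simulate_segmentation(volume, spec)
        assert (a.vertices == b.vertices).all()

    def test_threshold_out_of_range_rejected(self, volume):
        with pytest.raises(ValueError, match="intensity range"):
            simulate_segmentation(volume, SegmentationSimSpec(threshold=150.0))

    def test_offset_threshold_inversion(self):
        thr = threshold_for_offset(0.3, blur_sigma=0.45)
        assert offset_for_threshold(thr, blur_sigma=0.45) == pytest.approx(0.3)


class TestPerturbSurface:
    def test_identity(self, sphere10):
        out = perturb_surface(sphere10, 0.0, 0.0)
        np.testing.assert_array_equal(out.vertices, sphere10.vertices)

    def test_offset_scales_sphere_volume(self, sphere10):
        out = perturb_surface(sphere10, 0.45, 0.0)
        ratio = mesh_volume(out) / mesh_volume(sphere10)
        assert ratio == pytest.approx((10.45 / 10.0) ** 3, rel=1e-3)

    def test_displacements_normally_distributed(self, sphere10):
        # recovered normal displacements pass Shapiro-Wilk at alpha=0.01
        # in at least 9 of 10 seeds (1% nominal failure rate)
        normals = sphere10.vertex_normals()
        passes = 0
        for seed in range(10):
            out = perturb_surface(sphere10, 0.0, 0.1, seed=seed)
            disp = np.einsum("ij,ij->i", out.vertices - sphere10.vertices,
                             normals)
            rng = np.random.default_rng(seed + 100)
            sample = rng.choice(disp, size=500, replace=False)
            if sps.shapiro(sample).pvalue > 0.01:
                passes += 1
        assert passes >= 9

    def test_fold_detected(self):
        tiny = icosphere(0.5, 2)
        with pytest.raises(MeshError, match="folds"):
            perturb_surface(tiny, -0.49, 0.0)


class TestApplyRigid:
    def test_identity_and_inverse(self, phantom):
        mesh, lms = phantom
        T = RigidTransform.from_axis_angle([0, 0, 1], 33.0, [1, 2, 3])
        back = apply_rigid(apply_rigid(mesh, T), invert(T))
        np.testing.assert_allclose(back.vertices, mesh.vertices, atol=1e-9)

    def test_rotation_90deg(self):
        T = RigidTransform.from_axis_angle([0, 0, 1], 90.0)
        np.testing.assert_allclose(
            T.apply_points(np.array([[1.0, 0, 0]])), [[0, 1, 0]], atol=1e-12
        )

    def test_distances_preserved(self, phantom):
        mesh, _ = phantom
        T = RigidTransform.from_axis_angle([1, 1, 0], 17.0, [-4, 2, 9])
        moved = apply_rigid(mesh, T)
        d0 = np.linalg.norm(mesh.vertices[0] - mesh.vertices[100])
        d1 = np.linalg.norm(moved.vertices[0] - moved.vertices[100])
        assert d1 == pytest.approx(d0, abs=1e-9)


class TestRatingTable:
    def test_noise_free_table_equals_truth(self):
        truth = np.array([100.0, 200.0, 300.0])
        t = make_rating_table(3, truth, seed=0)
        for _, row in t.iterrows():
            assert row["value"] == truth[int(row["condyle"])]

    def test_between_rater_variance_separates_designs(self):
        rng = np.random.default_rng(0)
        truth = rng.normal(1631, 50, size=12)
        t = make_rating_table(
            12, truth, within_rater_sd=0.0, between_rater_sd=200.0, seed=4
        )
        assert icc(t, "intra").value == pytest.approx(1.0)
        assert icc(t, "inter").value < 0.5

    def test_reproducible(self):
        truth = np.linspace(1000, 2000, 5)
        a = make_rating_table(5, truth, within_rater_sd=5.0, seed=9)
        b = make_rating_table(5, truth, within_rater_sd=5.0, seed=9)
        assert a.equals(b)
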