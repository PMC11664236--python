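import numpy as np
import pytest

from beevision.eye_geometry import (
    DegenerateGeometryError,
    EyeSurface,
    GeometryConfig,
    OcelliSet,
    _covered_bins,
    binocular_overlap,
    compute_all_traits,
    facet_neighbours,
    icosphere_bins,
    local_eye_parameter,
    local_facet_diameter,
    local_facet_properties,
    local_io_angle,
    local_radius,
    monocular_fov,
    ocellar_traits,
    surface_area,
    viewing_directions,
    _fit_sphere,
)
from beevision.synthetic_data import CapEyeSpec, generate_cap_eye, generate_head

from conftest import random_rotation


class TestSurfaceArea:
    def test_cap_analytic(self, cap_eye):
        eye, truth = cap_eye
        assert surface_area(eye) == pytest.approx(truth.surface_area_um2, rel=0.01)

    def test_rigid_motion_invariance(self, small_cap_eye):
        eye, _ = small_cap_eye
        moved = eye.transformed(random_rotation(1), np.array([10.0, -5.0, 3.0]))
        assert surface_area(moved) == pytest.approx(surface_area(eye), rel=1e-12)

    def test_refinement_convergence(self, cap_spec):
        eye_coarse, truth = generate_cap_eye(cap_spec, mesh_resolution=48)
        eye_fine, _ = generate_cap_eye(cap_spec, mesh_resolution=96)
        a_coarse = surface_area(eye_coarse)
        a_fine = surface_area(eye_fine)
        assert abs(a_fine - a_coarse) / truth.surface_area_um2 <= 0.003
        assert abs(a_fine - truth.surface_area_um2) < abs(a_coarse - truth.surface_area_um2)

    def test_degenerate_mesh_rejected(self):
        verts = np.zeros((8, 3))
        tris = np.array([[0, 1, 2]] * 4)
        eye = EyeSurface(verts, tris, np.random.default_rng(0).normal(size=(7, 3)))
        with pytest.raises(DegenerateGeometryError):
            surface_area(eye)


class TestFacetNeighbours:
    def test_interior_facet_has_six(self, cap_eye):
        eye, _ = cap_eye
        nb = facet_neighbours(eye)
        # the facet closest to the cap axis is deep interior
        apex = np.argmax(eye.facet_centres[:, 2])
        assert len(nb[apex]) == 6

    def test_boundary_facet_has_three_to_five(self, cap_eye):
        eye, _ = cap_eye
        nb = facet_neighbours(eye)
        # brute-force oracle: recompute neighbour sets by a full distance scan
        centres = eye.facet_centres
        d = np.linalg.norm(centres[:, None] - centres[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        cutoff = 1.4 * np.median(d.min(axis=1))
        rim = np.argmin(centres[:, 2])  # farthest from the axis
        brute = set(np.where(d[rim] <= cutoff)[0])
        assert set(nb[rim].tolist()) == brute
        assert 3 <= len(nb[rim]) <= 5

    def test_fewer_than_seven_facets_rejected_upstream(self):
        verts = np.random.default_rng(0).normal(size=(4, 3))
        with pytest.raises(DegenerateGeometryError):
            EyeSurface(verts, np.array([[0, 1, 2]]), np.zeros((2, 3)))

    def test_coincident_centres_rejected(self):
        verts = np.random.default_rng(0).normal(size=(4, 3))
        eye = EyeSurface(verts, np.array([[0, 1, 2]]), np.zeros((7, 3)))
        with pytest.raises(DegenerateGeometryError):
            facet_neighbours(eye)


class TestLocalFacetDiameter:
    def test_cap_ground_truth(self, cap_eye, cap_props):
        _, truth = cap_eye
        mean_d = np.nanmean(cap_props.local_spacing)
        assert mean_d == pytest.approx(truth.facet_spacing_um, rel=0.01)

    def test_homogeneity_under_scaling(self, small_cap_eye):
        eye, _ = small_cap_eye
        scaled = EyeSurface(
            eye.vertices * 2.0, eye.triangles, eye.facet_centres * 2.0, side=eye.side
        )
        d1 = np.nanmean(local_facet_diameter(eye))
        d2 = np.nanmean(local_facet_diameter(scaled))
        assert d2 == pytest.approx(2.0 * d1, rel=1e-9)


class TestLocalRadius:
    def test_cap_ground_truth(self, cap_eye, cap_props):
        _, truth = cap_eye
        assert np.nanmean(cap_props.local_radius) == pytest.approx(truth.radius_um, rel=0.01)

    def test_exact_sphere_fit(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(200, 3))
        pts = 500.0 * pts / np.linalg.norm(pts, axis=1, keepdims=True)
        centre, r = _fit_sphere(pts)
        assert r == pytest.approx(500.0, rel=1e-9)
        np.testing.assert_allclose(centre, 0.0, atol=1e-6)

    def test_jittered_radius_within_two_percent(self):
        errs = []
        for seed in range(20):
            spec = CapEyeSpec(
                radius_um=1000.0,
                facet_spacing_um=40.0,
                cap_half_angle_deg=60.0,
                positional_jitter_sd_um=1.0,
                seed=seed,
            )
            eye, _ = generate_cap_eye(spec)
            r = np.nanmean(local_radius(eye))
            errs.append(abs(r - 1000.0) / 1000.0)
        assert np.median(errs) <= 0.02


class TestLocalIOAngle:
    def test_cap_ground_truth(self, cap_eye, cap_props):
        _, truth = cap_eye
        assert np.nanmean(cap_props.local_io_angle_deg) == pytest.approx(
            truth.io_angle_deg, rel=0.02
        )

    def test_scale_invariance(self, small_cap_eye):
        eye, _ = small_cap_eye
        scaled = EyeSurface(
            eye.vertices * 3.0, eye.triangles, eye.facet_centres * 3.0, side=eye.side
        )
        p1 = local_facet_properties(eye)
        p2 = local_facet_properties(scaled)
        assert np.nanmean(p2.local_io_angle_deg) == pytest.approx(
            np.nanmean(p1.local_io_angle_deg), rel=1e-6
        )


class TestLocalEyeParameter:
    def test_cap_ground_truth(self, cap_eye, cap_props):
        _, truth = cap_eye
        assert np.nanmean(cap_props.local_eye_parameter) == pytest.approx(
            truth.eye_parameter_umrad, rel=0.02
        )

    def test_local_product_definition(self):
        D = np.array([10.0, 30.0])
        dphi_deg = np.array([2.0, 1.0])
        p = local_eye_parameter(D, dphi_deg)
        np.testing.assert_allclose(p, D * np.radians(dphi_deg))

    def test_mean_local_product_differs_from_product_of_means(self):
        # two-zone eye: fine facets on one cap, coarse on another, same R
        fine, _ = generate_cap_eye(CapEyeSpec(1000.0, 16.0, 40.0))
        coarse, _ = generate_cap_eye(CapEyeSpec(1000.0, 32.0, 40.0))
        pf = local_facet_properties(fine)
        pc = local_facet_properties(coarse)
        D = np.concatenate([pf.local_spacing, pc.local_spacing])
        dphi = np.concatenate([pf.local_io_angle_deg, pc.local_io_angle_deg])
        p = np.concatenate([pf.local_eye_parameter, pc.local_eye_parameter])
        mean_local = np.nanmean(p)
        product_of_means = np.nanmean(D) * np.radians(np.nanmean(dphi))
        # analytically: E[D^2]/R > (E[D])^2/R for varying D
        assert mean_local > product_of_means * 1.05


class TestViewingDirections:
    def test_radial_within_two_degrees(self, cap_eye):
        eye, _ = cap_eye
        dirs = viewing_directions(eye)
        radial = eye.facet_centres / np.linalg.norm(eye.facet_centres, axis=1, keepdims=True)
        ang = np.degrees(np.arccos(np.clip(np.einsum("ij,ij->i", dirs, radial), -1, 1)))
        assert np.percentile(ang, 99) < 2.0

    def test_rotation_equivariance(self, small_cap_eye):
        eye, _ = small_cap_eye
        R = random_rotation(2)
        moved = eye.transformed(R, np.zeros(3))
        d1 = viewing_directions(eye)
        d2 = viewing_directions(moved)
        np.testing.assert_allclose(d2, d1 @ R.T, atol=1e-4)

    def test_mean_direction_is_cap_axis(self, cap_eye):
        eye, _ = cap_eye
        dirs = viewing_directions(eye)
        mean_dir = dirs.mean(axis=0)
        mean_dir /= np.linalg.norm(mean_dir)
        ang = np.degrees(np.arccos(np.clip(mean_dir @ np.array([0, 0, 1.0]), -1, 1)))
        assert ang < 1.0

    def test_inward_mesh_detected_and_flipped(self, small_cap_eye):
        eye, _ = small_cap_eye
        flipped = EyeSurface(
            eye.vertices, eye.triangles[:, [0, 2, 1]], eye.facet_centres, side=eye.side
        )
        with pytest.warns(UserWarning, match="inward-oriented"):
            dirs = viewing_directions(flipped)
        radial = eye.facet_centres / np.linalg.norm(eye.facet_centres, axis=1, keepdims=True)
        assert np.einsum("ij,ij->i", dirs, radial).min() > 0.9


class TestFieldsOfView:
    def test_bin_count(self):
        assert len(icosphere_bins(4)) == 20 * 4**4

    def test_bins_unit_norm(self):
        b = icosphere_bins(2)
        np.testing.assert_allclose(np.linalg.norm(b, axis=1), 1.0, rtol=1e-12)

    def test_monocular_fov_cap(self, cap_eye, cap_props):
        eye, truth = cap_eye
        fov = monocular_fov(eye, cap_props)
        assert abs(fov - truth.monocular_fov_pct) <= 1.0

    def test_self_overlap_equals_monocular(self, cap_eye, cap_props):
        eye, _ = cap_eye
        fov = monocular_fov(eye, cap_props)
        overlap = binocular_overlap(eye, eye, cap_props, cap_props)
        assert overlap == pytest.approx(fov, abs=1e-12)

    def test_empty_directions_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            _covered_bins(icosphere_bins(2), np.zeros((0, 3)), np.zeros(0))

    def test_too_few_bins_rejected(self):
        dirs = np.array([[0.0, 0.0, 1.0]])
        with pytest.raises(ValueError, match="100"):
            _covered_bins(icosphere_bins(0), dirs, np.array([1.0]))


class TestOcellarTraits:
    def test_area_to_diameter(self):
        oc = OcelliSet(
            central_centroid=[0, 0, 0],
            lateral_centroids=[[1, 0, 0], [0, 1, 0]],
            lens_areas=[7853.981633974483, 7853.981633974483, 7853.981633974483],
        )
        central, lateral, _ = ocellar_traits(oc)
        assert central == pytest.approx(100.0)
        assert lateral == pytest.approx(100.0)

    def test_right_angle_alignment(self):
        oc = OcelliSet([0, 0, 0], [[1, 0, 0], [0, 1, 0]], lens_diameters=[100, 80, 90])
        _, lateral, alignment = ocellar_traits(oc)
        assert alignment == pytest.approx(90.0)
        assert lateral == pytest.approx(85.0)

    def test_collinear_alignment(self):
        oc = OcelliSet([0, 0, 0], [[-2, 0, 0], [3, 0, 0]], lens_diameters=[100, 80, 80])
        _, _, alignment = ocellar_traits(oc)
        assert alignment == pytest.approx(180.0)

    def test_distinct_points_required(self):
        with pytest.raises(DegenerateGeometryError):
            OcelliSet([0, 0, 0], [[0, 0, 0], [1, 0, 0]], lens_diameters=[100, 80, 80])


@pytest.fixture(scope="module")
def head():
    spec = CapEyeSpec(radius_um=800.0, facet_spacing_um=22.0, cap_half_angle_deg=55.0)
    return generate_head(spec, spec, 40.0)


class TestComputeAllTraits:
    def test_round_trip_against_ground_truth(self, head):
        (left, right), truth = head
        oc = OcelliSet([0, 200, 900], [[-150, 100, 900], [150, 100, 900]],
                       lens_diameters=[120.0, 100.0, 100.0])
        traits = compute_all_traits(left, right, oc, itd_mm=4.2,
                                    specimen_id="syn1", species="synthetic")
        tl = truth.left
        assert traits.facet_number == tl.facet_count
        assert traits.facet_diameter_um == pytest.approx(tl.facet_spacing_um, rel=0.02)
        assert traits.radius_of_curvature_um == pytest.approx(tl.radius_um, rel=0.02)
        assert traits.io_angle_deg == pytest.approx(tl.io_angle_deg, rel=0.02)
        assert traits.eye_parameter_umrad == pytest.approx(tl.eye_parameter_umrad, rel=0.02)
        assert traits.eye_surface_area_um2 == pytest.approx(tl.surface_area_um2, rel=0.01)
        assert abs(traits.monocular_fov_pct - tl.monocular_fov_pct) <= 1.5
        assert abs(traits.binocular_overlap_pct - truth.binocular_overlap_pct) <= 1.5
        assert traits.central_ocellus_diameter_um == pytest.approx(120.0)
        assert traits.ocellar_alignment_deg is not None
        assert traits.itd_mm == 4.2

    def test_overlap_bounded_by_twice_fov(self, head):
        (left, right), _ = head
        traits = compute_all_traits(left, right, None, None, "s", "sp")
        assert traits.binocular_overlap_pct <= 2 * traits.monocular_fov_pct

    def test_missing_ocelli_flagged(self, head):
        (left, right), _ = head
        traits = compute_all_traits(left, None, None, None, "s", "sp")
        assert traits.central_ocellus_diameter_um is None
        assert traits.ocellar_alignment_deg is None
        assert traits.facet_diameter_um is not None
        assert traits.binocular_overlap_pct is None

    def test_missing_both_eyes_rejected(self):
        with pytest.raises(ValueError):
            compute_all_traits(None, None, None, None, "s", "sp")


class TestScaleCovariance:
    """Uniform coordinate scaling: lengths linear, areas quadratic,
    angles and FOV scale-free, eye parameter linear."""

    def test_all_covariances(self, small_cap_eye):
        eye, _ = small_cap_eye
        c = 2.5
        scaled = EyeSurface(eye.vertices * c, eye.triangles, eye.facet_centres * c,
                            side=eye.side)
        t1 = compute_all_traits(eye, None, None, None, "a", "sp")
        t2 = compute_all_traits(scaled, None, None, None, "b", "sp")
        assert t2.facet_diameter_um == pytest.approx(c * t1.facet_diameter_um, rel=1e-6)
        assert t2.radius_of_curvature_um == pytest.approx(c * t1.radius_of_curvature_um, rel=1e-6)
        assert t2.eye_surface_area_um2 == pytest.approx(c**2 * t1.eye_surface_area_um2, rel=1e-9)
        assert t2.io_angle_deg == pytest.approx(t1.io_angle_deg, rel=1e-6)
        assert t2.eye_parameter_umrad == pytest.approx(c * t1.eye_parameter_umrad, rel=1e-6)
        assert t2.monocular_fov_pct == pytest.approx(t1.monocular_fov_pct, abs=1e-9)
        assert t2.facet_number == t1.facet_number
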