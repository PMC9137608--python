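"""Geometry, variant-table and mesh-generation tests."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from phakosim.geometry import (
    BAND_VARIANTS,
    OVAL_VARIANTS,
    GeometryParams,
    LensShapeParams,
    build_complex,
    build_lens_profile,
)
from phakosim.mesh import generate_mesh
from phakosim.optics import fit_sphere_radius


@pytest.fixture(scope="module")
def profile():
    return build_lens_profile()


@pytest.fixture(scope="module")
def coarse_mesh(profile):
    cx = build_complex(profile, GeometryParams.from_variants("Initial", "Ring"))
    return generate_mesh(cx, target_edge_length=1.7, n_theta=24)


class TestLensProfile:
    def test_nucleus_strictly_inside_cortex(self, profile):
        profile.validate()
        assert profile.nucleus_contour[:, 0].max() < profile.equator_radius

    def test_contours_touch_axis_at_poles(self, profile):
        for c in (profile.nucleus_contour, profile.cortex_contour):
            assert c[0, 0] == 0.0 and c[-1, 0] == 0.0

    @pytest.mark.parametrize("frac", [0.0, 1.0, -0.2])
    def test_degenerate_nucleus_fraction_rejected(self, frac):
        with pytest.raises(ValueError):
            LensShapeParams(nucleus_thickness_fraction=frac)

    def test_non_nested_contours_rejected(self):
        """A nucleus contour poking outside the cortex fails validation."""
        import copy

        bad = copy.deepcopy(build_lens_profile())
        bad.nucleus_contour = bad.nucleus_contour.copy()
        bad.nucleus_contour[:, 0] *= 1.5  # inflate beyond the cortex equator
        from dataclasses import replace as _r

        bad.nucleus_caps = tuple(
            type(c)(a=c.a, R=1.5 * c.R, q=c.q, sign=c.sign, xi0=c.xi0)
            for c in bad.nucleus_caps
        )
        with pytest.raises(ValueError):
            bad.validate()

    def test_central_zones_are_spherical_with_declared_radii(self, profile):
        """Sphere fits of the central caps recover the pole-radius parameters."""
        p = profile.shape
        for cap, target in (
            (profile.cortex_caps[0], p.anterior_pole_radius),
            (profile.cortex_caps[1], p.posterior_pole_radius),
        ):
            r = np.linspace(0, 1.2, 12)
            theta = np.linspace(0, 2 * np.pi, 13)[:-1]
            pts = np.array(
                [[ri * np.sin(t), ri * np.cos(t), cap.xi(ri)] for ri in r for t in theta]
            )
            R, rms = fit_sphere_radius(pts)
            assert R == pytest.approx(target, rel=0.02)
            assert rms < 1e-3 * R


class TestVariants:
    def test_initial_model_is_circular(self):
        g = GeometryParams.from_variants("Initial", "Ring")
        theta = np.linspace(0, 360, 25)
        assert np.allclose(g.zonule_length_at(theta), 1.5)

    def test_oval_plus_56_lengths(self):
        g = GeometryParams.from_variants("Oval+5.6", "Ring")
        assert g.zonule_length_at(0.0) == pytest.approx(1.584)
        assert g.zonule_length_at(90.0) == pytest.approx(1.500)

    def test_band4_widths(self):
        g = GeometryParams.from_variants("Initial", "Band4")
        assert g.band_widths == (0.590, 0.590, 0.548)

    def test_all_table_variants_construct(self):
        for oval in OVAL_VARIANTS:
            for band in BAND_VARIANTS:
                GeometryParams.from_variants(oval, band)

    def test_excessive_oval_ratio_rejected(self):
        with pytest.raises(ValueError):
            GeometryParams(oval_vertical_length=1.7, oval_horizontal_length=1.5)

    def test_oval_length_ratio_matches_request(self):
        """Max/min zonular length around the circumference equals the table ratio."""
        g = GeometryParams.from_variants("Oval+5.6", "Ring")
        theta = np.linspace(0, 360, 721)
        lengths = g.zonule_length_at(theta)
        assert lengths.max() / lengths.min() == pytest.approx(1.584 / 1.5, rel=1e-6)

    def test_band_overlap_rejected(self, profile):
        params = GeometryParams.from_variants(
            "Initial", "Band7", attachment_arc_anterior=0.5, attachment_arc_posterior=0.5
        )
        with pytest.raises(ValueError, match="overlap"):
            build_complex(profile, params)


class TestMesh:
    def test_no_inverted_tetrahedra(self, coarse_mesh):
        assert coarse_mesh.tet_volumes().min() > 0

    def test_refinement_monotonicity(self, profile):
        cx = build_complex(profile, GeometryParams.from_variants("Initial", "Ring"))
        coarse = generate_mesh(cx, target_edge_length=1.7, n_theta=24)
        fine = generate_mesh(cx, target_edge_length=0.8, n_theta=48)
        assert len(fine.tets) > len(coarse.tets)
        assert fine.n_nodes > coarse.n_nodes

    def test_zonular_angle_tags_match_centroids(self, coarse_mesh):
        """Angle tags recomputed from element centroids agree exactly."""
        for s, tris in coarse_mesh.zonule_tris.items():
            cent = coarse_mesh.nodes[tris].mean(axis=1)
            theta = np.degrees(np.arctan2(cent[:, 0], cent[:, 1])) % 360.0
            assert np.allclose(theta, coarse_mesh.zonule_theta[s], atol=1e-9)
            assert np.all((coarse_mesh.zonule_theta[s] >= 0) & (coarse_mesh.zonule_theta[s] < 360))

    def test_mirror_symmetry_of_node_cloud(self, coarse_mesh):
        """Non-oval geometry maps onto itself under x -> -x reflection."""
        pts = coarse_mesh.nodes
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        tree = cKDTree(pts)
        d, _ = tree.query(mirrored)
        assert d.max() < 1e-9

    def test_capsule_area_matches_revolved_contour(self, profile, coarse_mesh):
        """Capsule facet area equals the analytic revolution surface area."""
        area = coarse_mesh.tri_areas(coarse_mesh.capsule_tris).sum()
        exact = 0.0
        for cap in profile.cortex_caps:
            r = np.linspace(0, profile.equator_radius, 20000)
            xi = cap.xi(r)
            ds = np.hypot(np.diff(r), np.diff(xi))
            exact += float(np.sum(2 * np.pi * 0.5 * (r[1:] + r[:-1]) * ds))
        assert area == pytest.approx(exact, rel=0.03)

    def test_zonule_inner_edges_tied_to_capsule(self, coarse_mesh):
        """Every tie slave is coincident with the centroid of its masters."""
        for tie in coarse_mesh.ties:
            target = (coarse_mesh.nodes[tie.masters] * tie.weights[:, None]).sum(axis=0)
            slave = coarse_mesh.nodes[tie.slave]
            # zero-width rings: exact coincidence; bands: same angular station
            assert np.hypot(slave[0] - target[0], slave[1] - target[1]) < 0.5

    def test_zero_width_ring_ties_are_identity(self, coarse_mesh):
        for tie in coarse_mesh.ties:
            assert len(tie.masters) == 1
            assert np.allclose(coarse_mesh.nodes[tie.slave], coarse_mesh.nodes[tie.masters[0]])

    def test_band_ties_span_the_band(self, profile):
        cx = build_complex(profile, GeometryParams.from_variants("Initial", "Band4"))
        mesh = generate_mesh(cx, target_edge_length=1.7, n_theta=24)
        multi = [t for t in mesh.ties if len(t.masters) > 1]
        assert multi, "Band4 should produce distributed ties"
        for tie in multi:
            assert np.isclose(tie.weights.sum(), 1.0)

    def test_invalid_inputs_rejected(self, profile):
        cx = build_complex(profile, GeometryParams())
        with pytest.raises(ValueError):
            generate_mesh(cx, target_edge_length=-1.0)
        with pytest.raises(ValueError):
            generate_mesh(cx, target_edge_length=1.0, n_theta=25)

    def test_mesh_is_deterministic(self, profile):
        cx = build_complex(profile, GeometryParams.from_variants("Oval+2.8", "Band2"))
        m1 = generate_mesh(cx, target_edge_length=1.7, n_theta=24)
        m2 = generate_mesh(cx, target_edge_length=1.7, n_theta=24)
        assert np.array_equal(m1.nodes, m2.nodes)
        assert np.array_equal(m1.tets, m2.tets)
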