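"""Finite-element engine tests: assembly, ties, boundary protocol."""

import numpy as np
import pytest

from phakosim import BoundaryProtocol, LensModel, reaction_force_total
from phakosim.materials import neo_hookean_pk2


@pytest.fixture(scope="module")
def model(initial_mesh):
    return LensModel(initial_mesh, protocol=BoundaryProtocol(gravity=False))


class TestAssembly:
    def test_reference_state_is_in_equilibrium(self, model):
        f, _ = model.assemble(np.zeros(3 * model.mesh.n_nodes), want_K=False)
        assert np.abs(f).max() < 1e-14

    def test_rigid_translation_produces_no_forces(self, model):
        """Zero-strain motion: no internal forces, hence no tie forces."""
        u = np.tile([0.3, -0.2, 0.5], model.mesh.n_nodes)
        f, _ = model.assemble(u, want_K=False)
        assert np.abs(f).max() < 1e-10

    def test_affine_field_reproduces_constant_stress(self, model):
        """Patch test: an affine displacement yields the closed-form
        constant solid stress in every tetrahedron."""
        grad = np.array([[0.02, 0.01, 0.0], [0.0, -0.015, 0.005], [0.0, 0.0, 0.01]])
        u = (model.mesh.nodes @ grad.T).ravel()
        sigma, _ = model.tet_stress(u)
        F = np.eye(3) + grad
        for region, mat in ((0, model.materials.nucleus), (1, model.materials.cortex)):
            lam, mu = mat.lame
            S, _, _ = neo_hookean_pk2((F.T @ F)[None], np.array([lam]), np.array([mu]))
            expected = F @ S[0] @ F.T / np.linalg.det(F)
            got = sigma[model.mesh.tet_region == region]
            assert np.abs(got - expected).max() < 1e-8

    def test_tangent_matches_finite_differences(self, model):
        rng = np.random.default_rng(3)
        n = 3 * model.mesh.n_nodes
        u = 1e-3 * rng.standard_normal(n)
        _, K = model.assemble(u)
        h = 1e-6
        for i in rng.integers(0, n, 5):
            du = np.zeros(n)
            du[i] = h
            fp, _ = model.assemble(u + du, want_K=False)
            fm, _ = model.assemble(u - du, want_K=False)
            col = (fp - fm) / (2 * h)
            ref = np.abs(K[:, int(i)].toarray().ravel()).max()
            assert np.abs(col - K[:, int(i)].toarray().ravel()).max() <= 1e-5 * max(ref, 1e-8)

    def test_tie_transform_reproduces_master_average(self, model):
        rng = np.random.default_rng(5)
        q = rng.standard_normal(model._nred)
        u = (model._T @ q).reshape(-1, 3)
        for tie in model.mesh.ties:
            target = (u[tie.masters] * tie.weights[:, None]).sum(axis=0)
            assert np.allclose(u[tie.slave], target, atol=1e-12)


class TestProtocol:
    def test_null_load_gives_null_response(self, initial_mesh):
        model = LensModel(initial_mesh, protocol=BoundaryProtocol(delta_z=0.0, n_steps=1))
        result = model.solve()
        assert np.abs(result.final.u).max() < 1e-10
        assert reaction_force_total(result)["total"] == pytest.approx(0.0, abs=1e-8)

    def test_invalid_protocol_rejected(self):
        with pytest.raises(ValueError):
            BoundaryProtocol(delta_z=-0.1)
        with pytest.raises(ValueError):
            BoundaryProtocol(n_steps=0)
        with pytest.raises(ValueError):
            BoundaryProtocol(zonule_constraint="nonsense")

    def test_step_count_and_labels(self, healthy_run):
        _, result, _ = healthy_run
        labels = [s.label for s in result.steps]
        assert labels[-1] == "step6"
        assert result.baseline.stretch == 0.0
        assert len(result.stretch_steps) == 7  # baseline + six loading steps

    def test_reaction_force_is_tensile_and_grows(self, healthy_run):
        """Radial reactions are positive (tension) and grow with stretch."""
        _, result, _ = healthy_run
        base = result.baseline_index
        totals = [
            reaction_force_total(result, step=i)["total"]
            for i in range(base + 1, len(result.steps))
        ]
        assert all(t > 0 for t in totals)
        assert all(b > a for a, b in zip(totals, totals[1:]))

    def test_external_work_increases_during_stretch(self, healthy_run):
        """Displacement-controlled stretching does positive external work."""
        model, result, _ = healthy_run
        mesh = model.mesh
        base = result.baseline_index
        work = 0.0
        works = []
        prev = result.steps[base]
        for sr in result.steps[base + 1:]:
            for s in mesh.zonule_tris:
                outer = mesh.node_sets[f"zonule_outer_{s}"]
                du = sr.u[outer] - prev.u[outer]
                f_avg = 0.5 * (sr.reactions[s] + prev.reactions[s])
                work += float(np.sum(f_avg * du))
            works.append(work)
            prev = sr
        assert works[0] > 0
        assert all(b > a for a, b in zip(works, works[1:]))

    def test_axisymmetric_solution_invariant_under_quarter_turn(self, initial_mesh):
        """Healthy non-oval model without gravity: the response is invariant
        under a quarter turn about the optical axis.

        The prism-to-tetrahedron splitting pattern is not rotation-periodic
        and parts of the capsule/jelly system carry nearly-flat energy
        directions, so pointwise displacements are only loosely pinned;
        sector-aggregated reactions are the well-conditioned observable and
        must agree tightly across quadrants.
        """
        model = LensModel(initial_mesh, protocol=BoundaryProtocol(gravity=False))
        result = model.solve()
        mesh = model.mesh
        sr = result.final
        quarter = mesh.n_theta // 4
        for s, R in sr.reactions.items():
            outer = mesh.node_sets[f"zonule_outer_{s}"]
            rad = np.einsum("ni,ni->n", R[:, :2], model.radial_dir[outer][:, :2])
            quads = rad.reshape(4, quarter).sum(axis=1)
            assert np.abs(quads - quads[0]).max() <= 2e-2 * np.abs(quads).max()
        # the geometric node cloud itself is exactly quarter-turn periodic
        from scipy.spatial import cKDTree

        Q = np.array([[0.0, 1.0, 0.0], [-1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        d, _ = cKDTree(mesh.nodes).query(mesh.nodes @ Q.T)
        assert d.max() < 1e-8

    def test_doubling_membrane_thickness_doubles_force(self, initial_mesh):
        """Linear regime: reaction scales with membrane thickness within 5%."""
        totals = []
        for scale in (1.0, 2.0):
            model = LensModel(
                initial_mesh,
                protocol=BoundaryProtocol(delta_z=0.02, n_steps=1, gravity=False),
                zonule_thickness_um={s: 10.0 * scale for s in ("ZA", "ZE", "ZP")},
                capsule_thickness_um=20.0 * scale,
            )
            totals.append(reaction_force_total(model.solve())["total"])
        assert totals[1] / totals[0] == pytest.approx(2.0, rel=0.05)

    def test_refinement_consistency(self, smoke_config, healthy_run):
        """Coarse-to-mid mesh refinement changes the key outputs moderately
        (a consistency check at the working resolutions)."""
        from phakosim.optics import compute_metrics
        from phakosim.study import MESH_PRESETS, build_base_mesh
        from dataclasses import replace

        _, _, rec_coarse = healthy_run
        ci_mesh = build_base_mesh(replace(smoke_config, mesh_preset="ci"))
        model = LensModel(ci_mesh, protocol=BoundaryProtocol(gravity=True))
        rec_ci = compute_metrics(model, model.solve())
        assert rec_ci.zonular_force_mn == pytest.approx(rec_coarse.zonular_force_mn, rel=0.10)
        assert rec_ci.delta_radius_pct == pytest.approx(rec_coarse.delta_radius_pct, rel=0.10)
        assert rec_ci.delta_thickness_pct == pytest.approx(
            rec_coarse.delta_thickness_pct, rel=0.10
        )
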