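"""Constitutive-model unit and property tests."""

import numpy as np
import pytest
from scipy.optimize import brentq

from phakosim.materials import (
    GRAVITY_M_S2,
    HGOParams,
    IsotropicElastic,
    hgo_energy,
    hgo_membrane_pk2,
    hgo_pk2,
    hgo_stress,
    linear_elastic_stress,
    membrane_plane_stress,
    neo_hookean_pk2,
    svk_membrane_pk2,
)

RNG = np.random.default_rng(42)
A0 = np.array([1.0, 0.0, 0.0])


def random_F(scale=0.1):
    F = np.eye(3) + scale * RNG.standard_normal((3, 3))
    if np.linalg.det(F) <= 0.1:
        F = np.eye(3) + 0.02 * RNG.standard_normal((3, 3))
    return F


def numeric_pk2(C, params, a0, h=1e-6):
    S = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            dC = np.zeros((3, 3))
            dC[i, j] += 0.5 * h
            dC[j, i] += 0.5 * h
            S[i, j] = 2 * (hgo_energy(C + dC, params, a0) - hgo_energy(C - dC, params, a0)) / (2 * h)
    return S


class TestIsotropicElastic:
    def test_zero_strain_gives_zero_stress(self):
        mat = IsotropicElastic(1.0, 0.3)
        assert np.allclose(linear_elastic_stress(np.zeros((3, 3)), mat), 0.0)

    def test_uniaxial_nu_zero(self):
        mat = IsotropicElastic(1.0, 0.0)  # 1 kPa expressed in its own unit
        eps = np.diag([0.01, 0.0, 0.0])
        sigma = linear_elastic_stress(eps, mat)
        assert sigma[0, 0] == pytest.approx(0.01)
        assert abs(sigma[1, 1]) < 1e-15

    def test_hydrostatic_pressure_matches_bulk_modulus(self):
        mat = IsotropicElastic(1.0, 0.47)
        e = 1e-3
        sigma = linear_elastic_stress(e * np.eye(3), mat)
        pressure = np.trace(sigma) / 3.0
        assert pressure == pytest.approx(mat.bulk_modulus * 3 * e, rel=1e-12)

    def test_invalid_poisson_rejected(self):
        with pytest.raises(ValueError):
            IsotropicElastic(1.0, 0.5)


class TestHGO:
    def test_reference_state_stress_free(self):
        p = HGOParams()
        state = hgo_stress(np.eye(3), p, A0)
        assert np.allclose(state.cauchy_stress, 0.0, atol=1e-14)
        assert state.energy_density == pytest.approx(0.0, abs=1e-14)

    @pytest.mark.parametrize("scale", [0.02, 0.08, 0.15])
    def test_stress_is_energy_gradient(self, scale):
        """S = 2 dPsi/dC to 1e-6 relative at random admissible states."""
        p = HGOParams(tension_only=False)
        for _ in range(5):
            F = random_F(scale)
            C = F.T @ F
            S = hgo_pk2(C, p, A0)
            S_num = numeric_pk2(C, p, A0)
            assert np.abs(S - S_num).max() <= 1e-6 * max(np.abs(S).max(), 1e-6)

    def test_kappa_third_is_isotropic(self):
        p = HGOParams(kappa=1.0 / 3.0, tension_only=False)
        F = random_F(0.1)
        C = F.T @ F
        b0 = RNG.standard_normal(3)
        b0 /= np.linalg.norm(b0)
        assert hgo_energy(C, p, A0) == pytest.approx(hgo_energy(C, p, b0), rel=1e-12)

    def test_k1_zero_reduces_to_ground_matrix(self):
        """Without fibres only the neo-Hookean + volumetric part remains."""
        p = HGOParams(k1=1e-30)
        F = random_F(0.1)
        C = F.T @ F
        J = np.sqrt(np.linalg.det(C))
        Cinv = np.linalg.inv(C)
        I1 = np.trace(C)
        S_expected = (
            2 * p.c10 * J ** (-2 / 3) * (np.eye(3) - I1 / 3 * Cinv)
            + (1 / p.d1) * (J * J - 1) * Cinv
        )
        assert np.allclose(hgo_pk2(C, p, A0), S_expected, rtol=1e-10, atol=1e-12)

    def test_objectivity(self):
        """Psi(QF) = Psi(F) for random rotations Q."""
        p = HGOParams(tension_only=False)
        F = random_F(0.1)
        from scipy.spatial.transform import Rotation

        for seed in range(4):
            Q = Rotation.random(random_state=seed).as_matrix()
            C1 = F.T @ F
            QF = Q @ F
            C2 = QF.T @ QF
            assert hgo_energy(C2, p, A0) == pytest.approx(hgo_energy(C1, p, A0), rel=1e-12)

    def test_tension_only_switch(self):
        """Fibre compression leaves only the ground-matrix response."""
        p_on = HGOParams(tension_only=True)
        p_off = HGOParams(k1=1e-30)
        F = np.diag([0.9, 1.02, 1.02])  # fibre shortened
        C = F.T @ F
        Ebar = p_on.kappa * (np.linalg.det(C) ** (-1 / 3) * np.trace(C) - 3) + (
            1 - 3 * p_on.kappa
        ) * (np.linalg.det(C) ** (-1 / 3) * C[0, 0] - 1)
        assert Ebar < 0
        assert np.allclose(hgo_pk2(C, p_on, A0), hgo_pk2(C, p_off, A0), atol=1e-12)

    def test_uniaxial_fiber_stretch_matches_independent_solve(self):
        """Incompressible-style uniaxial stretch vs an independent 1D solve.

        The transverse stretch is found with brentq on the analytically
        independent S22 = 0 condition evaluated through the energy gradient.
        """
        p = HGOParams()
        lam = 1.1

        def s22(mu):
            F = np.diag([lam, mu, mu])
            C = F.T @ F
            return numeric_pk2(C, p, A0)[1, 1]

        mu = brentq(s22, 0.5, 1.2, xtol=1e-12)
        F = np.diag([lam, mu, mu])
        state = hgo_stress(F, p, A0)
        C = F.T @ F
        S_num = numeric_pk2(C, p, A0)
        sigma_num = F @ S_num @ F.T / np.linalg.det(F)
        assert np.allclose(state.cauchy_stress, sigma_num, rtol=1e-5, atol=1e-10)
        assert abs(state.cauchy_stress[1, 1]) < 1e-7


class TestMembranePlaneStress:
    def test_identity_gives_zero_resultant(self):
        N = membrane_plane_stress(np.eye(2), HGOParams(), 10.0)
        assert np.allclose(N, 0.0, atol=1e-12)

    def test_resultant_scales_linearly_with_thickness(self):
        F2 = np.diag([1.05, 1.0])
        N10 = membrane_plane_stress(F2, HGOParams(), 10.0)
        N5 = membrane_plane_stress(F2, HGOParams(), 5.0)
        assert np.allclose(N10, 2.0 * N5, rtol=1e-12)

    def test_plane_stress_matches_3d_oracle(self):
        """Thickness stretch from the 2D condensation equals an independent
        root solve on the full 3D stress, and the in-plane stress matches."""
        p = HGOParams()
        F2 = np.array([[1.05, 0.01], [0.0, 0.99]])
        C2 = F2.T @ F2

        def sigma33(lam3):
            F = np.zeros((3, 3))
            F[:2, :2] = F2
            F[2, 2] = lam3
            return hgo_stress(F, p, A0).cauchy_stress[2, 2]

        lam3 = brentq(sigma33, 0.5, 1.5, xtol=1e-14)
        S2, c33, _ = hgo_membrane_pk2(C2, p, np.array([1.0, 0.0]))
        assert np.sqrt(c33[()]) == pytest.approx(lam3, rel=1e-8)
        F3 = np.zeros((3, 3))
        F3[:2, :2] = F2
        F3[2, 2] = lam3
        S3 = hgo_pk2(F3.T @ F3, p, A0)
        assert np.allclose(S2, S3[:2, :2], rtol=1e-8)

    def test_tangent_positive_definite_in_tension(self):
        """In-plane tangent of the condensed membrane law under tension."""
        p = HGOParams()
        C2 = np.diag([1.2, 1.05])
        h = 1e-6
        a0 = np.array([1.0, 0.0])
        K = np.zeros((3, 3))  # Voigt (11, 22, 12)
        idx = [(0, 0), (1, 1), (0, 1)]
        for col, (i, j) in enumerate(idx):
            dC = np.zeros((2, 2))
            dC[i, j] += 0.5 * h
            dC[j, i] += 0.5 * h
            Sp, _, _ = hgo_membrane_pk2(C2 + dC, p, a0)
            Sm, _, _ = hgo_membrane_pk2(C2 - dC, p, a0)
            dS = (Sp - Sm) / h
            K[:, col] = [dS[0, 0], dS[1, 1], dS[0, 1]]
        assert np.all(np.linalg.eigvalsh(0.5 * (K + K.T)) > 0)


class TestSolidLaws:
    def test_neo_hookean_reduces_to_hooke_at_small_strain(self):
        lam, mu = IsotropicElastic(1.0, 0.47).lame
        eps = 1e-6 * np.diag([1.0, -0.3, 0.2])
        F = np.eye(3) + eps
        S, _, _ = neo_hookean_pk2(F.T @ F, np.array(lam), np.array(mu))
        hooke = lam * np.trace(eps) * np.eye(3) + 2 * mu * eps
        assert np.allclose(S, hooke, atol=1e-10)

    def test_svk_membrane_energy_consistency(self):
        mat = IsotropicElastic(1.5, 0.47)
        E2 = np.array([[0.02, 0.005], [0.005, -0.01]])
        S2, psi = svk_membrane_pk2(E2, mat)
        assert psi == pytest.approx(0.5 * np.sum(S2 * E2))


def test_body_force_density_units():
    from phakosim.materials import body_force_density

    # 1000 kg/m^3 weighs 9.81e-6 N per mm^3
    assert body_force_density(1000.0) == pytest.approx(GRAVITY_M_S2 * 1e-6)
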