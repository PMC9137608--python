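"""Constitutive models for the lens complex.

Internal unit system: mm - N - MPa (1 N/mm^2 = 1 MPa). Densities are stored
in kg/m^3 and converted to body-force densities (N/mm^3) where needed.

Two material classes cover the whole model:

* nucleus, cortex and capsular bag: isotropic, quasi-incompressible
  elasticity. The solids enter the total-Lagrangian formulation through a
  compressible neo-Hookean energy (stable in compression, linearising to
  Hooke's law with the given constants); the capsule membrane uses the
  plane-stress Saint Venant-Kirchhoff form.
* zonular fibres: Holzapfel-Gasser-Ogden (HGO) fibre-reinforced
  hyperelasticity with the fibre family aligned with the zonule's length
  axis and dispersion parameter kappa, with the standard tension-only
  switch on the exponential fibre term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IsotropicElastic",
    "HGOParams",
    "StressState",
    "GRAVITY_M_S2",
    "linear_elastic_stress",
    "hgo_energy",
    "hgo_pk2",
    "hgo_stress",
    "membrane_plane_stress",
    "hgo_membrane_pk2",
]

GRAVITY_M_S2 = 9.81


def body_force_density(density_kg_m3: float) -> float:
    """Weight per unit volume in N/mm^3 for a density given in kg/m^3."""
    return density_kg_m3 * GRAVITY_M_S2 * 1e-9


@dataclass(frozen=True)
class IsotropicElastic:
    """Isotropic elastic constants (E in MPa, density in kg/m^3)."""

    young_modulus: float
    poisson_ratio: float
    density: float = 0.0

    def __post_init__(self) -> None:
        if self.young_modulus <= 0:
            raise ValueError("Young's modulus must be positive")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError("Poisson ratio must lie in [0, 0.5)")

    @property
    def lame(self) -> tuple[float, float]:
        E, nu = self.young_modulus, self.poisson_ratio
        lam = E * nu / ((1 + nu) * (1 - 2 * nu))
        mu = E / (2 * (1 + nu))
        return lam, mu

    @property
    def bulk_modulus(self) -> float:
        E, nu = self.young_modulus, self.poisson_ratio
        return E / (3 * (1 - 2 * nu))


@dataclass(frozen=True)
class HGOParams:
    """HGO constants for the zonular membranes.

    c10 (MPa) and d1 (1/MPa) govern the isochoric/volumetric ground matrix,
    k1 (MPa) and k2 (-) the exponential fibre stiffening, kappa the in-plane
    fibre dispersion (0 = perfectly aligned, 1/3 = isotropic).
    """

    c10: float = 0.0583
    d1: float = 1.0286
    k1: float = 0.087
    k2: float = 21.75
    kappa: float = 0.3
    density: float = 1000.0
    tension_only: bool = True
    # Number of coincident fibre families along the zonule axis (the HGO
    # two-family form collapses to one family for a uniaxial ligament).
    n_families: int = 1

    def __post_init__(self) -> None:
        if self.c10 <= 0 or self.d1 <= 0:
            raise ValueError("c10 and d1 must be positive")
        if self.k2 <= 0:
            raise ValueError("k2 must be positive")
        if not (0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12):
            raise ValueError("kappa must lie in [0, 1/3]")


@dataclass
class StressState:
    """Pointwise stress state (Cauchy stress in MPa)."""

    deformation_gradient: np.ndarray
    cauchy_stress: np.ndarray
    energy_density: float


def linear_elastic_stress(strain: np.ndarray, mat: IsotropicElastic) -> np.ndarray:
    """Isotropic Hooke law sigma = lam tr(eps) I + 2 mu eps.

    ``strain`` is a symmetric small-strain tensor (3x3 or batched ...x3x3).
    """
    strain = np.asarray(strain, dtype=float)
    lam, mu = mat.lame
    tr = np.trace(strain, axis1=-2, axis2=-1)
    eye = np.eye(3)
    return lam * tr[..., None, None] * eye + 2 * mu * strain


# ---------------------------------------------------------------------------
# HGO hyperelasticity
# ---------------------------------------------------------------------------


def _hgo_invariants(C: np.ndarray, a0: np.ndarray):
    I1 = np.trace(C, axis1=-2, axis2=-1)
    detC = np.linalg.det(C)
    J = np.sqrt(detC)
    I4 = np.einsum("...i,...ij,...j->...", a0, C, a0)
    return I1, I4, J


def hgo_energy(C: np.ndarray, params: HGOParams, a0: np.ndarray) -> np.ndarray:
    """Strain-energy density Psi(C) per unit reference volume (MPa).

    Psi = c10 (I1bar - 3) + (1/d1)((J^2-1)/2 - ln J)
        + (k1 / 2 k2) (exp(k2 <Ebar>^2) - 1)
    with Ebar = kappa (I1bar - 3) + (1 - 3 kappa)(I4bar - 1) and the Macaulay
    bracket applied when ``tension_only`` is set.
    """
    C = np.asarray(C, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    I1, I4, J = _hgo_invariants(C, a0)
    Jm23 = J ** (-2.0 / 3.0)
    I1b, I4b = Jm23 * I1, Jm23 * I4
    E = params.kappa * (I1b - 3.0) + (1.0 - 3.0 * params.kappa) * (I4b - 1.0)
    if params.tension_only:
        E = np.maximum(E, 0.0)
    psi = (
        params.c10 * (I1b - 3.0)
        + (1.0 / params.d1) * ((J * J - 1.0) / 2.0 - np.log(J))
        + params.n_families * (params.k1 / (2.0 * params.k2)) * np.expm1(params.k2 * E * E)
    )
    return psi


def hgo_pk2(C: np.ndarray, params: HGOParams, a0: np.ndarray) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dPsi/dC (batched-aware)."""
    C = np.asarray(C, dtype=float)
    a0 = np.asarray(a0, dtype=float)
    I1, I4, J = _hgo_invariants(C, a0)
    Cinv = np.linalg.inv(C)
    Jm23 = J ** (-2.0 / 3.0)
    I1b, I4b = Jm23 * I1, Jm23 * I4

    eye = np.broadcast_to(np.eye(C.shape[-1]), C.shape)
    # d(I1bar)/dC and d(I4bar)/dC (isochoric projections)
    dI1b = Jm23[..., None, None] * (eye - (I1 / 3.0)[..., None, None] * Cinv)
    M = a0[..., :, None] * a0[..., None, :]
    dI4b = Jm23[..., None, None] * (M - (I4 / 3.0)[..., None, None] * Cinv)

    S = 2.0 * params.c10 * dI1b
    S = S + ((1.0 / params.d1) * (J * J - 1.0))[..., None, None] * Cinv

    E = params.kappa * (I1b - 3.0) + (1.0 - 3.0 * params.kappa) * (I4b - 1.0)
    active = E > 0.0 if params.tension_only else np.ones_like(E, dtype=bool)
    fac = np.where(
        active, 2.0 * params.n_families * params.k1 * E * np.exp(params.k2 * E * E), 0.0
    )
    S = S + fac[..., None, None] * (
        params.kappa * dI1b + (1.0 - 3.0 * params.kappa) * dI4b
    )
    return S


def hgo_stress(F: np.ndarray, params: HGOParams, a0: np.ndarray) -> StressState:
    """Cauchy stress and energy density for a 3D deformation gradient."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("deformation gradient must have positive determinant")
    C = np.swapaxes(F, -1, -2) @ F
    S = hgo_pk2(C, params, a0)
    sigma = (F @ S @ np.swapaxes(F, -1, -2)) / J[..., None, None]
    psi = hgo_energy(C, params, a0)
    return StressState(F, sigma, psi)


# ---------------------------------------------------------------------------
# Plane-stress membrane condensation
# ---------------------------------------------------------------------------


def _hgo_s33(C2: np.ndarray, c33: np.ndarray, params: HGOParams, a0_2: np.ndarray):
    """Normal PK2 component S33 for a block-diagonal C = diag(C2, c33).

    The fibre lies in the membrane plane, so M33 = 0 and Cinv is block
    diagonal with (Cinv)33 = 1/c33.
    """
    trC2 = C2[..., 0, 0] + C2[..., 1, 1]
    detC2 = C2[..., 0, 0] * C2[..., 1, 1] - C2[..., 0, 1] * C2[..., 1, 0]
    I1 = trC2 + c33
    J2 = detC2 * c33
    J = np.sqrt(J2)
    I4 = np.einsum("...i,...ij,...j->...", a0_2, C2, a0_2)
    Jm23 = J2 ** (-1.0 / 3.0)
    I1b, I4b = Jm23 * I1, Jm23 * I4
    inv33 = 1.0 / c33

    dI1b_33 = Jm23 * (1.0 - (I1 / 3.0) * inv33)
    dI4b_33 = Jm23 * (0.0 - (I4 / 3.0) * inv33)

    E = params.kappa * (I1b - 3.0) + (1.0 - 3.0 * params.kappa) * (I4b - 1.0)
    active = E > 0.0 if params.tension_only else np.ones_like(E, dtype=bool)
    fac = np.where(
        active, 2.0 * params.n_families * params.k1 * E * np.exp(params.k2 * E * E), 0.0
    )

    S33 = (
        2.0 * params.c10 * dI1b_33
        + (1.0 / params.d1) * (J2 - 1.0) * inv33
        + fac * (params.kappa * dI1b_33 + (1.0 - 3.0 * params.kappa) * dI4b_33)
    )
    return S33


def solve_thickness_stretch(
    C2: np.ndarray,
    params: HGOParams,
    a0_2: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 60,
) -> np.ndarray:
    """Solve S33(c33) = 0 for the squared thickness stretch (vectorised Newton).

    Starts from the incompressible guess c33 = 1/det(C2); the derivative is
    taken by central differences, with step halving if a trial leaves the
    admissible range c33 > 0.
    """
    C2 = np.asarray(C2, dtype=float)
    detC2 = C2[..., 0, 0] * C2[..., 1, 1] - C2[..., 0, 1] * C2[..., 1, 0]
    if np.any(detC2 <= 0):
        raise ValueError("in-plane metric must be positive definite")
    c33 = 1.0 / detC2
    for _ in range(max_iter):
        f = _hgo_s33(C2, c33, params, a0_2)
        if np.all(np.abs(f) < tol * (1.0 / params.d1)):
            break
        h = 1e-7 * np.maximum(c33, 1e-3)
        df = (_hgo_s33(C2, c33 + h, params, a0_2) - _hgo_s33(C2, c33 - h, params, a0_2)) / (
            2.0 * h
        )
        step = np.where(np.abs(df) > 0, f / np.where(df == 0, 1.0, df), 0.0)
        new = c33 - step
        # keep iterates admissible
        for _ in range(30):
            bad = new <= 0.1 * c33
            if not np.any(bad):
                break
            step = np.where(bad, 0.5 * step, step)
            new = c33 - step
        c33 = new
    return c33


def hgo_membrane_pk2(C2: np.ndarray, params: HGOParams, a0_2: np.ndarray):
    """In-plane PK2 stress (2x2) under the plane-stress condition S33 = 0.

    Returns ``(S2, c33, psi)`` where c33 is the squared thickness stretch and
    psi the energy density at the condensed state. Because S33 vanishes, the
    total derivative of the condensed energy w.r.t. C2 equals the partial
    derivative, so S2 is simply the in-plane block of the 3D stress.
    """
    C2 = np.asarray(C2, dtype=float)
    a0_2 = np.broadcast_to(np.asarray(a0_2, dtype=float), C2.shape[:-2] + (2,))
    c33 = solve_thickness_stretch(C2, params, a0_2)
    C3 = np.zeros(C2.shape[:-2] + (3, 3))
    C3[..., :2, :2] = C2
    C3[..., 2, 2] = c33
    a0_3 = np.zeros(C2.shape[:-2] + (3,))
    a0_3[..., :2] = a0_2
    S3 = hgo_pk2(C3, params, a0_3)
    psi = hgo_energy(C3, params, a0_3)
    return S3[..., :2, :2], c33, psi


def membrane_plane_stress(
    F_surface: np.ndarray, params: HGOParams, thickness_um: float
) -> np.ndarray:
    """In-plane force resultants (N/mm) of an HGO membrane.

    ``F_surface`` is the 2x2 in-plane deformation gradient (fibre direction is
    the local first axis). The through-thickness stretch is solved so that
    the normal Cauchy stress vanishes; the resultant is the in-plane Cauchy
    stress times the current thickness, hence linear in the reference
    thickness at fixed stretch.
    """
    F2 = np.asarray(F_surface, dtype=float)
    if F2.shape[-2:] == (3, 2):
        C2 = np.swapaxes(F2, -1, -2) @ F2
    elif F2.shape[-2:] == (2, 2):
        C2 = np.swapaxes(F2, -1, -2) @ F2
    else:
        raise ValueError("F_surface must be 2x2 or 3x2")
    a0_2 = np.array([1.0, 0.0])
    S2, c33, _ = hgo_membrane_pk2(C2, params, a0_2)
    lam3 = np.sqrt(c33)
    detC2 = C2[..., 0, 0] * C2[..., 1, 1] - C2[..., 0, 1] * C2[..., 1, 0]
    J = np.sqrt(detC2) * lam3
    if F2.shape[-2:] == (2, 2):
        sigma2 = (F2 @ S2 @ np.swapaxes(F2, -1, -2)) / J[..., None, None]
    else:
        sigma2 = None
    t_cur_mm = thickness_um * 1e-3 * lam3
    if sigma2 is None:
        raise ValueError("resultants require the 2x2 in-plane deformation gradient")
    return sigma2 * t_cur_mm[..., None, None]


# Plane-stress Saint Venant-Kirchhoff (capsular bag membrane) ---------------


def svk_membrane_pk2(E2: np.ndarray, mat: IsotropicElastic):
    """Plane-stress SVK: S2 = C_ps : E2 on the Green strain, plus energy."""
    E2 = np.asarray(E2, dtype=float)
    E, nu = mat.young_modulus, mat.poisson_ratio
    fac = E / (1.0 - nu * nu)
    tr = E2[..., 0, 0] + E2[..., 1, 1]
    S2 = fac * ((1.0 - nu) * E2 + nu * tr[..., None, None] * np.eye(2))
    psi = 0.5 * np.einsum("...ij,...ij->...", S2, E2)
    return S2, psi


def svk_membrane_moduli(mat: IsotropicElastic) -> np.ndarray:
    """Constant plane-stress tangent C_ps[i,j,k,l] for the SVK membrane."""
    E, nu = mat.young_modulus, mat.poisson_ratio
    fac = E / (1.0 - nu * nu)
    D = np.zeros((2, 2, 2, 2))
    eye = np.eye(2)
    for i in range(2):
        for j in range(2):
            for k in range(2):
                for l in range(2):
                    D[i, j, k, l] = fac * (
                        nu * eye[i, j] * eye[k, l]
                        + 0.5 * (1 - nu) * (eye[i, k] * eye[j, l] + eye[i, l] * eye[j, k])
                    )
    return D


def neo_hookean_pk2(C: np.ndarray, lam, mu):
    """Compressible neo-Hookean PK2 stress S = mu (I - Cinv) + lam ln J Cinv.

    Energy: Psi = mu/2 (I1 - 3) - mu ln J + lam/2 (ln J)^2. Linearises to
    isotropic Hooke's law with Lame constants (lam, mu) at small strain and,
    unlike Saint Venant-Kirchhoff, remains stable under finite compression —
    which matters for the near-fluid lens substance, whose stress levels
    exceed its shear modulus.
    """
    C = np.asarray(C, dtype=float)
    Cinv = np.linalg.inv(C)
    lnJ = 0.5 * np.log(np.linalg.det(C))
    eye = np.eye(3)
    lam = np.asarray(lam)
    mu = np.asarray(mu)
    S = mu[..., None, None] * (eye - Cinv) + (lam * lnJ)[..., None, None] * Cinv
    return S, lnJ, Cinv


def neo_hookean_tangent(Cinv: np.ndarray, lnJ, lam, mu) -> np.ndarray:
    """Material tangent 2 dS/dC of the compressible neo-Hookean law."""
    lam = np.asarray(lam)
    mu = np.asarray(mu)
    CiCi = np.einsum("...pq,...rs->...pqrs", Cinv, Cinv)
    sym = 0.5 * (
        np.einsum("...pr,...qs->...pqrs", Cinv, Cinv)
        + np.einsum("...ps,...qr->...pqrs", Cinv, Cinv)
    )
    return lam[..., None, None, None, None] * CiCi + 2.0 * (
        (mu - lam * lnJ)[..., None, None, None, None]
    ) * sym
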