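"""Nonlinear static finite-element engine for the lens complex.

Total-Lagrangian formulation with:

* 4-node constant-strain tetrahedra (nucleus, cortex) with a compressible
  neo-Hookean law that linearises to the prescribed elastic constants;
* 3-node membrane triangles for the capsular bag (plane-stress SVK with a
  compression/wrinkling relaxation and discrete-hinge bending) and for the
  zonular sets (HGO with plane-stress thickness condensation);
* multipoint ties from zonular inner edges to capsular anchorage bands,
  eliminated exactly through a sparse transformation of the DOF vector;
* displacement-controlled incremental loading (radial stretch of the
  zonular outer edges) with Newton iteration, a backtracking safeguard,
  factorisation reuse, and automatic increment bisection on failure.

Assembly is vectorised over elements; the tangents of the solid elements
and of the plain capsule membrane are analytic (material + geometric), the
tangents of the HGO membranes, the wrinkling-relaxed capsule and the
bending hinges are central differences of their analytic forces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .materials import (
    HGOParams,
    IsotropicElastic,
    body_force_density,
    hgo_membrane_pk2,
    neo_hookean_pk2,
    neo_hookean_tangent,
    svk_membrane_pk2,
)
from .mesh import FEMesh

__all__ = [
    "BoundaryProtocol",
    "Materials",
    "default_materials",
    "LensModel",
    "SimulationResult",
    "run_disaccommodation",
    "reaction_force_total",
]


@dataclass(frozen=True)
class BoundaryProtocol:
    """Loading protocol for the disaccommodation simulation.

    ``delta_z`` (mm) is the prescribed radial displacement of the zonular
    outer edges, applied in ``n_steps`` equal increments. With gravity on, a
    gravity-equilibration step precedes the stretch and the post-gravity
    state is the baseline for all variation metrics.
    """

    delta_z: float = 0.5
    n_steps: int = 6
    gravity: bool = False
    gravity_direction: tuple[float, float, float] = (0.0, -1.0, 0.0)  # superior -> inferior
    # Scope of the radial-only zonular constraint: "outer_edge" restricts
    # only the loaded ciliary edge; "anterior_posterior" additionally
    # restricts the ZA/ZP capsular insertion bands (and any interior zonular
    # nodes) to radial motion; "all" restricts every insertion band.
    zonule_constraint: str = "anterior_posterior"
    n_gravity_steps: int = 2  # gravity ramp sub-increments (soft interior sags nonlinearly)
    # The lens is immersed in aqueous/vitreous humour, so the static body
    # force is the immersed (buoyancy-corrected) weight: (rho - rho_fluid) g.
    # Set to 0.0 to load the full tissue weight instead.
    buoyancy_density: float = 1006.0  # kg/m^3

    def __post_init__(self) -> None:
        if self.delta_z < 0:
            raise ValueError("delta_z must be non-negative")
        if self.n_steps < 1:
            raise ValueError("n_steps must be at least 1")
        if self.zonule_constraint not in ("outer_edge", "anterior_posterior", "all"):
            raise ValueError(
                "zonule_constraint must be 'outer_edge', 'anterior_posterior' or 'all'"
            )


@dataclass
class Materials:
    nucleus: IsotropicElastic
    cortex: IsotropicElastic
    capsule: IsotropicElastic
    zonule: HGOParams


def default_materials() -> Materials:
    """Material constants of the lens complex (MPa, kg/m^3)."""
    return Materials(
        nucleus=IsotropicElastic(0.82e-3, 0.47, 1099.0),  # E_N = 0.82 kPa
        cortex=IsotropicElastic(0.04e-3, 0.47, 1099.0),  # E_C = 0.04 kPa
        capsule=IsotropicElastic(1.5, 0.47, 1099.0),  # E_CB = 1.5 MPa
        zonule=HGOParams(),
    )


@dataclass
class StepResult:
    label: str
    u: np.ndarray  # (N, 3) nodal displacements, mm
    reactions: dict[str, np.ndarray]  # set -> (n_outer, 3) nodal reactions, N
    gravity_scale: float
    stretch: float  # applied outer-edge displacement, mm
    iterations: int
    residual: float


@dataclass
class SimulationResult:
    mesh: FEMesh
    protocol: BoundaryProtocol
    steps: list[StepResult] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    @property
    def baseline_index(self) -> int:
        """Index of the reference state (post-gravity, pre-stretch)."""
        idx = [i for i, s in enumerate(self.steps) if s.stretch == 0.0]
        return idx[-1] if idx else 0

    @property
    def baseline(self) -> StepResult:
        """Reference state for variation metrics (post-gravity, pre-stretch)."""
        return self.steps[self.baseline_index]

    @property
    def stretch_steps(self) -> list[StepResult]:
        """Baseline followed by the loading steps (the six-step series)."""
        return self.steps[self.baseline_index:]

    @property
    def final(self) -> StepResult:
        return self.steps[-1]


def _build_hinges(tris: np.ndarray):
    """Interior edges of a triangle surface as hinges (x0, x1, x2, x3).

    (x0, x1) is the shared edge, x2/x3 the opposite vertices of the two
    incident triangles.
    """
    edge_map: dict[tuple[int, int], list[int]] = {}
    for tri in tris:
        a, b, c = (int(v) for v in tri)
        for e, opp in (((a, b), c), ((b, c), a), ((c, a), b)):
            key = (min(e), max(e))
            edge_map.setdefault(key, []).append(opp)
    hinges = []
    for (a, b), opps in edge_map.items():
        if len(opps) == 2:
            hinges.append((a, b, opps[0], opps[1]))
    return np.asarray(hinges, dtype=np.int64)


def _hinge_angles(x: np.ndarray) -> np.ndarray:
    """Signed dihedral angles of hinge node quadruples x (nh, 4, 3)."""
    e = x[:, 1] - x[:, 0]
    nA = np.cross(e, x[:, 2] - x[:, 0])
    nB = np.cross(x[:, 3] - x[:, 0], e)
    ehat = e / np.linalg.norm(e, axis=1, keepdims=True)
    s = np.einsum("ij,ij->i", np.cross(nA, nB), ehat)
    c = np.einsum("ij,ij->i", nA, nB)
    return np.arctan2(s, c)


class _HingeBending:
    """Discrete-shell bending of the capsular bag.

    Energy ½ c_e (theta - theta0)^2 per interior edge with
    c_e = D |e|^2 / (A1 + A2), D = E t^3 / (12 (1 - nu^2)) the plate bending
    stiffness. Rest angles theta0 are taken from the reference surface, so
    the undeformed capsule is moment-free. Angle gradients are evaluated by
    central differences (the angles are cheap, smooth functions of the four
    hinge nodes).
    """

    def __init__(self, nodes: np.ndarray, tris: np.ndarray, D: float):
        self.hinges = _build_hinges(tris)
        x = nodes[self.hinges]
        e = x[:, 1] - x[:, 0]
        A1 = 0.5 * np.linalg.norm(np.cross(e, x[:, 2] - x[:, 0]), axis=1)
        A2 = 0.5 * np.linalg.norm(np.cross(x[:, 3] - x[:, 0], e), axis=1)
        l2 = np.einsum("ij,ij->i", e, e)
        self.c = D * l2 / (A1 + A2)
        self.theta0 = _hinge_angles(x)

    def force(self, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
        """Nodal forces (nh, 4, 3): c (theta - theta0) * grad theta."""
        mom = self.c * (_hinge_angles(x) - self.theta0)
        grad = np.zeros_like(x)
        for a in range(4):
            for i in range(3):
                dx = np.zeros_like(x)
                dx[:, a, i] = h
                grad[:, a, i] = (_hinge_angles(x + dx) - _hinge_angles(x - dx)) / (2 * h)
        return mom[:, None, None] * grad


def _fd_element_tangent(force_fn, x: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Central-difference element tangent K[e,a,i,b,j] = d f_ai / d u_bj."""
    ne, nn, _ = x.shape
    K = np.zeros((ne, nn, 3, nn, 3))
    for b in range(nn):
        for j in range(3):
            dx = np.zeros_like(x)
            dx[:, b, j] = h
            K[:, :, :, b, j] = (force_fn(x + dx) - force_fn(x - dx)) / (2 * h)
    return K


class _MembraneGroup:
    """Precomputed reference data for one family of membrane triangles."""

    def __init__(self, nodes: np.ndarray, tris: np.ndarray, fiber3: np.ndarray | None):
        self.tris = tris
        X = nodes[tris]  # (ne, 3, 3)
        e1 = X[:, 1] - X[:, 0]
        e2 = X[:, 2] - X[:, 0]
        n = np.cross(e1, e2)
        self.area = 0.5 * np.linalg.norm(n, axis=1)
        t1 = e1 / np.linalg.norm(e1, axis=1, keepdims=True)
        nh = n / np.linalg.norm(n, axis=1, keepdims=True)
        t2 = np.cross(nh, t1)
        Dref = np.zeros((len(tris), 2, 2))
        Dref[:, 0, 0] = np.einsum("ei,ei->e", e1, t1)
        Dref[:, 0, 1] = np.einsum("ei,ei->e", e2, t1)
        Dref[:, 1, 1] = np.einsum("ei,ei->e", e2, t2)
        self.invDref = np.linalg.inv(Dref)
        g = np.zeros((len(tris), 3, 2))
        g[:, 1] = self.invDref[:, 0, :]
        g[:, 2] = self.invDref[:, 1, :]
        g[:, 0] = -g[:, 1] - g[:, 2]
        self.g = g
        if fiber3 is not None:
            a = np.stack(
                [np.einsum("ei,ei->e", fiber3, t1), np.einsum("ei,ei->e", fiber3, t2)], axis=1
            )
            norm = np.linalg.norm(a, axis=1, keepdims=True)
            self.a0 = a / np.where(norm > 1e-12, norm, 1.0)
        else:
            self.a0 = None

    def F32(self, x_cur: np.ndarray) -> np.ndarray:
        """In-plane deformation gradient (ne, 3, 2) from current positions."""
        return np.einsum("eai,eaj->eij", x_cur, self.g)


class LensModel:
    """Assembled lens-complex model ready for the disaccommodation run."""

    def __init__(
        self,
        mesh: FEMesh,
        materials: Materials | None = None,
        protocol: BoundaryProtocol | None = None,
        zonule_thickness_um: dict[str, np.ndarray | float] | None = None,
        capsule_thickness_um: float = 20.0,
        rtol: float = 1e-6,
        max_newton: int = 40,
        max_bisections: int = 5,
        capsule_bending: bool = True,
        capsule_wrinkling: bool = True,
        wrinkle_eps: float = 0.02,
        wrinkle_width: float = 5e-4,  # MPa, transition width of the relaxation
        wrinkle_threshold: float = 2e-3,  # MPa, compression at which relaxation engages
    ) -> None:
        self.mesh = mesh
        self.materials = materials or default_materials()
        self.protocol = protocol or BoundaryProtocol()
        self.rtol = rtol
        self.max_newton = max_newton
        self.max_bisections = max_bisections
        self.capsule_bending = capsule_bending
        self.capsule_wrinkling = capsule_wrinkling
        self.wrinkle_eps = wrinkle_eps
        self.wrinkle_width = wrinkle_width
        self.wrinkle_threshold = wrinkle_threshold
        self.capsule_thickness = capsule_thickness_um * 1e-3  # mm
        self.zonule_thickness: dict[str, np.ndarray] = {}
        for s, tris in mesh.zonule_tris.items():
            t = 10.0 if zonule_thickness_um is None else zonule_thickness_um.get(s, 10.0)
            self.zonule_thickness[s] = np.broadcast_to(
                np.asarray(t, dtype=float) * 1e-3, (len(tris),)
            ).copy()
        self._precompute()

    # -- precomputation ----------------------------------------------------

    def _precompute(self) -> None:
        mesh = self.mesh
        X = mesh.nodes[mesh.tets]
        Dm = np.stack([X[:, k] - X[:, 0] for k in (1, 2, 3)], axis=-1)  # (ne,3,3) cols
        vol = np.linalg.det(Dm) / 6.0
        if np.any(vol <= 0):
            bad = int(np.argmin(vol))
            raise ValueError(f"non-positive Jacobian in tetrahedron {bad}")
        invDm = np.linalg.inv(Dm)
        G = np.zeros((len(mesh.tets), 4, 3))
        G[:, 1] = invDm[:, 0, :]
        G[:, 2] = invDm[:, 1, :]
        G[:, 3] = invDm[:, 2, :]
        G[:, 0] = -(G[:, 1] + G[:, 2] + G[:, 3])
        self._tet_G, self._tet_vol = G, vol
        lam_n, mu_n = self.materials.nucleus.lame
        lam_c, mu_c = self.materials.cortex.lame
        self._tet_lam = np.where(mesh.tet_region == 0, lam_n, lam_c)
        self._tet_mu = np.where(mesh.tet_region == 0, mu_n, mu_c)

        self._capsule = _MembraneGroup(mesh.nodes, mesh.capsule_tris, None)
        self._bending = None
        if self.capsule_bending:
            mat = self.materials.capsule
            D = mat.young_modulus * self.capsule_thickness**3 / (
                12.0 * (1.0 - mat.poisson_ratio**2)
            )
            self._bending = _HingeBending(mesh.nodes, mesh.capsule_tris, D)
        self._zonules = {
            s: _MembraneGroup(mesh.nodes, tris, mesh.zonule_fiber_dir[s])
            for s, tris in mesh.zonule_tris.items()
        }

        self._build_dof_map()
        self._build_gravity_load()
        self._ndof = 3 * mesh.n_nodes

    def _build_dof_map(self) -> None:
        """Build the sparse transform u_full = T u_red plus Dirichlet data."""
        mesh = self.mesh
        N = mesh.n_nodes
        kind = np.zeros(N, dtype=np.int8)  # 0 free, 1 slave(tie), 2 radial-only
        slaves = {t.slave: t for t in mesh.ties}
        for s in slaves:
            kind[s] = 1
        radial_nodes: list[int] = []
        mode = self.protocol.zonule_constraint
        if mode in ("all", "anterior_posterior"):
            ring_sets = mesh.zonule_tris if mode == "all" else ("ZA", "ZP")
            for s in mesh.zonule_tris:
                mid = mesh.node_sets.get(f"zonule_mid_{s}")
                if mid is not None:
                    radial_nodes.extend(int(n) for n in mid)
            # capsular insertion bands: the tied inner edges follow these
            # master nodes, so restricting them to radial motion realises
            # the all-nodes reading of the zonular constraint
            for s in ring_sets:
                radial_nodes.extend(int(n) for n in mesh.node_sets[f"attach_band_{s}"])
        for n in radial_nodes:
            if kind[n] == 0:
                kind[n] = 2

        col_of = np.full(3 * N, -1, dtype=np.int64)
        rows, cols, vals = [], [], []
        next_col = 0
        radial_dir = np.zeros((N, 3))
        rad = np.hypot(mesh.nodes[:, 0], mesh.nodes[:, 1])
        ok = rad > 1e-12
        radial_dir[ok, 0] = mesh.nodes[ok, 0] / rad[ok]
        radial_dir[ok, 1] = mesh.nodes[ok, 1] / rad[ok]
        self.radial_dir = radial_dir

        for n in range(N):
            if kind[n] == 0:
                for i in range(3):
                    rows.append(3 * n + i)
                    cols.append(next_col)
                    vals.append(1.0)
                    col_of[3 * n + i] = next_col
                    next_col += 1
            elif kind[n] == 2:
                for i in range(3):
                    rows.append(3 * n + i)
                    cols.append(next_col)
                    vals.append(radial_dir[n, i])
                col_of[3 * n] = next_col  # single radial dof
                next_col += 1
        # slave rows reference the master nodes' reduced columns (masters are
        # either free or radial-only)
        for n, tie in slaves.items():
            for m, w in zip(tie.masters, tie.weights):
                m = int(m)
                if kind[m] == 2:
                    for i in range(3):
                        rows.append(3 * n + i)
                        cols.append(col_of[3 * m])
                        vals.append(float(w) * radial_dir[m, i])
                else:
                    for i in range(3):
                        rows.append(3 * n + i)
                        cols.append(col_of[3 * m + i])
                        vals.append(float(w))
        self._T = sp.csr_matrix(
            (vals, (rows, cols)), shape=(3 * N, next_col)
        )
        self._nred = next_col
        self._col_of = col_of
        self._kind = kind

        # Dirichlet on reduced dofs
        fixed = np.zeros(next_col, dtype=bool)
        for name in ("pole_anterior", "pole_posterior", "nucleus_pole_anterior", "nucleus_pole_posterior"):
            for n in mesh.node_sets[name]:
                fixed[col_of[3 * int(n)]] = True
                fixed[col_of[3 * int(n) + 1]] = True
        self._outer_nodes: dict[str, np.ndarray] = {}
        presc_cols, presc_dirs = [], []
        for s in mesh.zonule_tris:
            outer = mesh.node_sets[f"zonule_outer_{s}"]
            self._outer_nodes[s] = outer
            for n in outer:
                n = int(n)
                for i in range(3):
                    fixed[col_of[3 * n + i]] = True
                    presc_cols.append(col_of[3 * n + i])
                    presc_dirs.append(radial_dir[n, i])
        self._fixed = fixed
        self._free = np.nonzero(~fixed)[0]
        self._presc_cols = np.asarray(presc_cols, dtype=np.int64)
        self._presc_dirs = np.asarray(presc_dirs)

    def _build_gravity_load(self) -> None:
        mesh = self.mesh
        g_dir = np.asarray(self.protocol.gravity_direction, dtype=float)
        g_dir = g_dir / np.linalg.norm(g_dir)
        f = np.zeros((mesh.n_nodes, 3))
        rho0 = self.protocol.buoyancy_density
        rho_n = body_force_density(self.materials.nucleus.density - rho0)
        rho_c = body_force_density(self.materials.cortex.density - rho0)
        w = np.where(mesh.tet_region == 0, rho_n, rho_c) * self._tet_vol / 4.0
        for a in range(4):
            np.add.at(f, mesh.tets[:, a], w[:, None] * g_dir[None, :])
        rho_cb = body_force_density(self.materials.capsule.density - rho0)
        w = rho_cb * self.capsule_thickness * self._capsule.area / 3.0
        for a in range(3):
            np.add.at(f, mesh.capsule_tris[:, a], w[:, None] * g_dir[None, :])
        rho_z = body_force_density(self.materials.zonule.density - rho0)
        for s, grp in self._zonules.items():
            w = rho_z * self.zonule_thickness[s] * grp.area / 3.0
            for a in range(3):
                np.add.at(f, grp.tris[:, a], w[:, None] * g_dir[None, :])
        self._gravity_load = f.ravel()

    # -- element internal forces and tangents -------------------------------

    def _tet_force_K(self, u: np.ndarray, want_K: bool):
        mesh, G, V = self.mesh, self._tet_G, self._tet_vol
        ue = u.reshape(-1, 3)[mesh.tets]  # (ne,4,3)
        F = np.eye(3) + np.einsum("eai,eaj->eij", ue, G)
        detF = np.linalg.det(F)
        if np.any(detF <= 0):
            raise ValueError("inverted solid element during assembly")
        C = np.einsum("eki,ekj->eij", F, F)
        S, lnJ, Cinv = neo_hookean_pk2(C, self._tet_lam, self._tet_mu)
        FS = F @ S
        f_el = V[:, None, None] * np.einsum("eij,eaj->eai", FS, G)
        if not want_K:
            return f_el, None
        Dt = neo_hookean_tangent(Cinv, lnJ, self._tet_lam, self._tet_mu)
        GSG = np.einsum("eai,eij,ebj->eab", G, S, G)
        K = np.einsum("eab,ij->eaibj", GSG, np.eye(3))
        # material part: F_ip Dt_pqrs F_jr G_aq G_bs
        FD = np.einsum("eip,epqrs->eiqrs", F, Dt)
        FDF = np.einsum("eiqrs,ejr->eiqjs", FD, F)
        K += np.einsum("eiqjs,eaq,ebs->eaibj", FDF, G, G)
        K *= V[:, None, None, None, None]
        return f_el, K

    def _capsule_pk2(self, F: np.ndarray) -> np.ndarray:
        """Plane-stress SVK stress of the capsule, with optional wrinkling.

        A membrane cannot sustain compressive in-plane stress: with the
        wrinkling relaxation on, compressive principal values of S2 are
        scaled by ``wrinkle_eps`` (a small residual stiffness that keeps the
        tangent well conditioned). SVK stress and Green strain are coaxial,
        so the relaxation acts in the strain eigenbasis directly.
        """
        mat = self.materials.capsule
        E2 = 0.5 * (np.einsum("eki,ekj->eij", F, F) - np.eye(2))
        if not self.capsule_wrinkling:
            S2, _ = svk_membrane_pk2(E2, mat)
            return S2
        a, b, c = E2[:, 0, 0], E2[:, 1, 1], E2[:, 0, 1]
        mean, d = 0.5 * (a + b), 0.5 * (a - b)
        rad = np.sqrt(d * d + c * c)
        e1, e2 = mean + rad, mean - rad
        Enu, nu = mat.young_modulus, mat.poisson_ratio
        fac = Enu / (1.0 - nu * nu)
        s1 = fac * (e1 + nu * e2)
        s2 = fac * (e2 + nu * e1)
        # Relaxation activates only beyond a small compression threshold, so
        # the response is exactly SVK around the stress-free state (keeps the
        # Newton iteration quadratic under small loads) while deep
        # compression is capped near -s_act with residual slope eps.
        w = self.wrinkle_width
        eps = self.wrinkle_eps
        s_act = self.wrinkle_threshold
        offset = np.logaddexp(0.0, -s_act / w)  # keeps the reference stress-free

        def relax(s):
            return s - (1.0 - eps) * w * (np.logaddexp(0.0, (-s - s_act) / w) - offset)

        s1 = relax(s1)
        s2 = relax(s2)
        phi = 0.5 * np.arctan2(2.0 * c, a - b)
        cs, sn = np.cos(phi), np.sin(phi)
        S2 = np.empty_like(E2)
        S2[:, 0, 0] = s1 * cs * cs + s2 * sn * sn
        S2[:, 1, 1] = s1 * sn * sn + s2 * cs * cs
        S2[:, 0, 1] = (s1 - s2) * cs * sn
        S2[:, 1, 0] = S2[:, 0, 1]
        return S2

    def _capsule_force(self, x: np.ndarray) -> np.ndarray:
        grp = self._capsule
        F = np.einsum("eai,eaj->eij", x, grp.g)
        S2 = self._capsule_pk2(F)
        TA = self.capsule_thickness * grp.area
        return TA[:, None, None] * np.einsum("eij,eaj->eai", F @ S2, grp.g)

    def _capsule_force_K(self, u: np.ndarray, want_K: bool):
        grp = self._capsule
        mat = self.materials.capsule
        x = self.mesh.nodes[grp.tris] + u.reshape(-1, 3)[grp.tris]
        f_el = self._capsule_force(x)
        if not want_K:
            return f_el, None
        if self.capsule_wrinkling:
            return f_el, _fd_element_tangent(self._capsule_force, x)
        F = grp.F32(x)  # (ne,3,2)
        E2 = 0.5 * (np.einsum("eki,ekj->eij", F, F) - np.eye(2))
        S2, _ = svk_membrane_pk2(E2, mat)
        TA = self.capsule_thickness * grp.area
        Enu, nu = mat.young_modulus, mat.poisson_ratio
        c1 = Enu * nu / (1 - nu * nu)
        c2 = Enu / (2 * (1 + nu))
        g = grp.g
        A = np.einsum("eip,eap->eai", F, g)  # (ne,3nodes,3dim)? -> (e,a,i)
        gSg = np.einsum("eap,epq,ebq->eab", g, S2, g)
        gg = np.einsum("eap,ebp->eab", g, g)
        FFt = np.einsum("eip,ejp->eij", F, F)
        K = np.einsum("eab,ij->eaibj", gSg, np.eye(3))
        K += c1 * np.einsum("eai,ebj->eaibj", A, A)
        K += c2 * (np.einsum("eab,eij->eaibj", gg, FFt) + np.einsum("ebi,eaj->eaibj", A, A))
        K *= TA[:, None, None, None, None]
        return f_el, K

    def _zonule_force(self, s: str, x: np.ndarray) -> np.ndarray:
        """Element internal forces of zonular set s at current positions x."""
        grp = self._zonules[s]
        F = np.einsum("eai,eaj->eij", x, grp.g)
        C2 = np.einsum("eki,ekj->eij", F, F)
        S2, _, _ = hgo_membrane_pk2(C2, self.materials.zonule, grp.a0)
        TA = self.zonule_thickness[s] * grp.area
        return TA[:, None, None] * np.einsum("eij,eaj->eai", F @ S2, grp.g)

    def _zonule_force_K(self, s: str, u: np.ndarray, want_K: bool):
        grp = self._zonules[s]
        x = self.mesh.nodes[grp.tris] + u.reshape(-1, 3)[grp.tris]
        f_el = self._zonule_force(s, x)
        if not want_K:
            return f_el, None
        return f_el, _fd_element_tangent(lambda y: self._zonule_force(s, y), x)

    # -- assembly ------------------------------------------------------------

    def assemble(self, u: np.ndarray, want_K: bool = True):
        """Internal force vector and (optionally) tangent at displacement u.

        ``u`` is the full (3N,) displacement vector; returns (f_int, K) in
        full coordinates.
        """
        ndof = self._ndof
        f = np.zeros(ndof)
        blocks = []

        f_el, K_el = self._tet_force_K(u, want_K)
        conn = self.mesh.tets
        np.add.at(f.reshape(-1, 3), conn, f_el)
        if want_K:
            blocks.append((conn, K_el))

        f_el, K_el = self._capsule_force_K(u, want_K)
        conn = self.mesh.capsule_tris
        np.add.at(f.reshape(-1, 3), conn, f_el)
        if want_K:
            blocks.append((conn, K_el))

        if self._bending is not None:
            conn = self._bending.hinges
            x = self.mesh.nodes[conn] + u.reshape(-1, 3)[conn]
            f_el = self._bending.force(x)
            np.add.at(f.reshape(-1, 3), conn, f_el)
            if want_K:
                blocks.append((conn, _fd_element_tangent(self._bending.force, x, h=1e-5)))

        for s in self._zonules:
            f_el, K_el = self._zonule_force_K(s, u, want_K)
            conn = self._zonules[s].tris
            np.add.at(f.reshape(-1, 3), conn, f_el)
            if want_K:
                blocks.append((conn, K_el))

        if not want_K:
            return f, None
        rows, cols, vals = [], [], []
        for conn, K_el in blocks:
            ne, nn = conn.shape
            dof = (3 * conn[:, :, None] + np.arange(3)[None, None, :]).reshape(ne, 3 * nn)
            r = np.repeat(dof[:, :, None], 3 * nn, axis=2)
            c = np.repeat(dof[:, None, :], 3 * nn, axis=1)
            rows.append(r.ravel())
            cols.append(c.ravel())
            vals.append(K_el.reshape(ne, 3 * nn, 3 * nn).ravel())
        K = sp.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(ndof, ndof),
        ).tocsr()
        return f, K

    # -- solve ---------------------------------------------------------------

    def _residual_norm(self, u_red, f_ext):
        """Residual norm on free dofs; inf for inadmissible states."""
        try:
            with np.errstate(over="ignore", invalid="ignore"):
                f_int, _ = self.assemble(self._T @ u_red, want_K=False)
        except ValueError:
            return None, np.inf, 1.0
        if not np.all(np.isfinite(f_int)):
            return None, np.inf, 1.0
        r = self._T.T @ (f_int - f_ext)
        ref = np.linalg.norm(self._T.T @ f_int) + np.linalg.norm(self._T.T @ f_ext) + 1e-8
        return r, float(np.linalg.norm(r[self._free])), ref

    def _solve_increment(self, u_red, presc_val, g_scale, log):
        """Newton-solve one equilibrium state; returns (u_red, its, res).

        Full Newton with a backtracking safeguard: a trial step is halved
        while it produces a non-finite state or grows the residual by more
        than 50%, which keeps the exponential fibre term from blowing up on
        overshoots far from equilibrium.
        """
        T = self._T
        free = self._free
        u_red = u_red.copy()
        u_red[self._presc_cols] = presc_val * self._presc_dirs
        f_ext = g_scale * self._gravity_load
        r, res, ref = self._residual_norm(u_red, f_ext)
        if r is None:
            return None, 0, np.inf
        # start from the previous increment's factorisation when available;
        # the backtracking safeguard triggers a refactor if it is too stale
        lu = getattr(self, "_lu", None)
        stale = lu is not None
        refactor = lu is None
        for it in range(self.max_newton):
            if res <= self.rtol * ref:
                return u_red, it, res
            if refactor:
                with np.errstate(over="ignore", invalid="ignore"):
                    _, K = self.assemble(T @ u_red, want_K=True)
                Kr = (T.T @ K @ T).tocsr()
                Kff = Kr[free][:, free].tocsc()
                try:
                    lu = splu(Kff)
                except RuntimeError:
                    return None, it, res
                self._lu = lu
                refactor, stale = False, False
            du = lu.solve(-r[free])
            alpha = 1.0
            accepted = False
            for _ in range(12):
                u_try = u_red.copy()
                u_try[free] += alpha * du
                r_try, res_try, ref_try = self._residual_norm(u_try, f_ext)
                if r_try is not None and res_try <= 1.5 * res:
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:
                if stale:
                    refactor = True  # retry this iteration with a fresh tangent
                    continue
                return None, it, res
            slow = res_try > 0.7 * res
            u_red, r, res, ref = u_try, r_try, res_try, ref_try
            stale = True
            if slow:
                refactor = True  # stale tangent is no longer effective
        if res <= self.rtol * ref:
            return u_red, self.max_newton, res
        return None, self.max_newton, res

    def solve(self) -> SimulationResult:
        """Run the full protocol: optional gravity step, then the stretch."""
        proto = self.protocol
        result = SimulationResult(self.mesh, proto)
        u_red = np.zeros(self._nred)

        schedule: list[tuple[str, float, float]] = []
        if proto.gravity:
            for k in range(1, proto.n_gravity_steps):
                schedule.append((f"gravity{k}", 0.0, k / proto.n_gravity_steps))
            schedule.append(("gravity", 0.0, 1.0))
        else:
            schedule.append(("reference", 0.0, 0.0))
        for k in range(1, proto.n_steps + 1):
            schedule.append((f"step{k}", k * proto.delta_z / proto.n_steps, 1.0 if proto.gravity else 0.0))

        prev_presc, prev_g = 0.0, 0.0
        for label, presc, g_scale in schedule:
            u_try, its, res = self._solve_increment(u_red, presc, g_scale, result.log)
            if u_try is None:
                u_try, its, res = self._bisect(u_red, prev_presc, presc, prev_g, g_scale, result.log)
                if u_try is None:
                    result.log.append(f"{label}: FAILED to converge; run truncated")
                    break
            u_red = u_try
            prev_presc, prev_g = presc, g_scale
            result.steps.append(self._make_step(label, u_red, presc, g_scale, its, res))
            result.log.append(f"{label}: converged in {its} iterations, residual {res:.3e}")
        if not result.steps:
            raise RuntimeError("simulation failed in the first increment")
        return result

    def _bisect(self, u_red, p0, p1, g0, g1, log, depth=0):
        if depth >= self.max_bisections:
            return None, 0, np.inf
        pm, gm = 0.5 * (p0 + p1), 0.5 * (g0 + g1)
        u_mid, its, res = self._solve_increment(u_red, pm, gm, log)
        if u_mid is None:
            u_mid, its, res = self._bisect(u_red, p0, pm, g0, gm, log, depth + 1)
            if u_mid is None:
                return None, 0, np.inf
        u_end, its, res = self._solve_increment(u_mid, p1, g1, log)
        if u_end is None:
            return self._bisect(u_mid, pm, p1, gm, g1, log, depth + 1)
        return u_end, its, res

    def _make_step(self, label, u_red, presc, g_scale, its, res) -> StepResult:
        u_full = self._T @ u_red
        f_int, _ = self.assemble(u_full, want_K=False)
        r_full = f_int - g_scale * self._gravity_load
        reactions = {}
        for s, outer in self._outer_nodes.items():
            reactions[s] = r_full.reshape(-1, 3)[outer]
        return StepResult(
            label=label,
            u=u_full.reshape(-1, 3).copy(),
            reactions=reactions,
            gravity_scale=g_scale,
            stretch=presc,
            iterations=its,
            residual=res,
        )

    # -- stress recovery (used by the metrics module) ------------------------

    def tet_stress(self, u: np.ndarray):
        """Cauchy stress (ne,3,3) and log-strain (ne,3,3) in the solids."""
        G = self._tet_G
        ue = u.reshape(-1, 3)[self.mesh.tets]
        F = np.eye(3) + np.einsum("eai,eaj->eij", ue, G)
        C = np.einsum("eki,ekj->eij", F, F)
        S, _, _ = neo_hookean_pk2(C, self._tet_lam, self._tet_mu)
        J = np.linalg.det(F)
        sigma = np.einsum("eik,ekl,ejl->eij", F, S, F) / J[:, None, None]
        C = np.einsum("eki,ekj->eij", F, F)
        w, V = np.linalg.eigh(C)
        LE = np.einsum("eik,ek,ejk->eij", V, 0.5 * np.log(w), V)
        return sigma, LE

    def capsule_stress(self, u: np.ndarray):
        """In-plane Cauchy principal stresses (ne,2) and log strain of the capsule."""
        grp = self._capsule
        mat = self.materials.capsule
        x = self.mesh.nodes[grp.tris] + u.reshape(-1, 3)[grp.tris]
        F = grp.F32(x)
        E2 = 0.5 * (np.einsum("eki,ekj->eij", F, F) - np.eye(2))
        S2 = self._capsule_pk2(F)  # wrinkle-relaxed stress actually carried
        # plane-stress thickness stretch of the SVK membrane: from S33 = 0,
        # E33 = -nu (E11 + E22) / (1 - nu)
        nu = mat.poisson_ratio
        trE = np.trace(E2, axis1=1, axis2=2)
        E33 = -nu * trE / (1.0 - nu)
        lam3sq = 1.0 + 2.0 * E33
        C2 = np.einsum("eki,ekj->eij", F, F)
        J = np.sqrt(np.linalg.det(C2) * np.clip(lam3sq, 1e-6, None))
        sigma2 = np.einsum("eip,epq,ejq->eij", F, S2, F) / J[:, None, None]
        princ = np.linalg.eigvalsh(sigma2)
        w, _ = np.linalg.eigh(C2)
        log_strain = np.column_stack([0.5 * np.log(w), 0.5 * np.log(np.clip(lam3sq, 1e-6, None))])
        return sigma2, princ, log_strain

    def zonule_stress(self, u: np.ndarray) -> dict[str, np.ndarray]:
        """In-plane Cauchy stress tensors per zonular set."""
        out = {}
        for s, grp in self._zonules.items():
            x = self.mesh.nodes[grp.tris] + u.reshape(-1, 3)[grp.tris]
            F = grp.F32(x)
            C2 = np.einsum("eki,ekj->eij", F, F)
            S2, c33, _ = hgo_membrane_pk2(C2, self.materials.zonule, grp.a0)
            J = np.sqrt(np.linalg.det(C2) * c33)
            out[s] = np.einsum("eip,epq,ejq->eij", F, S2, F) / J[:, None, None]
        return out


def run_disaccommodation(model: LensModel, protocol: BoundaryProtocol | None = None) -> SimulationResult:
    """Run the incremental disaccommodation protocol on an assembled model."""
    if protocol is not None and protocol != model.protocol:
        model = LensModel(
            model.mesh,
            model.materials,
            protocol,
            {s: t * 1e3 for s, t in model.zonule_thickness.items()},
            model.capsule_thickness * 1e3,
            rtol=model.rtol,
            max_newton=model.max_newton,
            capsule_bending=model.capsule_bending,
            capsule_wrinkling=model.capsule_wrinkling,
            wrinkle_eps=model.wrinkle_eps,
        )
    return model.solve()


def reaction_force_total(result: SimulationResult, step: int = -1) -> dict[str, float]:
    """Total radial zonular reaction per set and overall, in mN.

    Sums the radial component of the reaction at every zonular outer-edge
    node at the requested step (final step by default).
    """
    mesh = result.mesh
    out: dict[str, float] = {}
    total = 0.0
    sr = result.steps[step]
    for s, R in sr.reactions.items():
        outer = mesh.node_sets[f"zonule_outer_{s}"]
        pos = mesh.nodes[outer]
        rad = np.hypot(pos[:, 0], pos[:, 1])
        rhat = np.zeros_like(pos)
        rhat[:, 0] = pos[:, 0] / rad
        rhat[:, 1] = pos[:, 1] / rad
        f = float(np.sum(np.einsum("ni,ni->n", R, rhat))) * 1e3
        out[s] = f
        total += f
    out["total"] = total
    return out
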