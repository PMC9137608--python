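"""Optical and mechanical post-processing of disaccommodation runs.

Converts per-step displacement fields into the study's outputs: lens
thickness/radius variation, central optical power (COP) from the thick-lens
formula with sphere-fitted surface radii, accommodation amplitude, zonular
force and stress summaries.

The thick-lens central optical power is

    COP = (n_l - n_p)/r_a + (n_l - n_p)/r_p - t (n_l - n_p)^2 / (r_a r_p n_l)

with r_a, r_p the anterior/posterior central radii of curvature (positive
magnitudes), t the axial thickness and n_l, n_p the refractive indices of
lens and surrounding humours; lengths in metres give diopters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fem import LensModel, SimulationResult, reaction_force_total

__all__ = [
    "OpticalConstants",
    "MetricsRecord",
    "lens_dimensions",
    "fit_sphere",
    "fit_sphere_radius",
    "fit_circle_2d",
    "meridian_profile",
    "meridian_cap_radius",
    "sagittal_cap_radius",
    "plane_averaged_cap_radius",
    "central_optical_power",
    "accommodation_amplitude",
    "von_mises",
    "principal_stresses",
    "stress_summaries",
    "compute_metrics",
]


@dataclass(frozen=True)
class OpticalConstants:
    """Refractive indices (physiological defaults; the lens index is an
    effective homogeneous value, not a gradient-index profile)."""

    n_lens: float = 1.42
    n_humour: float = 1.336

    def __post_init__(self) -> None:
        if not (self.n_lens > self.n_humour > 1.0):
            raise ValueError("expected n_lens > n_humour > 1")


# ---------------------------------------------------------------------------
# Geometry of the deformed lens
# ---------------------------------------------------------------------------


def lens_dimensions(model: LensModel, u: np.ndarray) -> tuple[float, float]:
    """Deformed lens thickness t (pole-to-pole, mm) and equatorial radius (mm)."""
    mesh = model.mesh
    x = mesh.nodes + u.reshape(-1, 3)
    pa = mesh.node_sets["pole_anterior"][0]
    pp = mesh.node_sets["pole_posterior"][0]
    t = float(x[pa, 2] - x[pp, 2])
    outer = mesh.node_sets["outer_surface"]
    r = float(np.hypot(x[outer, 0], x[outer, 1]).max())
    return t, r


def fit_sphere(points: np.ndarray):
    """Algebraic least-squares sphere fit; returns (center, radius, rms).

    Solves |p|^2 = 2 c.p + (R^2 - |c|^2) as a linear system.
    """
    p = np.asarray(points, dtype=float)
    if len(p) < 10:
        raise ValueError("sphere fit needs at least 10 points")
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = np.einsum("ij,ij->i", p, p)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c, k = sol[:3], sol[3]
    R2 = k + c @ c
    if R2 <= 0:
        raise ValueError("degenerate point set: no sphere fits")
    R = float(np.sqrt(R2))
    rms = float(np.sqrt(np.mean((np.linalg.norm(p - c, axis=1) - R) ** 2)))
    if rms > 0.2 * R:
        raise ValueError("degenerate (flat or scattered) point set for sphere fit")
    return c, R, rms


def fit_sphere_radius(surface_points: np.ndarray, zone_radius: float | None = None):
    """Sphere radius (mm) fitted to points within ``zone_radius`` of the axis.

    Points are 3D (x, y, z) with z the optical axis; ``zone_radius`` filters
    on the transverse distance sqrt(x^2+y^2). Returns (radius, rms residual).
    """
    p = np.asarray(surface_points, dtype=float)
    if zone_radius is not None:
        p = p[np.hypot(p[:, 0], p[:, 1]) <= zone_radius]
    _, R, rms = fit_sphere(p)
    return R, rms


def meridian_profile(model: LensModel, u: np.ndarray, side: str):
    """Azimuthally averaged meridian of the deformed outer surface.

    Each reference contour ring is averaged over the circumference into one
    (mean transverse radius, mean axial position) station, which removes
    tilt and azimuthal asymmetry and yields the axisymmetric-equivalent
    sagittal profile. Returns (r, z) arrays ordered from the pole outward.
    """
    mesh = model.mesh
    x = mesh.nodes + u.reshape(-1, 3)
    arcs = mesh.outer_ring_arcs
    sel = arcs > 0 if side == "anterior" else arcs < 0
    order = np.argsort(-np.abs(arcs))  # pole (largest |arc|) first
    rs, zs = [], []
    for i in order:
        if not sel[i]:
            continue
        ring = x[mesh.outer_rings[i]]
        rs.append(float(np.hypot(ring[:, 0], ring[:, 1]).mean()))
        zs.append(float(ring[:, 2].mean()))
    return np.asarray(rs), np.asarray(zs)


def meridian_cap_radius(model: LensModel, u: np.ndarray, side: str, zone_radius: float = 2.5):
    """Central radius of curvature from a circle fit to the mean meridian.

    This is the package's default estimator for the radii entering the
    optical-power formula: it reproduces the sagittal-plane spherical
    reading while staying well conditioned on coarse meshes and under
    azimuthally asymmetric (dialysed) deformations.
    """
    r, z = meridian_profile(model, u, side)
    sel = r <= zone_radius
    if sel.sum() < 3:
        raise ValueError("too few meridian stations inside the fit zone")
    r, z = r[sel], z[sel]
    # circle with centre on the optical axis: r^2 + (z - c)^2 = R^2
    A = np.column_stack([2.0 * z, np.ones(len(z))])
    b = r * r + z * z
    (c, k), *_ = np.linalg.lstsq(A, b, rcond=None)
    R2 = k + c * c
    if R2 <= 0:
        raise ValueError("degenerate meridian profile")
    R = float(np.sqrt(R2))
    rms = float(np.sqrt(np.mean((np.hypot(r, z - c) - R) ** 2)))
    return R, rms


def sagittal_cap_radius(model: LensModel, u: np.ndarray, side: str, zone_radius: float = 2.5):
    """Radius of curvature from a circle fit in the vertical sagittal plane.

    Takes the deformed positions of the outer-surface nodes lying on the
    superior and inferior meridians (the x = 0 plane) whose reference
    transverse radius is inside the fit zone, and fits a circle with a free
    in-plane centre through their (y, z) coordinates. Because a rigid
    rotation maps circles to circles, this reading is insensitive to the
    tilt that asymmetric (partial-arc) zonular dialysis induces, unlike an
    apex-sagitta estimate.
    """
    mesh = model.mesh
    x = mesh.nodes + u.reshape(-1, 3)
    arcs = mesh.outer_ring_arcs
    sel = arcs > 0 if side == "anterior" else arcs < 0
    pts = []
    for i in np.nonzero(sel)[0]:
        ring = mesh.outer_rings[i]
        ref = mesh.nodes[ring]
        r_ref = np.hypot(ref[:, 0], ref[:, 1])
        if r_ref.max() > zone_radius + 1e-9 and len(ring) > 1:
            continue
        on_plane = np.abs(ref[:, 0]) < 1e-6
        pts.append(x[ring[on_plane]][:, 1:])  # (y, z)
    p = np.vstack(pts)
    if len(p) < 4:
        raise ValueError("too few sagittal-plane points inside the fit zone")
    R, rms = fit_circle_2d(p)
    return R, rms


def plane_averaged_cap_radius(model: LensModel, u: np.ndarray, side: str, zone_radius: float = 2.5):
    """Cap radius averaged over free-centre circle fits in every meridian plane.

    For each diametral plane through the optical axis, the deformed
    positions of the cap nodes on its two meridians are fitted by a circle
    with a free in-plane centre; the reported radius is the mean over all
    planes. Each single-plane fit is invariant under rigid rotations (tilt
    from asymmetric dialysis does not bias it) and the azimuthal average
    suppresses the noise of the non-axisymmetric tetrahedral splitting.
    """
    mesh = model.mesh
    x = mesh.nodes + u.reshape(-1, 3)
    arcs = mesh.outer_ring_arcs
    sel = arcs > 0 if side == "anterior" else arcs < 0
    rings = []
    for i in np.nonzero(sel)[0]:
        ring = mesh.outer_rings[i]
        ref = mesh.nodes[ring]
        r_ref = np.hypot(ref[:, 0], ref[:, 1]).max()
        if r_ref <= zone_radius + 1e-9 or len(ring) == 1:
            rings.append(ring)
    n = mesh.n_theta
    half = n // 2
    theta = np.deg2rad(np.arange(half) * (360.0 / n))
    radii = []
    for j, th in enumerate(theta):
        d = np.array([np.sin(th), np.cos(th)])  # in-plane transverse direction
        pts = []
        for ring in rings:
            if len(ring) == 1:
                p = x[ring[0]]
                pts.append((p[0] * d[0] + p[1] * d[1], p[2]))
            else:
                for k in (j, j + half):
                    p = x[ring[k]]
                    pts.append((p[0] * d[0] + p[1] * d[1], p[2]))
        R, _ = fit_circle_2d(np.asarray(pts))
        radii.append(R)
    radii = np.asarray(radii)
    return float(radii.mean()), float(radii.std())


def fit_circle_2d(points_rz: np.ndarray):
    """Least-squares circle in a sagittal plane; returns (radius, rms).

    Reproduces the clinical sagittal-plane reading of the radius of
    curvature (2D analogue of :func:`fit_sphere`).
    """
    p = np.asarray(points_rz, dtype=float)
    A = np.column_stack([2.0 * p, np.ones(len(p))])
    b = np.einsum("ij,ij->i", p, p)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    c, k = sol[:2], sol[2]
    R = float(np.sqrt(k + c @ c))
    rms = float(np.sqrt(np.mean((np.linalg.norm(p - c, axis=1) - R) ** 2)))
    return R, rms


def surface_cap_points(model: LensModel, u: np.ndarray, side: str, zone_radius: float = 1.5):
    """Deformed capsule points of the central anterior/posterior cap."""
    mesh = model.mesh
    x = mesh.nodes + u.reshape(-1, 3)
    outer = mesh.node_sets["outer_surface"]
    p = x[outer]
    rad = np.hypot(p[:, 0], p[:, 1])
    if side == "anterior":
        sel = (p[:, 2] > 0) & (rad <= zone_radius)
    elif side == "posterior":
        sel = (p[:, 2] < 0) & (rad <= zone_radius)
    else:
        raise ValueError("side must be 'anterior' or 'posterior'")
    return p[sel]


# ---------------------------------------------------------------------------
# Optical power
# ---------------------------------------------------------------------------


def central_optical_power(
    consts: OpticalConstants, t_mm: float, r_a_mm: float, r_p_mm: float
) -> float:
    """Thick-lens central optical power in diopters (radii as magnitudes)."""
    if r_a_mm <= 0 or r_p_mm <= 0:
        raise ValueError("radii of curvature must be positive")
    if t_mm < 0:
        raise ValueError("thickness must be non-negative")
    nl, np_ = consts.n_lens, consts.n_humour
    ra, rp, t = r_a_mm * 1e-3, r_p_mm * 1e-3, t_mm * 1e-3
    return (nl - np_) / ra + (nl - np_) / rp - t * (nl - np_) ** 2 / (ra * rp * nl)


def accommodation_amplitude(cop_series) -> float:
    """Amplitude of accommodation: COP(accommodated) - COP(final step), D.

    The full series should be inspected alongside — the power is not
    necessarily monotone over the six steps.
    """
    cop = np.asarray(list(cop_series), dtype=float)
    if len(cop) < 2:
        raise ValueError("need at least two COP values")
    return float(cop[0] - cop[-1])


# ---------------------------------------------------------------------------
# Stress summaries
# ---------------------------------------------------------------------------


def _as_full_tensor(sig: np.ndarray) -> np.ndarray:
    """Embed 2x2 in-plane membrane stress as a 3x3 tensor (zero normal)."""
    if sig.shape[-1] == 3:
        return sig
    out = np.zeros(sig.shape[:-2] + (3, 3))
    out[..., :2, :2] = sig
    return out


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Von-Mises equivalent stress of (batched) 3x3 Cauchy tensors."""
    s = _as_full_tensor(np.asarray(sigma, dtype=float))
    tr = np.trace(s, axis1=-2, axis2=-1)
    dev = s - (tr / 3.0)[..., None, None] * np.eye(3)
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))


def principal_stresses(sigma: np.ndarray) -> np.ndarray:
    """Sorted principal values of (batched) symmetric stress tensors."""
    s = _as_full_tensor(np.asarray(sigma, dtype=float))
    return np.linalg.eigvalsh(0.5 * (s + np.swapaxes(s, -1, -2)))


def stress_summaries(model: LensModel, u: np.ndarray) -> dict[str, float]:
    """Stress/strain summary of one converged state (kPa).

    Returns the capsule principal-stress range and average VMS, the maximum
    zonular VMS, the lenticular (nucleus+cortex) principal range and maximum
    VMS, and the capsule logarithmic-strain range.
    """
    out: dict[str, float] = {}
    sig_cb, princ_cb, le_cb = model.capsule_stress(u)
    out["capsule_principal_min_kpa"] = float(princ_cb.min() * 1e3)
    out["capsule_principal_max_kpa"] = float(princ_cb.max() * 1e3)
    out["capsule_vms_avg_kpa"] = float(von_mises(sig_cb).mean() * 1e3)
    out["capsule_le_min"] = float(le_cb.min())
    out["capsule_le_max"] = float(le_cb.max())

    zon = model.zonule_stress(u)
    out["zonule_vms_max_kpa"] = float(max(von_mises(s).max() for s in zon.values()) * 1e3)

    sig_sol, _ = model.tet_stress(u)
    princ = principal_stresses(sig_sol)
    out["lens_principal_min_kpa"] = float(princ.min() * 1e3)
    out["lens_principal_max_kpa"] = float(princ.max() * 1e3)
    # nodal stress recovery (volume-weighted average of adjacent elements)
    # before taking the maximum: constant-strain tetrahedra carry noisy
    # element values, and the recovered field is the standard readout
    mesh = model.mesh
    vms = von_mises(sig_sol)
    vol = model._tet_vol
    num = np.zeros(mesh.n_nodes)
    den = np.zeros(mesh.n_nodes)
    for a in range(4):
        np.add.at(num, mesh.tets[:, a], vms * vol)
        np.add.at(den, mesh.tets[:, a], vol)
    nodal = num[den > 0] / den[den > 0]
    out["lens_vms_max_kpa"] = float(nodal.max() * 1e3)
    return out


# ---------------------------------------------------------------------------
# Full metrics record
# ---------------------------------------------------------------------------


@dataclass
class MetricsRecord:
    """Outputs of one model run (percentages relative to the baseline state)."""

    delta_thickness_pct: float
    delta_radius_pct: float
    zonular_force_mn: float
    zonular_force_per_set_mn: dict[str, float]
    cop_series_d: list[float]
    delta_cop_d: float
    anterior_radius_mm: float  # baseline sphere-fit radii
    posterior_radius_mm: float
    stress: dict[str, float] = field(default_factory=dict)

    def as_row(self) -> dict[str, float]:
        row = {
            "delta_thickness_pct": self.delta_thickness_pct,
            "delta_radius_pct": self.delta_radius_pct,
            "zonular_force_mn": self.zonular_force_mn,
            "delta_cop_d": self.delta_cop_d,
            "anterior_radius_mm": self.anterior_radius_mm,
            "posterior_radius_mm": self.posterior_radius_mm,
        }
        for s, v in self.zonular_force_per_set_mn.items():
            row[f"force_{s}_mn"] = v
        for i, c in enumerate(self.cop_series_d):
            row[f"cop_step{i}_d"] = c
        row.update(self.stress)
        return row


def compute_metrics(
    model: LensModel,
    result: SimulationResult,
    consts: OpticalConstants | None = None,
    zone_radius: float = 2.5,
) -> MetricsRecord:
    """Full metrics record for a finished disaccommodation run.

    Variations are measured against the post-gravity, pre-stretch baseline;
    the COP series covers baseline plus each loading step.
    """
    consts = consts or OpticalConstants()
    steps = result.stretch_steps
    u0 = steps[0].u.ravel()
    t0, r0 = lens_dimensions(model, u0)

    cop = []
    ra0 = rp0 = None
    for sr in steps:
        u = sr.u.ravel()
        t, _ = lens_dimensions(model, u)
        # plane-averaged sagittal reading: tilt-invariant per plane and
        # insensitive to the non-axisymmetric tetrahedral splitting
        ra, _ = plane_averaged_cap_radius(model, u, "anterior", zone_radius)
        rp, _ = plane_averaged_cap_radius(model, u, "posterior", zone_radius)
        if ra0 is None:
            ra0, rp0 = ra, rp
        cop.append(central_optical_power(consts, t, ra, rp))

    tf, rf = lens_dimensions(model, steps[-1].u.ravel())
    forces = reaction_force_total(result)
    total = forces.pop("total")
    return MetricsRecord(
        delta_thickness_pct=100.0 * (t0 - tf) / t0,
        delta_radius_pct=100.0 * (rf - r0) / r0,
        zonular_force_mn=total,
        zonular_force_per_set_mn=forces,
        cop_series_d=cop,
        delta_cop_d=accommodation_amplitude(cop),
        anterior_radius_mm=ra0,
        posterior_radius_mm=rp0,
        stress=stress_summaries(model, steps[-1].u.ravel()),
    )
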