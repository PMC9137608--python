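"""Structured revolution meshing of the lens complex.

The axisymmetric cross-section (half-plane r >= 0) is meshed with a mapped
triangulation — a fan + ring layout inside the nucleus and interpolated
layers through the cortex — and revolved about the optical axis in equal
angular sectors. Prisms/pyramids arising from the revolution are split into
tetrahedra with the minimum-global-id diagonal rule, which guarantees
conforming faces between neighbouring cells. The procedure is fully
deterministic: the same inputs always produce the identical mesh.

Element inventory:

* nucleus and cortex: 4-node tetrahedra (conforming at the interface);
* capsular bag: 3-node triangles on the cortex outer surface, sharing its
  nodes (the cortex-capsule tie reduces to node identity);
* zonular sets ZA/ZE/ZP: 3-node membrane triangles spanning annuli from the
  capsule insertion to the outer (ciliary) edge, tagged with the
  circumferential angle of their centroid;
* ties: each zonular inner-edge node is constrained to the capsule anchorage
  band at the same angular station (multipoint average over the band rings;
  a zero-width band degenerates to a single-node identity tie).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import LensComplex, _Cap

__all__ = ["FEMesh", "Tie", "generate_mesh"]

_AXIS_TOL = 1e-9


@dataclass
class Tie:
    slave: int
    masters: np.ndarray
    weights: np.ndarray


@dataclass
class FEMesh:
    """Finite-element mesh of the full lens complex (coordinates in mm)."""

    nodes: np.ndarray  # (N, 3) x, y, z with z = xi (optical axis)
    tets: np.ndarray  # (M, 4)
    tet_region: np.ndarray  # (M,) 0 = nucleus, 1 = cortex
    capsule_tris: np.ndarray  # (Mc, 3)
    zonule_tris: dict[str, np.ndarray]
    zonule_theta: dict[str, np.ndarray]  # element centroid angle, degrees
    zonule_fiber_dir: dict[str, np.ndarray]  # (Mz, 3) unit vectors, reference
    node_sets: dict[str, np.ndarray]
    ties: list[Tie]
    n_theta: int
    sector_deg: float
    # outer-surface contour rings: per station, the 3D node ids around the
    # circumference (a single id on the axis), with the signed arc
    # coordinate from the equator (positive anterior)
    outer_rings: list[np.ndarray] = field(default_factory=list)
    outer_ring_arcs: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        nz = sum(len(t) for t in self.zonule_tris.values())
        return len(self.tets) + len(self.capsule_tris) + nz

    def tet_volumes(self) -> np.ndarray:
        x = self.nodes[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.einsum("ei,ei->e", np.cross(d[:, 0], d[:, 1]), d[:, 2]) / 6.0

    def tri_areas(self, tris: np.ndarray) -> np.ndarray:
        x = self.nodes[tris]
        return 0.5 * np.linalg.norm(np.cross(x[:, 1] - x[:, 0], x[:, 2] - x[:, 0]), axis=1)

    def validate(self) -> None:
        vol = self.tet_volumes()
        if np.any(vol <= 0):
            bad = int(np.argmin(vol))
            raise ValueError(f"inverted tetrahedron at element {bad} (volume {vol[bad]:g})")
        for name, tris in [("capsule", self.capsule_tris)] + [
            (s, t) for s, t in self.zonule_tris.items()
        ]:
            area = self.tri_areas(tris)
            if np.any(area <= 0):
                raise ValueError(f"zero-area triangle in {name} membrane")
        for s, th in self.zonule_theta.items():
            if np.any((th < 0) | (th >= 360)):
                raise ValueError(f"zonular angle tag out of [0, 360) in {s}")


# ---------------------------------------------------------------------------
# Cross-section construction
# ---------------------------------------------------------------------------


def _cap_arclength_table(cap: _Cap, R: float, n: int = 4000):
    """Cumulative arc length along a cap from the equator (r = R) to the pole."""
    u = np.linspace(0.0, 1.0, n)
    r = R * np.cos(0.5 * np.pi * u)  # equator -> pole
    xi = cap.xi(r)
    seg = np.hypot(np.diff(r), np.diff(xi))
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return s, r


def _r_at_arc(cap: _Cap, R: float, arcs: np.ndarray):
    s, r = _cap_arclength_table(cap, R)
    return np.interp(arcs, s, r), s[-1]


def _merge_mandatory(grid: np.ndarray, mandatory: np.ndarray) -> np.ndarray:
    """Insert mandatory stations, dropping ordinary grid points crowding them."""
    if len(mandatory) == 0:
        return np.unique(grid)
    spacing = grid[1] - grid[0]
    dist = np.min(np.abs(grid[:, None] - mandatory[None, :]), axis=1)
    keep = (dist > 0.4 * spacing) | (np.arange(len(grid)) == 0) | (
        np.arange(len(grid)) == len(grid) - 1
    )
    return np.unique(np.concatenate([grid[keep], mandatory]))


def _contour_samples(complex_: LensComplex, h: float):
    """Sample the cortex and nucleus contours at matched stations.

    Returns (cortex_pts, nucleus_pts, arc_signed) ordered anterior pole ->
    equator -> posterior pole; arc_signed is the arc coordinate from the
    equator along the cortex contour (positive anterior), with the equator,
    attachment centres and band edges included exactly.
    """
    prof = complex_.profile
    cap_a, cap_p = prof.cortex_caps
    ncap_a, ncap_p = prof.nucleus_caps
    R, Rn = prof.equator_radius, ncap_a.R

    _, L_ant = _r_at_arc(cap_a, R, np.array([0.0]))
    _, L_post = _r_at_arc(cap_p, R, np.array([0.0]))

    mand_ant, mand_post = [], []
    for s_name, (lo, hi) in complex_.band_spans.items():
        c = complex_.attachment_arcs[s_name]
        for v in {c, lo, hi}:
            if v > 1e-9:
                mand_ant.append(min(v, L_ant - 1e-6))
            elif v < -1e-9:
                mand_post.append(min(-v, L_post - 1e-6))
            else:
                pass  # equator is always a station
    # extra stations towards the poles keep the central optical zone (sphere
    # fits for the optical power) resolved even on coarse meshes
    for d in (0.5, 1.0, 1.5):
        mand_ant.append(L_ant - d)
        mand_post.append(L_post - d)
    n_ant = max(4, int(round(L_ant / h)))
    n_post = max(4, int(round(L_post / h)))
    arcs_ant = _merge_mandatory(np.linspace(0.0, L_ant, n_ant + 1), np.array(mand_ant))
    arcs_post = _merge_mandatory(np.linspace(0.0, L_post, n_post + 1), np.array(mand_post))

    def _cap_points(cap, arcs):
        r, _ = _r_at_arc(cap, R, arcs)
        r = np.clip(r, 0.0, R)
        return np.column_stack([r, cap.xi(r)])

    pts_ant = _cap_points(cap_a, arcs_ant)  # equator -> anterior pole
    pts_post = _cap_points(cap_p, arcs_post)
    # assemble anterior pole -> equator -> posterior pole
    cortex = np.vstack([pts_ant[::-1], pts_post[1:]])
    cortex[np.abs(cortex[:, 0]) < 1e-12, 0] = 0.0
    arc_signed = np.concatenate([arcs_ant[::-1], -arcs_post[1:]])

    # nucleus sampled at the same normalised arc fractions per cap
    def _ncap_points(ncap, arcs, L):
        sn, rn = _cap_arclength_table(ncap, ncap.R)
        r = np.interp(arcs / L * sn[-1], sn, rn)
        return np.column_stack([r, ncap.xi(r)])

    n_ant_pts = _ncap_points(ncap_a, arcs_ant, L_ant)
    n_post_pts = _ncap_points(ncap_p, arcs_post, L_post)
    nucleus = np.vstack([n_ant_pts[::-1], n_post_pts[1:]])
    nucleus[np.abs(nucleus[:, 0]) < 1e-12, 0] = 0.0
    return cortex, nucleus, arc_signed


def _cross_section(complex_: LensComplex, h: float):
    """Mapped 2D triangulation of the half cross-section.

    Returns nodes2d (r, xi), triangles, region ids, and bookkeeping: index of
    each outer-contour node and the signed arc coordinate per outer node.
    """
    cortex, nucleus, arc_signed = _contour_samples(complex_, h)
    n_s = len(cortex)
    prof = complex_.profile
    Rn = prof.nucleus_caps[0].R
    gap = np.linalg.norm(cortex - nucleus, axis=1).mean()
    n_layers = max(2, int(round(gap / h)))
    n_rings = max(2, int(round(Rn / h)))

    xi_c = 0.5 * (nucleus[0, 1] + nucleus[-1, 1])
    center = np.array([0.0, xi_c])

    nodes = [center]
    ring_ids = []  # nucleus rings, innermost first; each is array of node ids
    for k in range(1, n_rings + 1):
        t = k / n_rings
        ring = center + t * (nucleus - center)
        ids = np.arange(len(nodes), len(nodes) + n_s)
        nodes.extend(ring)
        ring_ids.append(ids)
    layer_ids = [ring_ids[-1]]  # cortex layers, nucleus contour first
    for l in range(1, n_layers + 1):
        t = l / n_layers
        layer = nucleus + t * (cortex - nucleus)
        ids = np.arange(len(nodes), len(nodes) + n_s)
        nodes.extend(layer)
        layer_ids.append(ids)
    nodes2d = np.asarray(nodes)
    nodes2d[np.abs(nodes2d[:, 0]) < 1e-12, 0] = 0.0

    tris, region = [], []

    def _strip(ids_lo, ids_hi, reg):
        for i in range(n_s - 1):
            a, b = ids_lo[i], ids_lo[i + 1]
            c, d = ids_hi[i + 1], ids_hi[i]
            tris.append((a, b, c))
            tris.append((a, c, d))
            region.append(reg)
            region.append(reg)

    for i in range(n_s - 1):  # fan around the centre point
        tris.append((0, ring_ids[0][i], ring_ids[0][i + 1]))
        region.append(0)
    for k in range(len(ring_ids) - 1):
        _strip(ring_ids[k], ring_ids[k + 1], 0)
    for l in range(len(layer_ids) - 1):
        _strip(layer_ids[l], layer_ids[l + 1], 1)

    tris = np.asarray(tris, dtype=np.int64)
    region = np.asarray(region, dtype=np.int64)
    # drop degenerate triangles (both nodes of an edge on the axis with the
    # strip collapsing) and enforce CCW orientation in the (r, xi) plane
    p = nodes2d[tris]
    area2 = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    keep = np.abs(area2) > 1e-14
    tris, region, area2 = tris[keep], region[keep], area2[keep]
    flip = area2 < 0
    tris[flip] = tris[flip][:, [0, 2, 1]]
    outer_ids = layer_ids[-1]
    return nodes2d, tris, region, outer_ids, arc_signed


# ---------------------------------------------------------------------------
# Revolution and prism/pyramid subdivision
# ---------------------------------------------------------------------------


def _split_prism(v):
    """Split prism (bottom v[0:3], top v[3:6]) into 3 tets, min-id rule."""
    rho = (1, 2, 0, 4, 5, 3)
    sigma = (3, 4, 5, 0, 1, 2)
    perms = []
    for base in [tuple(range(6)), sigma]:
        p = base
        for _ in range(3):
            perms.append(p)
            p = tuple(p[i] for i in rho)
    m = min(range(6), key=lambda i: v[i])
    for p in perms:
        if p[0] == m:
            w = [v[i] for i in p]
            break
    if min(w[1], w[5]) < min(w[2], w[4]):
        return [(w[0], w[1], w[2], w[5]), (w[0], w[1], w[5], w[4]), (w[0], w[4], w[5], w[3])]
    return [(w[0], w[1], w[2], w[4]), (w[0], w[4], w[2], w[5]), (w[0], w[4], w[5], w[3])]


def _split_pyramid(base, apex):
    """Split pyramid with cyclic base quad into 2 tets, min-id diagonal."""
    b0, b1, b2, b3 = base
    if min(b0, b2) < min(b1, b3):
        return [(b0, b1, b2, apex), (b0, b2, b3, apex)]
    return [(b1, b2, b3, apex), (b1, b3, b0, apex)]


def _revolve(nodes2d: np.ndarray, tris2d: np.ndarray, region2d: np.ndarray, n_theta: int):
    """Revolve the 2D triangulation into a conforming tet mesh."""
    on_axis = nodes2d[:, 0] <= _AXIS_TOL
    node_id = np.full((len(nodes2d), n_theta), -1, dtype=np.int64)
    coords = []
    theta = np.arange(n_theta) * (2.0 * np.pi / n_theta)
    sin_t, cos_t = np.sin(theta), np.cos(theta)
    for n, (r, xi) in enumerate(nodes2d):
        if on_axis[n]:
            node_id[n, :] = len(coords)
            coords.append((0.0, 0.0, xi))
        else:
            base = len(coords)
            node_id[n, :] = base + np.arange(n_theta)
            coords.extend(zip(r * sin_t, r * cos_t, np.full(n_theta, xi)))
    coords = np.asarray(coords)

    tets, tet_region = [], []
    for tri, reg in zip(tris2d, region2d):
        ax = [int(t) for t in tri if on_axis[t]]
        off = [int(t) for t in tri if not on_axis[t]]
        for j in range(n_theta):
            jp = (j + 1) % n_theta
            if len(ax) == 0:
                bottom = [node_id[t, j] for t in tri]
                top = [node_id[t, jp] for t in tri]
                new = _split_prism(bottom + top)
            elif len(ax) == 1:
                a = node_id[ax[0], j]
                q, r_ = off
                base = (node_id[q, j], node_id[r_, j], node_id[r_, jp], node_id[q, jp])
                new = _split_pyramid(base, a)
            else:
                q = off[0]
                new = [(node_id[ax[0], j], node_id[ax[1], j], node_id[q, j], node_id[q, jp])]
            tets.extend(new)
            tet_region.extend([reg] * len(new))
    tets = np.asarray(tets, dtype=np.int64)
    tet_region = np.asarray(tet_region, dtype=np.int64)

    x = coords[tets]
    d = x[:, 1:] - x[:, :1]
    vol = np.einsum("ei,ei->e", np.cross(d[:, 0], d[:, 1]), d[:, 2])
    neg = vol < 0
    tets[neg] = tets[neg][:, [0, 1, 3, 2]]
    return coords, tets, tet_region, node_id


def _boundary_capsule(tets: np.ndarray, outer_nodes: np.ndarray) -> np.ndarray:
    """Boundary faces of the tet mesh whose nodes all lie on the outer surface."""
    faces = np.vstack(
        [tets[:, [0, 1, 2]], tets[:, [0, 1, 3]], tets[:, [0, 2, 3]], tets[:, [1, 2, 3]]]
    )
    key = np.sort(faces, axis=1)
    _, idx, counts = np.unique(key, axis=0, return_index=True, return_counts=True)
    bnd = key[idx[counts == 1]]
    mask = np.isin(bnd, outer_nodes).all(axis=1)
    return bnd[mask]


# ---------------------------------------------------------------------------
# Public entry point
# ---------------------------------------------------------------------------


def generate_mesh(
    complex_: LensComplex,
    target_edge_length: float = 0.5,
    n_theta: int | None = None,
    zonule_radial_divisions: int = 1,
) -> FEMesh:
    """Mesh the lens complex.

    ``target_edge_length`` (mm) controls the in-plane resolution; ``n_theta``
    the number of angular sectors (must be a multiple of 24 so that sector
    boundaries fall on 15-degree stations, aligning clock-hour dialysis arcs
    and their flanks with element edges). With the default single radial
    strip every zonular node belongs to either the tied inner edge or the
    loaded outer edge.
    """
    if target_edge_length <= 0:
        raise ValueError("target_edge_length must be positive")
    prof = complex_.profile
    if n_theta is None:
        circ = 2.0 * np.pi * prof.equator_radius
        n_theta = 24 * max(1, int(round(circ / (24.0 * target_edge_length))))
    if n_theta % 24 != 0:
        raise ValueError("n_theta must be a multiple of 24")

    nodes2d, tris2d, region2d, outer_ids, arc_signed = _cross_section(
        complex_, target_edge_length
    )
    coords, tets, tet_region, node_id = _revolve(nodes2d, tris2d, region2d, n_theta)

    node_sets: dict[str, np.ndarray] = {}
    outer3d = np.unique(node_id[outer_ids].ravel())
    node_sets["outer_surface"] = outer3d
    outer_rings = [np.unique(node_id[i2d]) for i2d in outer_ids]
    i_ant = outer_ids[int(np.argmax(arc_signed))]
    i_post = outer_ids[int(np.argmin(arc_signed))]
    node_sets["pole_anterior"] = np.array([node_id[i_ant, 0]])
    node_sets["pole_posterior"] = np.array([node_id[i_post, 0]])
    # nucleus poles: axis nodes nearest the nucleus cap apices
    axis_nodes = np.unique(node_id[nodes2d[:, 0] <= _AXIS_TOL, 0])
    z_axis = coords[axis_nodes, 2]
    na, npo = prof.nucleus_caps
    node_sets["nucleus_pole_anterior"] = np.array(
        [axis_nodes[int(np.argmin(np.abs(z_axis - na.xi(0.0))))]]
    )
    node_sets["nucleus_pole_posterior"] = np.array(
        [axis_nodes[int(np.argmin(np.abs(z_axis - npo.xi(0.0))))]]
    )
    node_sets["superior_half"] = np.nonzero(coords[:, 1] > 0)[0]
    node_sets["inferior_half"] = np.nonzero(coords[:, 1] < 0)[0]

    capsule_tris = _boundary_capsule(tets, outer3d)

    # --- zonular membranes -------------------------------------------------
    p = complex_.params
    theta_deg = np.arange(n_theta) * (360.0 / n_theta)
    sin_t = np.sin(np.deg2rad(theta_deg))
    cos_t = np.cos(np.deg2rad(theta_deg))
    zonule_tris: dict[str, np.ndarray] = {}
    zonule_theta: dict[str, np.ndarray] = {}
    zonule_fiber: dict[str, np.ndarray] = {}
    ties: list[Tie] = []
    coords_list = [coords]
    next_id = len(coords)
    angles = dict(zip(("ZA", "ZE", "ZP"), p.zonule_angles_deg))

    for s_name in complex_.zonule_sets:
        arc_c = complex_.attachment_arcs[s_name]
        i_center = int(np.argmin(np.abs(arc_signed - arc_c)))
        lo, hi = complex_.band_spans[s_name]
        band_idx = np.nonzero((arc_signed >= lo - 1e-9) & (arc_signed <= hi + 1e-9))[0]
        if len(band_idx) == 0:
            band_idx = np.array([i_center])
        center_2d = outer_ids[i_center]
        node_sets[f"attach_center_{s_name}"] = node_id[center_2d]
        node_sets[f"attach_band_{s_name}"] = np.unique(node_id[outer_ids[band_idx]].ravel())

        r0 = nodes2d[center_2d, 0]
        xi0 = nodes2d[center_2d, 1]
        alpha = np.deg2rad(angles[s_name])
        length = p.zonule_length_at(theta_deg)
        n_rad = max(1, zonule_radial_divisions)
        ring_node_ids = []
        # sign convention: a positive set angle tilts the outer (ciliary)
        # edge posterior of its insertion (ZP descends at +24 deg, ZA rises
        # slightly at -10 deg, ZE stays equatorial)
        for k in range(n_rad + 1):
            t = k / n_rad
            r_k = r0 + t * length * np.cos(alpha)
            z_k = xi0 - t * length * np.sin(alpha)
            pts = np.column_stack([r_k * sin_t, r_k * cos_t, z_k])
            ids = next_id + np.arange(n_theta)
            next_id += n_theta
            coords_list.append(pts)
            ring_node_ids.append(ids)
        ring_node_ids = np.asarray(ring_node_ids)
        node_sets[f"zonule_inner_{s_name}"] = ring_node_ids[0]
        node_sets[f"zonule_outer_{s_name}"] = ring_node_ids[-1]
        if n_rad > 1:
            node_sets[f"zonule_mid_{s_name}"] = ring_node_ids[1:-1].ravel()

        tris, fibs = [], []
        all_coords = np.vstack(coords_list)
        for k in range(n_rad):
            inner, outer = ring_node_ids[k], ring_node_ids[k + 1]
            for j in range(n_theta):
                jp = (j + 1) % n_theta
                quad = (inner[j], outer[j], outer[jp], inner[jp])
                if min(quad[0], quad[2]) < min(quad[1], quad[3]):
                    tris.extend([(quad[0], quad[1], quad[2]), (quad[0], quad[2], quad[3])])
                else:
                    tris.extend([(quad[1], quad[2], quad[3]), (quad[1], quad[3], quad[0])])
        tris = np.asarray(tris, dtype=np.int64)
        cent = all_coords[tris].mean(axis=1)
        th = np.degrees(np.arctan2(cent[:, 0], cent[:, 1])) % 360.0
        rad = np.hypot(cent[:, 0], cent[:, 1])
        rhat = np.column_stack([cent[:, 0] / rad, cent[:, 1] / rad, np.zeros(len(cent))])
        fib = np.cos(alpha) * rhat
        fib[:, 2] = -np.sin(alpha)
        fib /= np.linalg.norm(fib, axis=1, keepdims=True)
        zonule_tris[s_name] = tris
        zonule_theta[s_name] = th
        zonule_fiber[s_name] = fib

        band_masters = node_id[outer_ids[band_idx]]  # (n_band, n_theta)
        for j in range(n_theta):
            masters = band_masters[:, j]
            w = np.full(len(masters), 1.0 / len(masters))
            ties.append(Tie(slave=int(ring_node_ids[0][j]), masters=masters, weights=w))

    mesh = FEMesh(
        nodes=np.vstack(coords_list),
        tets=tets,
        tet_region=tet_region,
        capsule_tris=capsule_tris,
        zonule_tris=zonule_tris,
        zonule_theta=zonule_theta,
        zonule_fiber_dir=zonule_fiber,
        node_sets=node_sets,
        ties=ties,
        n_theta=n_theta,
        sector_deg=360.0 / n_theta,
        outer_rings=outer_rings,
        outer_ring_arcs=arc_signed,
    )
    mesh.validate()
    return mesh
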