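"""Parametric geometry of the crystalline lens complex.

The lens is an axisymmetric body of revolution about the optical axis xi.
Anterior and posterior surfaces are "power-cap" profiles

    xi(r) = xi_eq +/- a * (1 - (r / R)^2)^q

where ``a`` is the cap height, ``R`` the equatorial radius and ``q`` an
exponent chosen so the central radius of curvature at the pole equals a
prescribed value (q = R^2 / (2 a r_pole); q = 1/2 recovers an ellipse). The
two caps meet at the equator with a vertical tangent, giving a smooth closed
contour. The nucleus is a scaled copy of the same construction nested inside
the cortex. Default dimensions are the package's calibrated 62-year-old
profile.

Coordinate and angle conventions used throughout the package:

* xi is the optical axis (+xi anterior); the equatorial plane is xi = 0;
* in 3D, xi maps to z, and the circumferential angle theta is measured from
  the superior direction (+y) towards +x, theta in [0, 360);
* "superior" structures sit near theta = 0, "inferior" near theta = 180.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LensShapeParams",
    "LensProfile",
    "GeometryParams",
    "LensComplex",
    "build_lens_profile",
    "build_complex",
    "OVAL_VARIANTS",
    "BAND_VARIANTS",
]


# Table of oval zonular variants: (vertical length, horizontal length) in mm.
# The vertical/horizontal split follows the frontal-view schematic in which
# the superior-inferior (vertical) fibres are the longer ones for "+" models.
OVAL_VARIANTS: dict[str, tuple[float, float]] = {
    "Oval-5.6": (1.500, 1.416),
    "Oval-2.8": (1.500, 1.458),
    "Initial": (1.500, 1.500),
    "Oval+2.8": (1.542, 1.500),
    "Oval+5.6": (1.584, 1.500),
}

# Capsular anchorage band widths (anterior, equatorial, posterior) in mm.
BAND_VARIANTS: dict[str, tuple[float, float, float]] = {
    "Ring": (0.0, 0.0, 0.0),
    "Band1": (0.167, 0.167, 0.133),
    "Band2": (0.333, 0.333, 0.267),
    "Band3": (0.500, 0.500, 0.400),
    "Band4": (0.590, 0.590, 0.548),
    "Band5": (0.680, 0.680, 0.695),
    "Band6": (0.770, 0.770, 0.843),
    "Band7": (0.860, 0.860, 0.990),
}


@dataclass(frozen=True)
class LensShapeParams:
    """Dimensional parameters of the axisymmetric lens profile (mm).

    Defaults are the package's calibrated accommodated 62-year-old lens.
    """

    thickness: float = 5.0
    diameter: float = 7.8
    anterior_fraction: float = 0.435  # share of thickness anterior to the equator
    anterior_pole_radius: float = 8.0  # central radius of curvature, anterior
    posterior_pole_radius: float = 5.75
    nucleus_thickness_fraction: float = 0.75
    nucleus_diameter_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.thickness <= 0 or self.diameter <= 0:
            raise ValueError("thickness and diameter must be positive")
        if not (0 < self.anterior_fraction < 1):
            raise ValueError("anterior_fraction must lie in (0, 1)")
        if self.anterior_pole_radius <= 0 or self.posterior_pole_radius <= 0:
            raise ValueError("pole radii must be positive")
        if not (0 < self.nucleus_thickness_fraction < 1):
            raise ValueError("nucleus fraction must lie strictly in (0, 1)")
        if not (0 < self.nucleus_diameter_fraction < 1):
            raise ValueError("nucleus fraction must lie strictly in (0, 1)")


@dataclass(frozen=True)
class _Cap:
    """One power-cap surface xi = sign * a (1 - (r/R)^2)^q + xi0."""

    a: float
    R: float
    q: float
    sign: float
    xi0: float = 0.0

    def xi(self, r: np.ndarray) -> np.ndarray:
        u = np.clip(1.0 - (np.asarray(r, dtype=float) / self.R) ** 2, 0.0, None)
        return self.xi0 + self.sign * self.a * u**self.q


def _cap_from_pole_radius(a: float, R: float, pole_radius: float, sign: float, xi0=0.0) -> _Cap:
    q = R * R / (2.0 * a * pole_radius)
    return _Cap(a=a, R=R, q=q, sign=sign, xi0=xi0)


@dataclass
class LensProfile:
    """Axisymmetric outer contours of nucleus and cortex.

    Contours are ordered (r, xi) polylines from the anterior pole (r = 0)
    over the equator to the posterior pole (r = 0); mirroring across the xi
    axis closes them.
    """

    nucleus_contour: np.ndarray
    cortex_contour: np.ndarray
    anterior_pole_xi: float
    posterior_pole_xi: float
    equator_radius: float
    cortex_caps: tuple[_Cap, _Cap] = None
    nucleus_caps: tuple[_Cap, _Cap] = None
    shape: LensShapeParams = None

    @property
    def thickness(self) -> float:
        return self.anterior_pole_xi - self.posterior_pole_xi

    def validate(self) -> None:
        for name, c in (("nucleus", self.nucleus_contour), ("cortex", self.cortex_contour)):
            if abs(c[0, 0]) > 1e-12 or abs(c[-1, 0]) > 1e-12:
                raise ValueError(f"{name} contour must start and end on the axis (r = 0)")
            if np.any(c[:, 0] < -1e-12):
                raise ValueError(f"{name} contour has negative radii")
        if not self._nested():
            raise ValueError("nucleus contour must lie strictly inside the cortex contour")

    def _nested(self) -> bool:
        ca, cp = self.cortex_caps
        na, npost = self.nucleus_caps
        r = self.nucleus_contour[:, 0]
        xi = self.nucleus_contour[:, 1]
        if np.max(r) >= self.equator_radius:
            return False
        inside = (xi <= ca.xi(r) + 1e-9) & (xi >= cp.xi(r) - 1e-9)
        strict = (xi < ca.xi(r) - 1e-9) | (r < 1e-9)
        strict &= (xi > cp.xi(r) + 1e-9) | (r < 1e-9)
        return bool(np.all(inside) and np.all(strict))


def _sample_contour(cap_ant: _Cap, cap_post: _Cap, R: float, n_half: int) -> np.ndarray:
    """Sample a closed half-contour with points clustered towards the equator.

    Uses r = R sin(pi/2 * u) spacing on each cap so the near-vertical equator
    region is resolved; the equator point is shared exactly.
    """
    u = np.sin(0.5 * np.pi * np.linspace(0.0, 1.0, n_half + 1))
    r_ant = R * u
    pts_ant = np.column_stack([r_ant, cap_ant.xi(r_ant)])
    r_post = R * u[::-1][1:]
    pts_post = np.column_stack([r_post, cap_post.xi(r_post)])
    return np.vstack([pts_ant, pts_post])


def build_lens_profile(params: LensShapeParams | None = None, n_half: int = 40) -> LensProfile:
    """Build the axisymmetric lens profile from dimensional parameters.

    ``n_half`` controls the sampling density of each cap of the stored
    contours (the caps themselves remain available analytically).
    """
    p = params or LensShapeParams()
    R = 0.5 * p.diameter
    a_ant = p.anterior_fraction * p.thickness
    a_post = (1.0 - p.anterior_fraction) * p.thickness
    cap_a = _cap_from_pole_radius(a_ant, R, p.anterior_pole_radius, +1.0)
    cap_p = _cap_from_pole_radius(a_post, R, p.posterior_pole_radius, -1.0)

    Rn = R * p.nucleus_diameter_fraction
    an_ant = a_ant * p.nucleus_thickness_fraction
    an_post = a_post * p.nucleus_thickness_fraction
    # nucleus caps reuse the cortex exponents, scaled to the nucleus axes
    ncap_a = _Cap(a=an_ant, R=Rn, q=cap_a.q, sign=+1.0)
    ncap_p = _Cap(a=an_post, R=Rn, q=cap_p.q, sign=-1.0)

    profile = LensProfile(
        nucleus_contour=_sample_contour(ncap_a, ncap_p, Rn, n_half),
        cortex_contour=_sample_contour(cap_a, cap_p, R, n_half),
        anterior_pole_xi=a_ant,
        posterior_pole_xi=-a_post,
        equator_radius=R,
        cortex_caps=(cap_a, cap_p),
        nucleus_caps=(ncap_a, ncap_p),
        shape=p,
    )
    profile.validate()
    return profile


@dataclass(frozen=True)
class GeometryParams:
    """Geometric parameters of capsule, zonules and anchorage bands.

    Lengths in mm unless suffixed _um. ``oval_vertical_length`` and
    ``oval_horizontal_length`` are the zonular lengths along the vertical
    (superior-inferior) and horizontal meridians; equal values give a
    circular (non-oval) outer edge.
    """

    capsule_thickness_um: float = 20.0
    zonule_length: float = 1.5
    zonule_angles_deg: tuple[float, float, float] = (-10.0, 0.0, 24.0)  # ZA, ZE, ZP
    zonule_thickness_um: float = 10.0
    oval_vertical_length: float = 1.5
    oval_horizontal_length: float = 1.5
    band_widths: tuple[float, float, float] = (0.0, 0.0, 0.0)  # anterior, equatorial, posterior
    attachment_arc_anterior: float = 0.6  # arc distance from equator to ZA insertion
    attachment_arc_posterior: float = 0.6  # arc distance from equator to ZP insertion

    def __post_init__(self) -> None:
        if min(self.capsule_thickness_um, self.zonule_thickness_um, self.zonule_length) <= 0:
            raise ValueError("thicknesses and zonule length must be positive")
        if self.oval_vertical_length <= 0 or self.oval_horizontal_length <= 0:
            raise ValueError("oval lengths must be positive")
        if min(self.band_widths) < 0:
            raise ValueError("band widths must be non-negative")
        ratio = max(self.oval_vertical_length, self.oval_horizontal_length) / min(
            self.oval_vertical_length, self.oval_horizontal_length
        )
        if ratio > 1.06 + 1e-9:
            raise ValueError("vertical/horizontal zonule length ratio exceeds 6%")

    @classmethod
    def from_variants(cls, oval: str = "Initial", band: str = "Ring", **kwargs) -> "GeometryParams":
        v, h = OVAL_VARIANTS[oval]
        widths = BAND_VARIANTS[band]
        return cls(
            oval_vertical_length=v, oval_horizontal_length=h, band_widths=widths, **kwargs
        )

    def zonule_length_at(self, theta_deg: np.ndarray) -> np.ndarray:
        """Zonular length vs circumferential angle (elliptic interpolation).

        theta = 0 is superior (vertical meridian), theta = 90 horizontal.
        """
        th = np.deg2rad(np.asarray(theta_deg, dtype=float))
        lv, lh = self.oval_vertical_length, self.oval_horizontal_length
        return lv * lh / np.sqrt((lh * np.cos(th)) ** 2 + (lv * np.sin(th)) ** 2)


@dataclass
class LensComplex:
    """Pre-mesh description: profile + zonular attachment layout on the capsule.

    The capsule surface coincides with the cortex outer surface. Attachment
    positions are stored as signed arc-length coordinates along the cortex
    contour, measured from the equator (positive towards the anterior pole).
    """

    profile: LensProfile
    params: GeometryParams
    attachment_arcs: dict[str, float] = field(default_factory=dict)  # set -> arc coord
    band_spans: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def zonule_sets(self) -> tuple[str, ...]:
        return ("ZA", "ZE", "ZP")


def build_complex(profile: LensProfile, params: GeometryParams | None = None) -> LensComplex:
    """Assemble the lens complex layout (capsule + three zonular annuli).

    The three zonular sets insert on the capsule at arc distances
    (+attachment_arc_anterior, 0, -attachment_arc_posterior) from the equator
    and emanate at the set angles relative to the equatorial plane.
    Anchorage bands of the requested widths are laid out around each
    insertion; overlapping bands are rejected.
    """
    params = params or GeometryParams()
    profile.validate()
    arcs = {
        "ZA": +params.attachment_arc_anterior,
        "ZE": 0.0,
        "ZP": -params.attachment_arc_posterior,
    }
    widths = dict(zip(("ZA", "ZE", "ZP"), (params.band_widths[0], params.band_widths[1], params.band_widths[2])))
    spans = {s: (arcs[s] - 0.5 * widths[s], arcs[s] + 0.5 * widths[s]) for s in arcs}
    order = ["ZP", "ZE", "ZA"]  # increasing arc coordinate
    for lo_set, hi_set in zip(order[:-1], order[1:]):
        if spans[lo_set][1] >= spans[hi_set][0] - 1e-9:
            raise ValueError(
                f"anchorage bands of {lo_set} and {hi_set} overlap; reduce band widths"
            )
    return LensComplex(profile=profile, params=params, attachment_arcs=arcs, band_spans=spans)
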