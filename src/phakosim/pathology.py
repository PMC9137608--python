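"""Pseudoexfoliation zonulopathy scenarios.

Zonular dialysis is modelled as a reduction of the reference thickness of
the affected zonular membrane over an angular arc:

* moderate dialysis: 50% of the fibres detached, thickness 5 um over the arc;
* severe dialysis: 5% of healthy thickness (0.5 um) over the stated core
  arc, flanked on both sides by transitional moderate regions (5 um) of one
  clock-hour (30 deg) by default; at 360 deg the flanks vanish.

Healthy thickness is 10 um. Extents follow the clinical clock-hour grading
(1, 3, 6, 9, 12 hours = 30, 90, 180, 270, 360 deg), centred on the superior
(theta = 0) or inferior (theta = 180) direction. The study's scenario space
is the five set-groups {ZA}, {ZE}, {ZP}, {ZA,ZE}, {ZA,ZE,ZP} x two
severities x five extents x two origins, with the origin collapsed for the
origin-independent 360-degree extent — 90 unique models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ZonulopathyScenario",
    "thickness_field",
    "enumerate_scenarios",
    "SET_GROUPS",
    "EXTENT_DEGREES",
    "HEALTHY_THICKNESS_UM",
    "MODERATE_THICKNESS_UM",
    "SEVERE_THICKNESS_UM",
]

SET_GROUPS: tuple[tuple[str, ...], ...] = (
    ("ZA",),
    ("ZE",),
    ("ZP",),
    ("ZA", "ZE"),
    ("ZA", "ZE", "ZP"),
)
EXTENT_HOURS = (1, 3, 6, 9, 12)
EXTENT_DEGREES = (30, 90, 180, 270, 360)
HEALTHY_THICKNESS_UM = 10.0
MODERATE_THICKNESS_UM = 5.0
SEVERE_THICKNESS_UM = 0.5


@dataclass(frozen=True)
class ZonulopathyScenario:
    """One zonular dialysis configuration."""

    affected_sets: tuple[str, ...]
    severity: str  # "moderate" | "severe"
    extent_deg: int  # 30/90/180/270/360 (core arc)
    origin: str  # "superior" | "inferior"

    def __post_init__(self) -> None:
        order = {"ZA": 0, "ZE": 1, "ZP": 2}
        if tuple(sorted(self.affected_sets, key=order.get)) not in {
            tuple(sorted(g, key=order.get)) for g in SET_GROUPS
        }:
            raise ValueError(f"unsupported set group {self.affected_sets}")
        if self.severity not in ("moderate", "severe"):
            raise ValueError("severity must be 'moderate' or 'severe'")
        if self.extent_deg not in EXTENT_DEGREES and self.extent_deg != 0:
            raise ValueError("extent must be one of 30/90/180/270/360 degrees")
        if self.origin not in ("superior", "inferior"):
            raise ValueError("origin must be 'superior' or 'inferior'")

    @property
    def extent_hours(self) -> int:
        return self.extent_deg // 30

    @property
    def scenario_id(self) -> str:
        sets = "+".join(self.affected_sets)
        return f"{sets}-{self.severity}-{self.extent_deg}-{self.origin}"


def _angular_distance(theta_deg: np.ndarray, center_deg: float) -> np.ndarray:
    d = np.abs((np.asarray(theta_deg, dtype=float) - center_deg) % 360.0)
    return np.minimum(d, 360.0 - d)


def thickness_field(
    scenario: ZonulopathyScenario,
    flank_deg: float = 30.0,
    healthy_um: float = HEALTHY_THICKNESS_UM,
    moderate_um: float = MODERATE_THICKNESS_UM,
    severe_um: float = SEVERE_THICKNESS_UM,
):
    """Per-set zonular thickness as a function of circumferential angle.

    Returns ``field(set_name, theta_deg) -> thickness_um`` (vectorised).
    The stated extent measures the core arc; for severe dialysis the
    transitional flanks are additional, one clock-hour per side by default.
    """
    center = 0.0 if scenario.origin == "superior" else 180.0
    half = 0.5 * scenario.extent_deg
    affected = set(scenario.affected_sets)

    def field(set_name: str, theta_deg):
        theta_deg = np.asarray(theta_deg, dtype=float)
        t = np.full(theta_deg.shape, healthy_um)
        if set_name not in affected or scenario.extent_deg == 0:
            return t
        d = _angular_distance(theta_deg, center)
        core = d <= half + 1e-9
        if scenario.severity == "moderate":
            t[core] = moderate_um
        else:
            t[core] = severe_um
            flank = (~core) & (d <= half + flank_deg + 1e-9)
            t[flank] = moderate_um
        return t

    return field


def enumerate_scenarios() -> list[ZonulopathyScenario]:
    """The study's 90 unique zonulopathy models, in deterministic order.

    Ordering: set group, then severity (moderate first), then extent, then
    origin (superior first). A 360-degree dialysis is origin-independent, so
    it appears once, canonically labelled superior.
    """
    out: list[ZonulopathyScenario] = []
    for group in SET_GROUPS:
        for severity in ("moderate", "severe"):
            for extent in EXTENT_DEGREES:
                origins = ("superior",) if extent == 360 else ("superior", "inferior")
                for origin in origins:
                    out.append(ZonulopathyScenario(group, severity, extent, origin))
    return out
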