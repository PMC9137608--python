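"""Study orchestration: model runs, sweeps and superior/inferior comparison.

One *model run* = build geometry -> mesh -> assign zonular thickness field
-> disaccommodation protocol -> metrics record. The pseudoexfoliation sweep
enumerates the 90 zonulopathy scenarios on the optimised base configuration
(Oval+5.6 zonular geometry, Band4 anchorage, gravity on) and tabulates one
metrics row per model.

The superior/inferior comparison uses the signed percentage

    lambda% = (value_inferior - value_superior) / value_superior * 100

for each metric of each matched scenario pair (same sets, severity, extent).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fem import BoundaryProtocol, LensModel, Materials
from .geometry import GeometryParams, LensShapeParams, build_complex, build_lens_profile
from .mesh import FEMesh, generate_mesh
from .optics import MetricsRecord, OpticalConstants, compute_metrics
from .pathology import ZonulopathyScenario, enumerate_scenarios, thickness_field

__all__ = [
    "MESH_PRESETS",
    "RunConfig",
    "build_model",
    "run_model",
    "run_study",
    "lambda_percent",
    "compare_superior_inferior",
]

# Mesh presets: target edge length (mm), angular sectors, zonule strips.
# "smoke" resolves trends at minimum cost, "ci" is the default working
# resolution, "paper" the fine resolution used for quantitative readouts.
MESH_PRESETS: dict[str, dict] = {
    "smoke": dict(target_edge_length=1.7, n_theta=24),
    "ci": dict(target_edge_length=0.9, n_theta=24),
    "paper": dict(target_edge_length=0.65, n_theta=48),
}


@dataclass(frozen=True)
class RunConfig:
    """Fully serialisable configuration of one run or sweep."""

    shape: LensShapeParams = field(default_factory=LensShapeParams)
    oval_variant: str = "Oval+5.6"
    band_variant: str = "Band4"
    mesh_preset: str = "ci"
    gravity: bool = True
    delta_z: float = 0.5
    n_steps: int = 6
    flank_deg: float = 30.0
    zone_radius: float = 2.5
    optics: OpticalConstants = field(default_factory=OpticalConstants)

    def content_hash(self) -> str:
        payload = json.dumps(
            {
                "shape": asdict(self.shape),
                "oval": self.oval_variant,
                "band": self.band_variant,
                "mesh": self.mesh_preset,
                "gravity": self.gravity,
                "delta_z": self.delta_z,
                "n_steps": self.n_steps,
                "flank": self.flank_deg,
                "zone": self.zone_radius,
                "optics": asdict(self.optics),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def build_base_mesh(config: RunConfig) -> FEMesh:
    profile = build_lens_profile(config.shape)
    params = GeometryParams.from_variants(config.oval_variant, config.band_variant)
    complex_ = build_complex(profile, params)
    return generate_mesh(complex_, **MESH_PRESETS[config.mesh_preset])


def build_model(
    config: RunConfig,
    scenario: ZonulopathyScenario | None = None,
    mesh: FEMesh | None = None,
    materials: Materials | None = None,
) -> LensModel:
    """Assemble a ready-to-run model; ``mesh`` may be shared between runs."""
    if mesh is None:
        mesh = build_base_mesh(config)
    protocol = BoundaryProtocol(
        delta_z=config.delta_z, n_steps=config.n_steps, gravity=config.gravity
    )
    thickness: dict[str, np.ndarray] | None = None
    if scenario is not None:
        fld = thickness_field(scenario, flank_deg=config.flank_deg)
        thickness = {s: fld(s, mesh.zonule_theta[s]) for s in mesh.zonule_tris}
    return LensModel(mesh, materials=materials, protocol=protocol, zonule_thickness_um=thickness)


def run_model(
    config: RunConfig,
    scenario: ZonulopathyScenario | None = None,
    mesh: FEMesh | None = None,
    materials: Materials | None = None,
) -> tuple[LensModel, MetricsRecord]:
    """Run one model (healthy if scenario is None) and post-process it."""
    model = build_model(config, scenario, mesh, materials)
    result = model.solve()
    record = compute_metrics(model, result, config.optics, config.zone_radius)
    return model, record


def _scenario_row(scenario: ZonulopathyScenario | None, record: MetricsRecord) -> dict:
    row = {
        "scenario_id": "healthy" if scenario is None else scenario.scenario_id,
        "sets": "" if scenario is None else "+".join(scenario.affected_sets),
        "severity": "" if scenario is None else scenario.severity,
        "extent_deg": 0 if scenario is None else scenario.extent_deg,
        "origin": "" if scenario is None else scenario.origin,
    }
    row.update(record.as_row())
    return row


def run_study(
    config: RunConfig,
    scenarios: list[ZonulopathyScenario] | None = None,
    include_healthy: bool = True,
    out_dir: str | Path | None = None,
    verbose: bool = False,
) -> pd.DataFrame:
    """Run a scenario sweep on a shared mesh and tabulate the metrics.

    ``scenarios`` defaults to the full 90-model enumeration. With
    ``out_dir`` set, each finished row is cached as a JSON file keyed by the
    config hash and scenario id; completed runs are skipped on re-entry and
    the combined table is written as CSV. Individual model failures are
    recorded (``failed`` column) without aborting the sweep.
    """
    if scenarios is None:
        scenarios = enumerate_scenarios()
    mesh = build_base_mesh(config)
    cache = None
    if out_dir is not None:
        cache = Path(out_dir) / config.content_hash()
        cache.mkdir(parents=True, exist_ok=True)

    rows = []
    todo: list[ZonulopathyScenario | None] = ([None] if include_healthy else []) + list(scenarios)
    for scenario in todo:
        sid = "healthy" if scenario is None else scenario.scenario_id
        if cache is not None and (cache / f"{sid}.json").exists():
            rows.append(json.loads((cache / f"{sid}.json").read_text()))
            continue
        try:
            _, record = run_model(config, scenario, mesh)
            row = _scenario_row(scenario, record)
            row["failed"] = False
        except RuntimeError as exc:
            row = {"scenario_id": sid, "failed": True, "error": str(exc)}
        if verbose:
            print(f"[{sid}] done", flush=True)
        if cache is not None:
            (cache / f"{sid}.json").write_text(json.dumps(row))
        rows.append(row)
    df = pd.DataFrame(rows)
    if cache is not None:
        df.to_csv(cache / "metrics.csv", index=False)
    return df


# ---------------------------------------------------------------------------
# Superior vs inferior comparison
# ---------------------------------------------------------------------------


def lambda_percent(value_inf: float, value_sup: float) -> float:
    """Signed percent difference of inferior vs superior model outputs."""
    if value_sup == 0:
        raise ZeroDivisionError("superior value is zero; lambda undefined")
    return (value_inf - value_sup) / value_sup * 100.0


#: metrics compared between superior- and inferior-origin models
COMPARED_METRICS = (
    "delta_thickness_pct",
    "delta_radius_pct",
    "zonular_force_mn",
    "capsule_vms_avg_kpa",
    "zonule_vms_max_kpa",
    "lens_vms_max_kpa",
    "delta_cop_d",
)


def compare_superior_inferior(
    table: pd.DataFrame, metrics: tuple[str, ...] = COMPARED_METRICS
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise lambda% table plus per-set-group averages.

    Pairs are matched on (sets, severity, extent); extents of 360 degrees
    have a single origin-independent model and are excluded. Unmatched pairs
    are reported with NaN lambdas and excluded from averages.
    """
    df = table[(table["scenario_id"] != "healthy") & (~table.get("failed", False))]
    rows = []
    for (sets, severity, extent), grp in df.groupby(["sets", "severity", "extent_deg"]):
        if extent == 360:
            continue
        sup = grp[grp["origin"] == "superior"]
        inf = grp[grp["origin"] == "inferior"]
        for metric in metrics:
            row = {
                "sets": sets,
                "severity": severity,
                "extent_deg": extent,
                "metric": metric,
            }
            if len(sup) == 1 and len(inf) == 1 and metric in grp:
                vs = float(sup.iloc[0][metric])
                vi = float(inf.iloc[0][metric])
                row["value_sup"] = vs
                row["value_inf"] = vi
                row["lambda_pct"] = lambda_percent(vi, vs) if vs != 0 else np.nan
            else:
                row["lambda_pct"] = np.nan
            rows.append(row)
    pairs = pd.DataFrame(rows)
    averages = (
        pairs.dropna(subset=["lambda_pct"])
        .groupby(["sets", "metric"])["lambda_pct"]
        .mean()
        .reset_index()
        .rename(columns={"lambda_pct": "lambda_avg_pct"})
    )
    return pairs, averages
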