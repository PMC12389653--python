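"""Scenario orchestration: mesh, solve, metrics, outputs, manifest.

For every scenario the pipeline builds the geometry and mesh, solves the
conduction problem, re-tags the same mesh as a no-NP baseline and solves
that too (discretisation-matched comparison), computes the amplification
metrics, and writes: a field profile CSV (gap scenarios), a JSON report,
and a run manifest recording versions, controls and tolerances -- enough to
reproduce every number exactly (the whole chain is deterministic).
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .fem import assemble_and_solve, FieldSolution
from .geometry import build_geometry
from .meshing import generate_mesh, Mesh
from .metrics import (amplification_report, evaluation_line_profile,
                      matched_baseline_mesh, membrane_field_station)
from .model import MeshControls, PlacementMode, ScenarioSpec, default_materials


@dataclass
class ScenarioResult:
    spec: ScenarioSpec
    mesh: Mesh
    solution: FieldSolution
    baseline: FieldSolution          # matched-mesh baseline (== solution when no NP)
    report: dict | None


def solve_scenario(spec: ScenarioSpec, level: float | None = None,
                   order: int = 2) -> ScenarioResult:
    """Mesh and solve one scenario plus its matched baseline."""
    controls = spec.mesh_controls
    if level is not None:
        controls = controls.model_copy(update={"level": level})
    geom = build_geometry(spec)
    mesh = generate_mesh(geom, controls)
    mats = dict(spec.materials)
    sol = assemble_and_solve(mesh, mats, spec.domain.applied_voltage, order=order)
    if spec.nanoparticle is None:
        return ScenarioResult(spec=spec, mesh=mesh, solution=sol,
                              baseline=sol, report=None)
    mesh0 = matched_baseline_mesh(mesh)
    sol0 = assemble_and_solve(mesh0, mats, spec.domain.applied_voltage, order=order)
    rep = amplification_report(sol, sol0).to_dict()
    return ScenarioResult(spec=spec, mesh=mesh, solution=sol, baseline=sol0,
                          report=rep)


def run_pipeline(specs: list[ScenarioSpec], out_dir: str | Path,
                 level: float | None = None, order: int = 2) -> dict:
    """Run a scenario set and write profiles, reports and the manifest.

    Returns the manifest dict.  Solver failure on any scenario is recorded
    in the manifest under ``failed`` and re-raised at the end.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "order": order,
        "level": level,
        "tolerances": {"solver_backward_error": 1e-10,
                       "quality_floor_deg": 15.0},
        "scenarios": {},
        "failed": {},
    }
    first_error = None
    for spec in specs:
        try:
            res = solve_scenario(spec, level=level, order=order)
        except Exception as exc:
            manifest["failed"][spec.label] = str(exc)
            if first_error is None:
                first_error = exc
            continue
        entry = {
            "mesh": res.mesh.quality_report(res.mesh.refined_window_mask()),
            "controls": json.loads(res.spec.mesh_controls.model_dump_json()),
            "drive_V": res.spec.domain.applied_voltage,
        }
        is_gap = (spec.nanoparticle is not None
                  and spec.nanoparticle.placement_mode is PlacementMode.GAP)
        if spec.nanoparticle is None or is_gap:
            prof = evaluation_line_profile(res.solution)
            prof.to_frame().to_csv(out / f"{spec.label}_profile.csv", index=False)
            entry["profile_csv"] = f"{spec.label}_profile.csv"
        if res.report is not None:
            _write_json(out / f"{spec.label}_report.json", res.report)
            entry["report_json"] = f"{spec.label}_report.json"
            entry["report"] = res.report
        else:
            th0 = 0.0 if spec.nanoparticle is None else spec.nanoparticle.angular_position
            entry["membrane_field_summary_V_per_cm"] = {
                "window_centre_station": membrane_field_station(
                    res.solution, th0) * 1e-2}
        manifest["scenarios"][spec.label] = entry
    _write_json(out / "manifest.json", manifest)
    if first_error is not None:
        raise first_error
    return manifest


def _write_json(path: Path, obj) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o).__name__)

    path.write_text(json.dumps(obj, indent=2, default=default,
                               allow_nan=True) + "\n")
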