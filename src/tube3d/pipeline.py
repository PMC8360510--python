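"""End-to-end pipeline: phantom -> section -> align -> register -> profile
-> torsion -> mesh, driven by one configuration and one global seed.

Each stage writes its artefacts under the output directory and contributes
a summary to the JSON run report.  Stage toggles must respect the
dependency chain (e.g. torsion needs alignment); a failed stage marks the
report and skips everything downstream.  Identical configuration + seed
produces byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import alignment, mesh, morphometry, registration, sectioning, stack_io, torsion
from .phantom import PhantomSpec, build_phantom, make_reference_volume
from .presets import spawn_seed, specimen_phantom_spec, specimen_protocol
from .sectioning import ProtocolSpec

log = logging.getLogger("tube3d")

STAGE_ORDER = ["phantom", "section", "align", "register", "profile", "torsion", "mesh"]
STAGE_DEPS = {
    "section": ["phantom"],
    "align": ["section"],
    "register": ["align", "phantom"],
    "profile": ["align"],
    "torsion": ["align"],
    "mesh": ["align"],
}


@dataclass
class PipelineConfig:
    phantom: PhantomSpec = field(default_factory=specimen_phantom_spec)
    protocol: ProtocolSpec = field(default_factory=specimen_protocol)
    out_dir: Path = Path("tube3d_run")
    stages: dict = field(default_factory=lambda: {s: True for s in STAGE_ORDER})
    mesh_labels: tuple[str, ...] = ("cartilage", "lumen", "TVPM", "LVPM", "OFP", "bone")
    write_volumes: bool = False
    seed: int = 0

    def validate(self) -> None:
        enabled = {s for s in STAGE_ORDER if self.stages.get(s, False)}
        if not enabled:
            raise ValueError("no pipeline stages enabled")
        for stage in enabled:
            missing = [d for d in STAGE_DEPS.get(stage, []) if d not in enabled]
            if missing:
                raise ValueError(
                    f"stage {stage!r} requires {missing} but they are disabled"
                )


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and return the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    state: dict = {}
    failed = False
    for stage in STAGE_ORDER:
        if not config.stages.get(stage, False):
            continue
        entry: dict = {"status": "skipped_due_to_failure"} if failed else {}
        if failed:
            report["stages"][stage] = entry
            continue
        t0 = time.perf_counter()
        try:
            summary = _STAGE_FUNCS[stage](config, state, out)
            entry = {"status": "ok", **summary}
        except Exception as exc:  # noqa: BLE001 - report and halt downstream
            log.error("stage=%s status=failed error=%r", stage, exc)
            entry = {"status": "failed", "error": str(exc)}
            failed = True
        entry["elapsed_s"] = round(time.perf_counter() - t0, 3)
        log.info("stage=%s status=%s elapsed_s=%s", stage, entry["status"],
                 entry["elapsed_s"])
        report["stages"][stage] = entry
    report["ok"] = not failed
    _json_dump(report, out / "run_report.json")
    return report


def _stage_phantom(config: PipelineConfig, state: dict, out: Path) -> dict:
    vol, truth = build_phantom(config.phantom)
    state["phantom"] = vol
    state["truth"] = truth
    _json_dump(truth, out / "phantom_truth.json")
    summary = {
        "shape_zyx": list(vol.voxels.shape),
        "twist_total_deg": truth["spec_twist_total_deg"],
    }
    if config.write_volumes:
        stack_io.write_volume(vol, out / "phantom.nrrd")
        dens, spacing = make_reference_volume(vol)
        stack_io.write_density(dens, spacing, out / "reference.nrrd")
        summary["reference_spacing_mm"] = list(spacing)
    return summary


def _stage_section(config: PipelineConfig, state: dict, out: Path) -> dict:
    rng = spawn_seed(config.seed, "section")
    sections = sectioning.simulate_sectioning(state["phantom"], config.protocol, rng)
    state["sections"] = sections
    stack_dir = out / "sections"
    stack_io.write_stack(sections, stack_dir)
    return {
        "n_sections": len(sections),
        "lost": list(config.protocol.lost_indices()),
        "stack_dir": str(stack_dir),
    }


def _stage_align(config: PipelineConfig, state: dict, out: Path) -> dict:
    result, volume = alignment.align_stack(state["sections"], config.protocol)
    state["alignment"] = result
    state["aligned"] = volume
    result.residuals.to_csv(out / "residuals.csv", index=False, float_format="%.9g")
    if config.write_volumes:
        stack_io.write_volume(volume, out / "aligned.nrrd")
    return {
        "rms_residual_mm": result.rms_residual_mm,
        "noise_sigma_mm": result.noise_sigma_mm,
        "n_iterations": int(len(result.cost_history)),
        "final_cost": float(result.cost_history[-1]),
        "n_interpolated": int(result.interpolated.sum()),
    }


def _stage_register(config: PipelineConfig, state: dict, out: Path) -> dict:
    result = state["alignment"]
    moving = registration.extract_stack_landmarks(result.lines, result.z_mm)
    z = [float(result.z_mm.min()), float(np.median(result.z_mm)),
         float(result.z_mm.max())]
    fixed = registration.sample_lines(state["truth"]["fiducial_lines"], z)
    transform, fre = registration.register_landmarks(moving, fixed)
    _json_dump(
        {"matrix4": transform.matrix4().tolist(), "fre_mm": fre},
        out / "registration.json",
    )
    return {"fre_mm": fre}


def _stage_profile(config: PipelineConfig, state: dict, out: Path) -> dict:
    df = morphometry.profile(state["aligned"])
    df.to_csv(out / "profile.csv", index=False, float_format="%.9g")
    return {"n_rows": int(len(df)), "compartments": sorted(df["compartment"].unique())}


def _stage_torsion(config: PipelineConfig, state: dict, out: Path) -> dict:
    est = torsion.total_torsion(state["aligned"])
    est.table.to_csv(out / "torsion.csv", index=False, float_format="%.9g")
    _json_dump(est.summary(), out / "torsion.json")
    return est.summary()


def _stage_mesh(config: PipelineConfig, state: dict, out: Path) -> dict:
    present = [
        lab for lab in config.mesh_labels
        if np.any(state["aligned"].voxels == state["aligned"].label_scheme[lab])
    ]
    written = mesh.export_compartments(state["aligned"], present, out / "meshes")
    return {"stl_files": {k: str(v) for k, v in written.items()}}


_STAGE_FUNCS = {
    "phantom": _stage_phantom,
    "section": _stage_section,
    "align": _stage_align,
    "register": _stage_register,
    "profile": _stage_profile,
    "torsion": _stage_torsion,
    "mesh": _stage_mesh,
}
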