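"""End-to-end per-case orchestration of the 3D surface pipeline.

For every cardiac phase: threshold segmentation -> seeded component
selection -> marching-cubes surface -> plane crop of the appendage ->
ostium plane fit and contour -> capping -> voxel-counting volumetry.  The
threshold and landmarks defined on the first phase are reused for the
remaining phases (operator input is typically needed only once per case).
Phase-resolved volumes then give the ejection fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as laa_io
from .core import ImageVolume, LandmarkSet, PhaseStack, Plane
from .function_stats import BodyMetrics, FunctionReport, PhaseSeries, ejection_fraction
from .morphometry import (
    close_surface,
    contour_area,
    fit_plane,
    intersect_mesh_plane,
    voxelize_volume,
)
from .segmentation import apply_threshold, auto_threshold, select_component
from .surface import CropSpec, crop_mesh, extract_surface, mesh_volume

__all__ = ["CaseConfig", "CaseReport", "run_case", "run_phases"]

SCHEMA_VERSION = "1"


@dataclass
class CaseConfig:
    """Inputs for one patient case."""

    volume_paths: list[str]
    landmarks_path: str
    phase_percents: list[float] | None = None
    threshold_override: float | None = None
    voxel_spacing: tuple[float, float, float] | None = None  # default: source CT spacing
    crop_margin_mm: float = 2.0
    smoothing_iterations: int = 0
    output_dir: str | None = None
    body: BodyMetrics | None = None

    def __post_init__(self) -> None:
        if len(self.volume_paths) < 1:
            raise ValueError("at least one phase volume is required")


@dataclass
class CaseReport:
    """Per-phase morphology plus cycle-level function for one case."""

    phase_percents: list[float]
    ostium_areas_cm2: list[float]
    voxel_volumes_cm3: list[float]
    mesh_volumes_cm3: list[float]
    function: FunctionReport | None
    normalized: dict[str, float] = field(default_factory=dict)
    decisions: dict = field(default_factory=dict)
    schema_version: str = SCHEMA_VERSION

    def to_dict(self) -> dict:
        d = {
            "schema_version": self.schema_version,
            "phase_percents": self.phase_percents,
            "ostium_areas_cm2": self.ostium_areas_cm2,
            "voxel_volumes_cm3": self.voxel_volumes_cm3,
            "mesh_volumes_cm3": self.mesh_volumes_cm3,
            "decisions": self.decisions,
            "normalized": self.normalized,
        }
        if self.function is None:
            d["function"] = None
            d["ef_note"] = "single phase: ejection fraction requires >= 2 phases"
        else:
            f = self.function
            d["function"] = {
                "ef": f.ef,
                "ef_percent": f.ef_percent,
                "diastolic_index": f.diastolic_index,
                "systolic_index": f.systolic_index,
                "diastolic_volume_cm3": f.diastolic_volume,
                "systolic_volume_cm3": f.systolic_volume,
                "diastolic_phase_percent": f.diastolic_phase_percent,
                "systolic_phase_percent": f.systolic_phase_percent,
            }
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _stage(phase: int, name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"phase {phase}, stage {name}: {exc}") from exc
            return False

    return _Ctx()


class _StageError(RuntimeError):
    """Pipeline failure annotated with the phase index and stage name."""


def run_phases(
    stack: PhaseStack,
    landmarks: LandmarkSet,
    threshold_override: float | None = None,
    voxel_spacing=None,
    crop_margin_mm: float = 2.0,
    smoothing_iterations: int = 0,
    output_dir=None,
    body: BodyMetrics | None = None,
) -> CaseReport:
    """Run the full surface pipeline on an in-memory phase stack."""
    laa_seed = landmarks.single("laa_seed")
    ostium_pts = landmarks.with_role("ostium_cut")
    if len(ostium_pts) < 3:
        raise ValueError("need at least 3 ostium_cut landmarks to fit the cutting plane")
    la_seeds = landmarks.with_role("la_seed")
    seg_seed = la_seeds[0] if len(la_seeds) else laa_seed
    anchor = ostium_pts.mean(axis=0)
    out = Path(output_dir) if output_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    threshold = threshold_override
    areas, vox_vols, mesh_vols, cap_methods = [], [], [], []
    for k, vol in enumerate(stack.volumes):
        with _stage(k, "threshold"):
            if threshold is None:
                threshold = auto_threshold(vol)  # phase 0 value reused downstream
            mask = apply_threshold(vol, threshold)
        with _stage(k, "component"):
            mask = select_component(mask, seg_seed)
        with _stage(k, "surface"):
            mesh = extract_surface(mask, smoothing_iterations)
        with _stage(k, "ostium_plane"):
            plane = fit_plane(ostium_pts, mesh=mesh)
            toward_laa = 1.0 if float(plane.signed_distance(laa_seed)[0]) > 0 else -1.0
        with _stage(k, "crop"):
            crop_plane = Plane(
                plane.point - toward_laa * crop_margin_mm * plane.normal, plane.normal
            )
            cropped = crop_mesh(mesh, CropSpec(crop_plane, laa_seed))
        with _stage(k, "ostium_contour"):
            contour = intersect_mesh_plane(cropped, plane, anchor=anchor)
        with _stage(k, "close"):
            distal = crop_mesh(cropped, CropSpec(plane, laa_seed))
            model = close_surface(distal, contour)
        with _stage(k, "voxelize"):
            spacing = vol.spacing if voxel_spacing is None else np.asarray(voxel_spacing)
            v_vox, _ = voxelize_volume(model, spacing)
        areas.append(contour_area(contour))
        vox_vols.append(v_vox)
        mesh_vols.append(mesh_volume(model.mesh))
        cap_methods.append(model.cap_method)
        if out is not None:
            laa_io.write_stl(mesh, out / f"phase{k:02d}_la.stl")
            laa_io.write_stl(model.mesh, out / f"phase{k:02d}_laa_closed.stl")

    function = None
    if len(stack) >= 2:
        series = PhaseSeries(stack.phase_percents, vox_vols, areas)
        function = ejection_fraction(series)

    normalized: dict[str, float] = {}
    if body is not None and function is not None:
        bsa = body.bsa_m2
        normalized = {
            "bsa_m2": bsa,
            "diastolic_volume_cm3_per_m2": function.diastolic_volume / bsa,
            "systolic_volume_cm3_per_m2": function.systolic_volume / bsa,
            "diastolic_ostium_area_cm2_per_m2": areas[function.diastolic_index] / bsa,
            "systolic_ostium_area_cm2_per_m2": areas[function.systolic_index] / bsa,
        }

    report = CaseReport(
        phase_percents=[float(p) for p in stack.phase_percents],
        ostium_areas_cm2=areas,
        voxel_volumes_cm3=vox_vols,
        mesh_volumes_cm3=mesh_vols,
        function=function,
        normalized=normalized,
        decisions={
            "threshold": threshold,
            "loop_selection": "anchor (ostium landmark centroid)",
            "crop_margin_mm": crop_margin_mm,
            "cap_methods": cap_methods,
            "smoothing_iterations": smoothing_iterations,
        },
    )
    if out is not None:
        (out / "report.json").write_text(report.to_json())
    return report


def run_case(config: CaseConfig) -> CaseReport:
    """Load a case from disk and run the full pipeline."""
    volumes: list[ImageVolume] = []
    for k, p in enumerate(config.volume_paths):
        volumes.append(laa_io.read_volume(p))
    n = len(volumes)
    if config.phase_percents is not None:
        phases = [float(p) for p in config.phase_percents]
    else:
        labels = [v.phase_label for v in volumes]
        if all(l is not None for l in labels) and n > 1:
            phases = [float(l) for l in labels]  # type: ignore[arg-type]
        else:
            phases = [100.0 * k / n for k in range(n)]
    stack = PhaseStack(volumes, phases)
    landmarks = laa_io.read_landmarks(config.landmarks_path)
    return run_phases(
        stack,
        landmarks,
        threshold_override=config.threshold_override,
        voxel_spacing=config.voxel_spacing,
        crop_margin_mm=config.crop_margin_mm,
        smoothing_iterations=config.smoothing_iterations,
        output_dir=config.output_dir,
        body=config.body,
    )
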