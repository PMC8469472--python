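"""End-to-end pipeline: orient -> section -> landmarks -> measure -> report.

Deterministic: identical inputs and configuration produce byte-identical
artifacts.  Every stage's intermediate result is saved so runs can be
inspected instead of paused.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np

from . import landmarks as lm
from . import measures, mesh_io, orientation, sectioning, surface_analysis
from .errors import AdoError, ConfigError

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    curvature_radius: float | None = None   # mm; None = 5x mean edge length
    border_percentile: float = 90.0
    max_iterations: int = 10
    iteration_tolerance: float = 0.005      # radians
    ns: int = 80
    landmark_mode: str = "euclidean"        # euclidean | curvature
    curvature_window: float = 0.5           # mm, curvature landmark mode
    exclusion: str = "invalid"              # invalid | trim | none
    tooth_number: int | None = None
    buccal_mark: tuple | None = None        # 3D hint point on the buccal side
    output_dir: str = "ado_output"
    landmark_overrides: dict = field(default_factory=dict)  # {section: {layer: {name: [x, y]}}}
    write_svg: bool = False

    def validate(self) -> None:
        if self.ns < 1:
            raise ConfigError("ns must be >= 1")
        if not 0 <= self.border_percentile <= 100:
            raise ConfigError("border_percentile must be in [0, 100]")
        if self.curvature_radius is not None and self.curvature_radius <= 0:
            raise ConfigError("curvature_radius must be positive")
        if self.max_iterations < 1:
            raise ConfigError("max_iterations must be >= 1")
        if self.iteration_tolerance <= 0:
            raise ConfigError("iteration_tolerance must be positive")
        if self.landmark_mode not in ("euclidean", "curvature"):
            raise ConfigError("landmark_mode must be 'euclidean' or 'curvature'")
        if self.curvature_window <= 0:
            raise ConfigError("curvature_window must be positive")
        if self.exclusion not in ("invalid", "trim", "none"):
            raise ConfigError("exclusion must be invalid/trim/none")

    # -- flat key=value round trip -----------------------------------------

    def to_file(self, path) -> None:
        lines = []
        for f in dc_fields(self):
            value = getattr(self, f.name)
            lines.append(f"{f.name} = {json.dumps(value)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        names = {f.name for f in dc_fields(cls)}
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"malformed config line: {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in names:
                raise ConfigError(f"unknown config key {key!r}")
            try:
                kwargs[key] = json.loads(value)
            except json.JSONDecodeError as exc:
                raise ConfigError(f"bad value for {key}: {value!r}") from exc
        cfg = cls(**kwargs)
        if cfg.buccal_mark is not None:
            cfg.buccal_mark = tuple(cfg.buccal_mark)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    frame: orientation.ToothFrame
    border: orientation.OcclusalBorder
    contours: list
    sections_by_layer: dict
    report: measures.ToothReport
    ratios: dict
    artifacts: dict  # name -> path


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not serialisable: {type(obj)}")


def _dump_json(data, path: Path) -> None:
    path.write_text(json.dumps(data, indent=1, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: PipelineConfig, mesh_path, surface=None) -> PipelineResult:
    """Execute the full measurement pipeline on one crown mesh.

    Stage failures abort with the stage name; artifacts produced so far
    are retained in the output directory.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict = {}

    def stage(name):
        log.info("stage: %s", name)
        return name

    current = stage("load")
    try:
        if surface is None:
            surface = mesh_io.load_surface(mesh_path)
        surface.validate()

        current = stage("curvature")
        field_ = surface_analysis.estimate_curvature(surface, config.curvature_radius)

        current = stage("orient")
        border, frame = orientation.iterate_orientation(
            surface,
            field_,
            percentile=config.border_percentile,
            max_iterations=config.max_iterations,
            tolerance=config.iteration_tolerance,
        )
        if config.buccal_mark is not None:
            # flip the vestibulo-oral axis toward the marked buccal side
            hint = np.asarray(config.buccal_mark, float) - frame.origin
            if hint @ frame.vestibulooral_axis < 0:
                frame = orientation.ToothFrame(
                    origin=frame.origin,
                    vertical_axis=frame.vertical_axis,
                    mesiodistal_axis=-frame.mesiodistal_axis,
                    vestibulooral_axis=-frame.vestibulooral_axis,
                    iterations_used=frame.iterations_used,
                    converged=frame.converged,
                    calibrated=frame.calibrated,
                )
        frame_path = outdir / "frame.json"
        _dump_json(
            {
                "transform": frame.to_matrix(),
                "iterations_used": frame.iterations_used,
                "converged": frame.converged,
                "calibrated": frame.calibrated,
                "tooth_number": config.tooth_number,
                "border_vertices": border.vertex_indices,
            },
            frame_path,
        )
        artifacts["frame"] = str(frame_path)

        current = stage("section")
        basis = np.array([1.0, 0.0, 0.0])
        if abs(frame.vertical_axis[0]) >= 0.9:
            basis = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(frame.vertical_axis, basis)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(frame.vertical_axis, e1)
        border2 = np.column_stack(
            [(border.points - frame.origin) @ e1, (border.points - frame.origin) @ e2]
        )
        ellipse = sectioning.fit_ellipse(border2)
        planes = sectioning.generate_planes(frame, ellipse, surface, config.ns)
        contours = sectioning.cut_surface(surface, planes, frame)
        contours_path = outdir / "contours.csv"
        sectioning.contours_to_frame(contours).to_csv(contours_path, index=False)
        artifacts["contours"] = str(contours_path)

        current = stage("landmarks")
        per_section = []
        for c in contours:
            overrides = config.landmark_overrides.get(str(c.section_index))
            per_section.append(
                lm.landmark_section(
                    c,
                    mode=config.landmark_mode,
                    window=config.curvature_window,
                    overrides=overrides,
                )
            )
        lm_rows = []
        for c, layers in zip(contours, per_section):
            for layer in sorted(layers):
                entry = layers[layer]
                marks = entry["landmarks"]
                if marks is None:
                    continue
                for f in dc_fields(marks):
                    if f.name in ("mode", "overridden"):
                        continue
                    value = getattr(marks, f.name)
                    if value is None:
                        continue
                    lm_rows.append(
                        {
                            "section_index": c.section_index,
                            "layer": layer,
                            "landmark": f.name,
                            "x": float(value[0]),
                            "y": float(value[1]),
                            "mode": marks.mode,
                            "overridden": f.name in marks.overridden,
                        }
                    )
        import pandas as pd

        lm_path = outdir / "landmarks.csv"
        pd.DataFrame(lm_rows).to_csv(lm_path, index=False)
        artifacts["landmarks"] = str(lm_path)
        if config.write_svg:
            svg_dir = outdir / "sections"
            svg_dir.mkdir(exist_ok=True)
            for c in contours:
                (svg_dir / f"section_{c.section_index:03d}.svg").write_text(
                    sectioning.section_svg(c)
                )
            artifacts["svg"] = str(svg_dir)

        current = stage("measure")
        sections_by_layer: dict = {}
        for c, layers in zip(contours, per_section):
            for layer in sorted(layers):
                entry = layers[layer]
                params = measures.measure_section(
                    entry["polyline"],
                    entry["landmarks"],
                    layer=layer,
                    section_index=c.section_index,
                    valid=entry["valid"],
                    reason=entry["reason"],
                )
                sections_by_layer.setdefault(layer, []).append(params)
        sections_path = outdir / "sections.csv"
        measures.sections_to_frame(sections_by_layer).to_csv(sections_path, index=False)
        artifacts["sections"] = str(sections_path)

        current = stage("report")
        report = measures.ToothReport()
        for layer, params in sorted(sections_by_layer.items()):
            try:
                report.layers[layer] = measures.aggregate(params, exclusion=config.exclusion)
            except measures.EmptyReportError:
                log.warning("layer %s has no valid sections; skipped", layer)
        ratios = {}
        if "enamel" in report.layers and "dentine" in report.layers:
            ratios = measures.compare_layers(report)
        report_path = outdir / "report.json"
        _dump_json({"report": report.as_dict(), "ratios": ratios}, report_path)
        artifacts["report"] = str(report_path)
    except AdoError as exc:
        raise AdoError(f"pipeline failed at stage {current!r}: {exc}") from exc

    return PipelineResult(
        frame=frame,
        border=border,
        contours=contours,
        sections_by_layer=sections_by_layer,
        report=report,
        ratios=ratios,
        artifacts=artifacts,
    )
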