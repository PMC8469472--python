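"""Per-section odontometric parameters, stack aggregation and layer ratios.

Conventions (all in the common tooth frame; horizontal = vestibulo-oral):

* tooth width — maximal horizontal extent of the layer's contour;
* occlusal width — horizontal-projection distance between the cusp tips;
* occlusal depth — perpendicular distance between the two parallel tangent
  lines (headline value); the vertical-drop variant is reported alongside;
* tip-line angle — inclination of the cusp-tip tangent line to the
  horizontal axis, degrees in [0, 90).

Averages are computed from unrounded per-section values over included
(valid, non-marginal) sections; layer comparisons are percentages
100 x dentine / enamel rounded to two decimals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .errors import EmptyReportError
from .landmarks import ContourLandmarks
from .sectioning import Polyline2D

PARAMETERS = (
    "tooth_vo_width",
    "occlusal_vo_width",
    "occlusal_depth",
    "occlusal_depth_vertical",
    "contour_length",
    "enclosed_area",
    "cusp_tip_line_angle",
    "cervical_shortest_vestibular",
    "cervical_shortest_oral",
)


def round2(value: float) -> float:
    """Two-decimal rounding, half away from zero (printed-table precision)."""
    return float(Decimal(repr(float(value))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class SectionParameters:
    section_index: int
    layer: str
    valid: bool = True
    reason: str = "ok"
    tooth_vo_width: float | None = None
    occlusal_vo_width: float | None = None
    occlusal_depth: float | None = None
    occlusal_depth_vertical: float | None = None
    contour_length: float | None = None
    enclosed_area: float | None = None
    cusp_tip_line_angle: float | None = None
    cervical_shortest_vestibular: float | None = None
    cervical_shortest_oral: float | None = None

    def as_dict(self) -> dict:
        return {name: getattr(self, name) for name in PARAMETERS}


def measure_section(
    polyline: Polyline2D | np.ndarray,
    landmarks: ContourLandmarks | None,
    layer: str = "enamel",
    section_index: int = 0,
    valid: bool = True,
    reason: str = "ok",
) -> SectionParameters:
    """Compute the per-section parameter set for one layer's contour.

    Landmark-dependent fields stay None when landmarks are missing; such
    sections are excluded downstream.
    """
    if isinstance(polyline, Polyline2D):
        pts, closed = polyline.points, polyline.closed
        length = polyline.length()
        area = polyline.area() if polyline.closed else None
    else:
        pts = np.asarray(polyline, float)
        closed = True
        p = Polyline2D(pts, closed=True)
        length, area = p.length(), p.area()

    out = SectionParameters(section_index=section_index, layer=layer, valid=valid, reason=reason)
    out.tooth_vo_width = float(pts[:, 0].max() - pts[:, 0].min())
    out.contour_length = float(length)
    out.enclosed_area = None if area is None else float(area)

    if landmarks is None:
        out.valid = False
        if reason == "ok":
            out.reason = "missing landmarks"
        return out

    vest, oral = landmarks.tips("dentine" if layer == "dentine" else "enamel")
    deepest = landmarks.deepest("dentine" if layer == "dentine" else "enamel")
    if layer == "dentine" and vest is None:
        # band-split sections store dentine landmarks in the primary slots
        vest, oral = landmarks.tips("enamel")
        deepest = landmarks.deepest("enamel")
    if vest is None or oral is None or deepest is None:
        out.valid = False
        if reason == "ok":
            out.reason = "missing landmarks"
        return out

    out.occlusal_vo_width = float(abs(vest[0] - oral[0]))
    seg = vest - oral
    norm = float(np.hypot(*seg))
    if norm > 0:
        out.occlusal_depth = float(
            abs(seg[0] * (oral[1] - deepest[1]) - seg[1] * (oral[0] - deepest[0])) / norm
        )
        slope = abs(seg[1] / seg[0]) if seg[0] != 0 else math.inf
        out.cusp_tip_line_angle = float(np.degrees(np.arctan(slope)))
        # vertical drop from the tip line evaluated at the deepest abscissa
        if seg[0] != 0:
            y_line = oral[1] + (deepest[0] - oral[0]) * seg[1] / seg[0]
            out.occlusal_depth_vertical = float(abs(y_line - deepest[1]))

    for side in ("vestibular", "oral"):
        conv = getattr(landmarks, f"max_convexity_{side}")
        edge = getattr(landmarks, f"cervical_enamel_edge_{side}")
        if conv is not None and edge is not None:
            setattr(out, f"cervical_shortest_{side}", float(np.linalg.norm(conv - edge)))
    return out


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class LayerReport:
    layer: str
    maxima: dict = field(default_factory=dict)          # parameter -> value
    argmax_section: dict = field(default_factory=dict)  # parameter -> 1-based index
    means: dict = field(default_factory=dict)           # parameter -> value
    included: list = field(default_factory=list)
    excluded: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "layer": self.layer,
            "maxima": self.maxima,
            "argmax_section": self.argmax_section,
            "means": self.means,
            "included": self.included,
            "excluded": self.excluded,
        }


@dataclass
class ToothReport:
    layers: dict = field(default_factory=dict)  # layer name -> LayerReport

    def as_dict(self) -> dict:
        return {name: rep.as_dict() for name, rep in sorted(self.layers.items())}


def aggregate(parameters: list[SectionParameters], exclusion: str = "invalid") -> LayerReport:
    """Aggregate one layer's section stack: per-parameter max with 1-based
    arg-max section index, and the arithmetic mean over included sections.

    ``exclusion='invalid'`` (default) excludes sections flagged invalid —
    which includes the degenerate marginal slices.  ``'trim'``
    additionally drops the first and last remaining section.  ``'none'``
    keeps everything that has values.
    """
    if exclusion not in ("invalid", "trim", "none"):
        raise ValueError(f"unknown exclusion rule {exclusion!r}")
    if not parameters:
        raise EmptyReportError("no sections to aggregate")
    layer = parameters[0].layer
    included = [p for p in parameters if p.valid or exclusion == "none"]
    if exclusion == "trim" and len(included) > 2:
        included = included[1:-1]
    excluded = [p.section_index for p in parameters if p not in included]
    if not included:
        raise EmptyReportError(f"no valid sections for layer {layer!r}")

    report = LayerReport(
        layer=layer,
        included=[p.section_index for p in included],
        excluded=excluded,
    )
    for name in PARAMETERS:
        values = [(getattr(p, name), p.section_index) for p in included if getattr(p, name) is not None]
        if not values:
            continue
        vmax, imax = max(values, key=lambda vi: (vi[0], -vi[1]))
        report.maxima[name] = float(vmax)
        report.argmax_section[name] = int(imax)
        report.means[name] = float(np.mean([v for v, _ in values]))
    return report


# ---------------------------------------------------------------------------
# layer comparison (ratio table)


def compare_layers(report: ToothReport) -> dict:
    """Dentine-as-percent-of-enamel ratios and per-layer vertical/horizontal
    ratios, rounded to two decimals.  Ratios whose enamel denominator is
    zero or missing are reported as None.
    """
    enamel = report.layers.get("enamel")
    dentine = report.layers.get("dentine")
    if enamel is None or dentine is None:
        raise EmptyReportError("both enamel and dentine layers are required")

    def pct(num, den):
        if num is None or den is None or den == 0:
            return None
        return round2(100.0 * num / den)

    def ratio(num, den):
        if num is None or den is None or den == 0:
            return None
        return round2(num / den)

    out = {
        "tooth_vo_max_dentine_pct": pct(
            dentine.maxima.get("tooth_vo_width"), enamel.maxima.get("tooth_vo_width")
        ),
        "occlusal_vo_max_dentine_pct": pct(
            dentine.maxima.get("occlusal_vo_width"), enamel.maxima.get("occlusal_vo_width")
        ),
        "occlusal_depth_max_dentine_pct": pct(
            dentine.maxima.get("occlusal_depth"), enamel.maxima.get("occlusal_depth")
        ),
        "tooth_vo_mean_dentine_pct": pct(
            dentine.means.get("tooth_vo_width"), enamel.means.get("tooth_vo_width")
        ),
        "occlusal_vo_mean_dentine_pct": pct(
            dentine.means.get("occlusal_vo_width"), enamel.means.get("occlusal_vo_width")
        ),
        "occlusal_depth_mean_dentine_pct": pct(
            dentine.means.get("occlusal_depth"), enamel.means.get("occlusal_depth")
        ),
        "depth_width_mean_ratio_enamel": ratio(
            enamel.means.get("occlusal_depth"), enamel.means.get("occlusal_vo_width")
        ),
        "depth_width_mean_ratio_dentine": ratio(
            dentine.means.get("occlusal_depth"), dentine.means.get("occlusal_vo_width")
        ),
    }
    return out


def sections_to_frame(sections_by_layer: dict) -> "pd.DataFrame":
    """Long-format per-section table mirroring the per-tooth report rows."""
    import pandas as pd

    rows = []
    for layer in sorted(sections_by_layer):
        for p in sections_by_layer[layer]:
            row = {"section_index": p.section_index, "layer": layer, "valid": p.valid, "reason": p.reason}
            row.update(p.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
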