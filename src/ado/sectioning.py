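"""Ellipse approximation of the occlusal border and transverse sectioning.

Cutting planes are perpendicular to the mesio-distal axis, equally spaced
over the crown's full projected extent with interior placement: plane k of
Ns sits at span_min + k * span / (Ns + 1), so the extreme planes always
intersect the crown.

Section contours are expressed in the common tooth frame: horizontal
coordinate along the vestibulo-oral axis, vertical along the vertical
axis, so every section of a tooth shares axes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon

from .errors import EllipseFitError
from .mesh_io import TriangulatedSurface

__all__ = [
    "FittedEllipse",
    "SectionSet",
    "Polyline2D",
    "SectionContour",
    "fit_ellipse",
    "generate_planes",
    "cut_surface",
]


# ---------------------------------------------------------------------------
# ellipse fitting


@dataclass(frozen=True)
class FittedEllipse:
    center: np.ndarray              # (2,)
    semi_major: float
    semi_minor: float
    major_axis_direction: np.ndarray  # unit 2-vector

    def __post_init__(self):
        if not (self.semi_major >= self.semi_minor > 0):
            raise EllipseFitError("requires semi_major >= semi_minor > 0")


def fit_ellipse(points: np.ndarray) -> FittedEllipse:
    """Direct least-squares ellipse fit (Halir & Flusser stabilisation of
    Fitzgibbon's method); the conic is constrained to be an ellipse.

    Near-circular fits break the direction tie toward (1, 0).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 5:
        raise EllipseFitError("need at least 5 two-dimensional points")
    mean = pts.mean(axis=0)
    x, y = (pts - mean).T
    scale = max(float(np.abs(np.column_stack([x, y])).max()), 1e-12)
    x, y = x / scale, y / scale
    if np.linalg.matrix_rank(np.column_stack([x, y, np.ones_like(x)])) < 3:
        raise EllipseFitError("points are collinear")

    d1 = np.column_stack([x * x, x * y, y * y])
    d2 = np.column_stack([x, y, np.ones_like(x)])
    s1 = d1.T @ d1
    s2 = d1.T @ d2
    s3 = d2.T @ d2
    try:
        t = -np.linalg.solve(s3, s2.T)
    except np.linalg.LinAlgError as exc:
        raise EllipseFitError("degenerate point configuration") from exc
    m = s1 + s2 @ t
    m = np.array([m[2] / 2.0, -m[1], m[0] / 2.0])
    eigval, eigvec = np.linalg.eig(np.vstack(m))
    cond = 4.0 * eigvec[0] * eigvec[2] - eigvec[1] ** 2
    ok = np.flatnonzero(cond > 0)
    if len(ok) == 0:
        raise EllipseFitError("no elliptical solution")
    a1 = eigvec[:, ok[np.argmax(eigval[ok].real)]].real
    conic = np.concatenate([a1, t @ a1])  # A x^2 + B xy + C y^2 + D x + E y + F

    A, B, C, D, E, F = conic
    den = B * B - 4 * A * C
    if den >= 0:
        raise EllipseFitError("fit is not an ellipse")
    cx = (2 * C * D - B * E) / den
    cy = (2 * A * E - B * D) / den
    # eigen-decomposition of the quadratic part for axes
    mq = np.array([[A, B / 2.0], [B / 2.0, C]])
    evals, evecs = np.linalg.eigh(mq)
    f0 = A * cx * cx + B * cx * cy + C * cy * cy + D * cx + E * cy + F
    axes2 = -f0 / evals
    if np.any(axes2 <= 0):
        raise EllipseFitError("fit is not an ellipse")
    axes = np.sqrt(axes2)
    order = np.argsort(axes)[::-1]
    semi_major, semi_minor = axes[order] * scale
    direction = evecs[:, order[0]]
    if semi_major - semi_minor < 1e-9 * semi_major:
        direction = np.array([1.0, 0.0])
    elif direction[0] < 0 or (direction[0] == 0 and direction[1] < 0):
        direction = -direction
    center = mean + np.array([cx, cy]) * scale
    return FittedEllipse(center, float(semi_major), float(semi_minor), direction)


# ---------------------------------------------------------------------------
# cutting planes


@dataclass(frozen=True)
class SectionSet:
    ns: int
    plane_positions: np.ndarray   # offsets along the mesio-distal axis, mm
    plane_normal: np.ndarray      # unit vector (= mesiodistal axis)
    spacing: float

    def __post_init__(self):
        pos = np.asarray(self.plane_positions, float)
        if self.ns < 1 or len(pos) != self.ns:
            raise ValueError("need ns >= 1 positions")
        if np.any(np.diff(pos) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(np.abs(np.diff(pos) - self.spacing) > 1e-9):
            raise ValueError("positions must be equally spaced")


def generate_planes(frame, ellipse: FittedEllipse | None, surface: TriangulatedSurface, ns: int) -> SectionSet:
    """Ns planes perpendicular to the mesio-distal axis, equally spaced over
    the crown's projected extent (interior placement, spacing span/(Ns+1)).
    """
    if ns < 1:
        raise ValueError("ns must be >= 1")
    md = np.asarray(frame.mesiodistal_axis, float)
    proj = (surface.vertices - frame.origin) @ md
    lo, hi = float(proj.min()), float(proj.max())
    span = hi - lo
    if span <= 0:
        raise ValueError("degenerate surface extent")
    spacing = span / (ns + 1)
    positions = lo + spacing * np.arange(1, ns + 1)
    return SectionSet(ns=int(ns), plane_positions=positions, plane_normal=md, spacing=spacing)


# ---------------------------------------------------------------------------
# contours


@dataclass
class Polyline2D:
    points: np.ndarray          # (N, 2): horizontal = vestibulo-oral, vertical = vertical axis
    closed: bool
    layer: str = "unknown"      # outer (enamel) / inner (dentine) / unknown

    def length(self) -> float:
        p = self.points
        seg = np.linalg.norm(np.diff(p, axis=0), axis=1).sum()
        if self.closed:
            seg += float(np.linalg.norm(p[0] - p[-1]))
        return float(seg)

    def area(self) -> float:
        """Shoelace area of a closed polyline (0 for open chains)."""
        if not self.closed:
            return 0.0
        x, y = self.points.T
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def is_simple(self) -> bool:
        p = self.points
        geom = LineString(np.vstack([p, p[:1]]) if self.closed else p)
        return bool(geom.is_simple)


@dataclass
class SectionContour:
    section_index: int          # 1-based, mesial -> distal
    position: float             # offset along the mesio-distal axis
    polylines: list             # list[Polyline2D]


def _chain_segments(segments: list[tuple]) -> list[tuple[list, bool]]:
    """Chain (key_a, key_b) segments into paths; returns (key list, closed)."""
    adj: dict = {}
    for a, b in segments:
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)
    used = set()
    paths = []

    def walk(start, first):
        path = [start, first]
        used.add(frozenset((start, first)))
        prev, cur = start, first
        while True:
            nxt = None
            for cand in adj[cur]:
                if frozenset((cur, cand)) not in used:
                    nxt = cand
                    break
            if nxt is None:
                return path, False
            used.add(frozenset((cur, nxt)))
            if nxt == path[0]:
                return path, True
            path.append(nxt)
            prev, cur = cur, nxt

    ends = sorted((k for k, v in adj.items() if len(v) == 1))
    for e in ends:  # open chains first
        nbrs = [c for c in adj[e] if frozenset((e, c)) not in used]
        if nbrs:
            paths.append(walk(e, nbrs[0]))
    for a, b in segments:  # remaining cycles
        if frozenset((a, b)) in used:
            continue
        paths.append(walk(a, b))
    return paths


def _dedupe(points: np.ndarray, closed: bool) -> np.ndarray:
    keep = [0]
    for i in range(1, len(points)):
        if np.linalg.norm(points[i] - points[keep[-1]]) > 1e-9:
            keep.append(i)
    pts = points[keep]
    if closed and len(pts) > 1 and np.linalg.norm(pts[0] - pts[-1]) <= 1e-9:
        pts = pts[:-1]
    return pts


def _assign_layers(polylines: list[Polyline2D]) -> None:
    """Tag nested closed polylines by even-odd containment depth."""
    closed = [p for p in polylines if p.closed and len(p.points) >= 3]
    polys = []
    for p in closed:
        try:
            polys.append(Polygon(p.points))
        except Exception:
            polys.append(None)
    for i, p in enumerate(closed):
        if polys[i] is None:
            continue
        depth = 0
        probe = Point(p.points[0])
        for j, q in enumerate(closed):
            if i == j or polys[j] is None or not polys[j].is_valid:
                continue
            if polys[j].contains(probe):
                depth += 1
        p.layer = "outer" if depth % 2 == 0 else "inner"


def cut_surface(surface: TriangulatedSurface, sections: SectionSet, frame) -> list[SectionContour]:
    """Intersect every cutting plane with the mesh.

    Watertight meshes yield closed polylines only; open chains from
    non-watertight regions are kept but flagged open (excluded from area
    computation downstream).  Deterministic: no randomness, stable
    ordering.
    """
    v = surface.vertices
    origin = np.asarray(frame.origin, float)
    md = np.asarray(sections.plane_normal, float)
    vo = np.asarray(frame.vestibulooral_axis, float)
    up = np.asarray(frame.vertical_axis, float)
    proj = (v - origin) @ md
    faces = surface.faces

    out = []
    for k, pos in enumerate(sections.plane_positions):
        d = proj - pos
        d = np.where(d == 0.0, 1e-12, d)  # nudge on-plane vertices
        sides = d[faces] > 0
        crossing = np.flatnonzero(sides.any(axis=1) & ~sides.all(axis=1))
        segments = []
        pt_for_key: dict = {}
        for fi in crossing:
            tri = faces[fi]
            keys = []
            for a, b in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0])):
                if (d[a] > 0) == (d[b] > 0):
                    continue
                key = (int(min(a, b)), int(max(a, b)))
                if key not in pt_for_key:
                    t = d[a] / (d[a] - d[b])
                    pt_for_key[key] = v[a] + t * (v[b] - v[a])
                keys.append(key)
            if len(keys) == 2:
                segments.append((keys[0], keys[1]))
        polylines = []
        if segments:
            for keys, closed in _chain_segments(segments):
                pts3 = np.asarray([pt_for_key[key] for key in keys])
                rel = pts3 - origin
                pts2 = np.column_stack([rel @ vo, rel @ up])
                pts2 = _dedupe(pts2, closed)
                if len(pts2) >= (3 if closed else 2):
                    polylines.append(Polyline2D(pts2, closed=closed))
            _assign_layers(polylines)
        out.append(SectionContour(section_index=k + 1, position=float(pos), polylines=polylines))
    return out


def contours_to_frame(contours: list[SectionContour]) -> "pd.DataFrame":
    """Long-format table (section_index, polyline, layer, closed, x, y)."""
    import pandas as pd

    rows = []
    for c in contours:
        for pi, p in enumerate(c.polylines):
            for x, y in p.points:
                rows.append((c.section_index, pi, p.layer, p.closed, x, y))
    return pd.DataFrame(rows, columns=["section_index", "polyline", "layer", "closed", "x", "y"])


def section_svg(contour: SectionContour, scale: float = 20.0) -> str:
    """Minimal SVG rendering of one section for visual QC."""
    pts = np.vstack([p.points for p in contour.polylines]) if contour.polylines else np.zeros((1, 2))
    lo = pts.min(axis=0) - 1.0
    hi = pts.max(axis=0) + 1.0
    w, h = (hi - lo) * scale
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{w:.0f}" height="{h:.0f}" '
        f'viewBox="0 0 {w:.2f} {h:.2f}">'
    ]
    colors = {"outer": "#1f77b4", "inner": "#d62728", "unknown": "#7f7f7f"}
    for p in contour.polylines:
        xy = (p.points - lo) * scale
        xy[:, 1] = h - xy[:, 1]  # SVG y runs down
        d = "M " + " L ".join(f"{x:.2f} {y:.2f}" for x, y in xy) + (" Z" if p.closed else "")
        parts.append(f'<path d="{d}" fill="none" stroke="{colors[p.layer]}" stroke-width="1"/>')
    parts.append("</svg>")
    return "\n".join(parts)
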