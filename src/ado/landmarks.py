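"""Morphological landmarks on 2D transverse section contours.

Two detection modes:

* Euclidean — the parallel-tangent construction: the upper convex hull
  edge bridging the deepest occlusal concavity defines the two cusp tips
  and the tangent line; the deepest occlusal point is the contour point
  of maximal perpendicular distance below that line within the bridged
  arc, and the second (parallel) line passes through it.
* Curvature — arc-length resampling and smoothing; cusp tips are the two
  most prominent convex curvature peaks on the upper side, the deepest
  point the extremal concave point between them.

Enamel-cap band contours are split at the two cervical enamel edges (the
sharpest turning points of the lower half) into an enamel (upper/outer)
and a dentine (lower/inner) sector that share those two edge points.
"""

from __future__ import annotations

from dataclasses import dataclass, fields as dc_fields

import numpy as np
from scipy.signal import find_peaks

from .errors import LandmarkError, SplitError
from .sectioning import Polyline2D, SectionContour

_MIN_DEPTH = 0.05  # mm of occlusal concavity required for a two-cusp contour


@dataclass
class ContourLandmarks:
    """Up to twelve landmarks on a (possibly two-layer) section contour.

    2D coordinates in the common section frame (horizontal = vestibulo-
    oral, vertical = vertical axis).  The vestibular side is the positive
    horizontal half-plane by convention.
    """

    vestibular_cusp_tip: np.ndarray | None = None
    oral_cusp_tip: np.ndarray | None = None
    deepest_occlusal_point: np.ndarray | None = None
    max_convexity_vestibular: np.ndarray | None = None
    max_convexity_oral: np.ndarray | None = None
    cervical_enamel_edge_vestibular: np.ndarray | None = None
    cervical_enamel_edge_oral: np.ndarray | None = None
    dentine_vestibular_cusp_tip: np.ndarray | None = None
    dentine_oral_cusp_tip: np.ndarray | None = None
    dentine_deepest_occlusal_point: np.ndarray | None = None
    dentine_max_convexity_vestibular: np.ndarray | None = None
    dentine_max_convexity_oral: np.ndarray | None = None
    mode: str = "euclidean"
    overridden: tuple = ()

    def count(self) -> int:
        n = 0
        for f in dc_fields(self):
            if f.name in ("mode", "overridden"):
                continue
            if getattr(self, f.name) is not None:
                n += 1
        return n

    def tips(self, layer: str = "enamel"):
        if layer == "dentine":
            return self.dentine_vestibular_cusp_tip, self.dentine_oral_cusp_tip
        return self.vestibular_cusp_tip, self.oral_cusp_tip

    def deepest(self, layer: str = "enamel"):
        return self.dentine_deepest_occlusal_point if layer == "dentine" else self.deepest_occlusal_point

    def apply_overrides(self, overrides: dict) -> None:
        """Replace landmark coordinates from a {name: (x, y)} mapping."""
        changed = list(self.overridden)
        for name, xy in overrides.items():
            if not any(f.name == name for f in dc_fields(self)) or name in ("mode", "overridden"):
                raise LandmarkError(f"unknown landmark {name!r}")
            setattr(self, name, np.asarray(xy, dtype=float))
            changed.append(name)
        self.overridden = tuple(changed)


# ---------------------------------------------------------------------------
# Euclidean (parallel-tangent) mode


def _upper_hull(points: np.ndarray) -> np.ndarray:
    """Indices of the upper convex hull, left to right (monotone chain)."""
    order = np.lexsort((points[:, 1], points[:, 0]))
    hull: list[int] = []
    for i in order:
        while len(hull) >= 2:
            o, a = points[hull[-2]], points[hull[-1]]
            if (a[0] - o[0]) * (points[i][1] - o[1]) - (a[1] - o[1]) * (points[i][0] - o[0]) >= 0:
                hull.pop()
            else:
                break
        hull.append(int(i))
    return np.asarray(hull)


def _subtended_arc(points: np.ndarray, i: int, j: int, closed: bool) -> np.ndarray | None:
    """Indices of the occlusal contour path between vertices i and j.

    The occlusal arc stays inside the tips' horizontal range; when no
    path does, there is no subtended arc (returns None).  When both paths
    of a closed contour qualify the shorter one is the valley.
    """
    n = len(points)
    lo, hi = sorted((i, j))
    inner = np.arange(lo + 1, hi)
    candidates = [inner]
    if closed:
        candidates.append(np.concatenate([np.arange(hi + 1, n), np.arange(0, lo)]))
    x_lo, x_hi = sorted((points[i, 0], points[j, 0]))
    tol = 1e-9 * max(1.0, x_hi - x_lo)
    valid = [
        idx
        for idx in candidates
        if len(idx) > 0
        and np.all((points[idx, 0] >= x_lo - tol) & (points[idx, 0] <= x_hi + tol))
    ]
    if not valid:
        return None
    return min(valid, key=len)


def _bridge(points: np.ndarray, min_depth: float, closed: bool = True):
    """Best upper-hull bridge: returns (tip_left, tip_right, deepest, depth).

    The bridge is the hull edge whose subtended contour arc has maximal
    perpendicular depth below it.
    """
    hull = _upper_hull(points)
    best = None
    for a_i, b_i in zip(hull[:-1], hull[1:]):
        a, b = points[a_i], points[b_i]
        seg = b - a
        norm = np.hypot(*seg)
        if norm < 1e-12:
            continue
        between = _subtended_arc(points, int(a_i), int(b_i), closed)
        if between is None or len(between) == 0:
            continue
        mid = points[between]
        depth = (seg[0] * (a[1] - mid[:, 1]) - seg[1] * (a[0] - mid[:, 0])) / norm
        i_max = int(depth.argmax())
        if best is None or depth[i_max] > best[3]:
            best = (int(a_i), int(b_i), int(between[i_max]), float(depth[i_max]))
    if best is None or best[3] < min_depth:
        raise LandmarkError("no occlusal concavity on the upper side of the contour")
    return best


def _lateral_extremes(points: np.ndarray):
    right = points[np.lexsort((points[:, 1], -points[:, 0]))[0]]
    left = points[np.lexsort((points[:, 1], points[:, 0]))[0]]
    return right.copy(), left.copy()


def find_landmarks_euclidean(
    polyline: np.ndarray | Polyline2D,
    min_depth: float = _MIN_DEPTH,
    closed: bool | None = None,
) -> ContourLandmarks:
    """Parallel-tangent landmarks on a single contour (closed or open arc)."""
    if isinstance(polyline, Polyline2D):
        pts = polyline.points
        if closed is None:
            closed = polyline.closed
    else:
        pts = np.asarray(polyline, float)
        closed = True if closed is None else bool(closed)
    if len(pts) < 4:
        raise LandmarkError("contour too short")
    a_i, b_i, d_i, depth = _bridge(pts, min_depth, closed=closed)
    tip_a, tip_b = pts[a_i], pts[b_i]
    # vestibular = positive horizontal side
    if tip_a[0] >= tip_b[0]:
        vest, oral = tip_a, tip_b
    else:
        vest, oral = tip_b, tip_a
    conv_v, conv_o = _lateral_extremes(pts)
    return ContourLandmarks(
        vestibular_cusp_tip=vest.copy(),
        oral_cusp_tip=oral.copy(),
        deepest_occlusal_point=pts[d_i].copy(),
        max_convexity_vestibular=conv_v,
        max_convexity_oral=conv_o,
        mode="euclidean",
    )


# ---------------------------------------------------------------------------
# curvature mode


def _resample(points: np.ndarray, step: float, closed: bool) -> np.ndarray:
    p = np.vstack([points, points[:1]]) if closed else points
    seg = np.linalg.norm(np.diff(p, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < step * 4:
        raise LandmarkError("contour too short for curvature analysis")
    n = max(int(round(total / step)), 8)
    si = np.linspace(0.0, total, n, endpoint=not closed)
    x = np.interp(si, s, p[:, 0])
    y = np.interp(si, s, p[:, 1])
    return np.column_stack([x, y])


def _signed_curvature(p: np.ndarray, closed: bool, smooth: int) -> np.ndarray:
    if smooth > 1:
        kernel = np.ones(smooth) / smooth
        if closed:
            pad = smooth // 2
            ext = np.vstack([p[-pad:], p, p[:pad]])
            p = np.column_stack(
                [np.convolve(ext[:, k], kernel, mode="same")[pad:-pad] for k in range(2)]
            )
        else:
            p = np.column_stack([np.convolve(p[:, k], kernel, mode="same") for k in range(2)])
    if closed:
        d1 = (np.roll(p, -1, axis=0) - np.roll(p, 1, axis=0)) / 2.0
        d2 = np.roll(p, -1, axis=0) - 2 * p + np.roll(p, 1, axis=0)
    else:
        d1 = np.gradient(p, axis=0)
        d2 = np.gradient(d1, axis=0)
    num = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    den = (d1[:, 0] ** 2 + d1[:, 1] ** 2) ** 1.5
    den[den == 0] = np.inf
    return num / den


def _is_ccw(points: np.ndarray) -> bool:
    x, y = points.T
    return (np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) > 0


def find_landmarks_curvature(
    polyline: np.ndarray | Polyline2D,
    window: float = 0.5,
    closed: bool | None = None,
    min_depth: float = _MIN_DEPTH,
) -> ContourLandmarks:
    """Curvature-analysis landmarks: resample at window/10, smooth over the
    window, take the two most prominent convex peaks on the upper side as
    cusp tips and the extremal concave point between them as the deepest
    occlusal point.
    """
    if isinstance(polyline, Polyline2D):
        pts = polyline.points
        if closed is None:
            closed = polyline.closed
    else:
        pts = np.asarray(polyline, float)
        closed = bool(closed) if closed is not None else True
    step = window / 10.0
    rs = _resample(pts, step, closed)
    # orientation fixes the curvature sign: convex-up bumps must be positive
    if closed:
        if not _is_ccw(rs):
            rs = rs[::-1]
    elif rs[0, 0] < rs[-1, 0]:  # open arcs: traverse right-to-left (CCW-at-top)
        rs = rs[::-1]
    kappa = _signed_curvature(rs, closed, smooth=max(3, int(round(window / step))))

    signal = kappa.copy()
    if not closed:
        # endpoint curvature estimates (and sharp cervical tips) are unreliable
        guard = max(3, int(round(window / step)))
        signal[:guard] = -np.inf
        signal[-guard:] = -np.inf
    if closed:
        ext = np.concatenate([signal, signal[: len(signal) // 4]])
    else:
        ext = signal
    peaks, _ = find_peaks(ext, prominence=1e-6)
    peaks = np.unique(peaks % len(signal))
    peaks = peaks[np.isfinite(signal[peaks]) & (kappa[peaks] > 0)]
    if len(peaks) < 2:
        raise LandmarkError("fewer than two convex curvature peaks")

    # cusp tips: the strongest convex peak pair whose chord has nothing
    # poking above it and a genuine concavity below (parallel-tangent rule;
    # sharp non-cusp corners fail the chord test)
    top = peaks[np.argsort(-kappa[peaks])][:6]
    above_tol = max(2.0 * step, 0.1 * window)
    best = None
    for a_rank in range(len(top)):
        for b_rank in range(a_rank + 1, len(top)):
            i, j = sorted((int(top[a_rank]), int(top[b_rank])), key=lambda k: rs[k, 0])
            a, b = rs[i], rs[j]
            seg = b - a
            norm = np.hypot(*seg)
            if abs(seg[0]) < 4 * step or norm < 1e-12:
                continue
            arc = _subtended_arc(rs, i, j, closed)
            if arc is None or len(arc) == 0:
                continue
            # upper-tangent test over the whole contour: nothing with an
            # abscissa between the tips may poke above the chord
            x_lo2, x_hi2 = sorted((a[0], b[0]))
            span = np.flatnonzero((rs[:, 0] > x_lo2) & (rs[:, 0] < x_hi2))
            off_span = (
                seg[0] * (a[1] - rs[span, 1]) - seg[1] * (a[0] - rs[span, 0])
            ) / norm
            if len(span) and off_span.min() < -above_tol:
                continue
            mid = rs[arc]
            off = (seg[0] * (a[1] - mid[:, 1]) - seg[1] * (a[0] - mid[:, 0])) / norm
            depth = float(off.max())
            if depth < min_depth:
                continue
            score = kappa[i] + kappa[j]
            if best is None or score > best[0]:
                best = (score, i, j, int(arc[int(off.argmax())]))
    if best is None:
        raise LandmarkError("no occlusal concavity between curvature peaks")
    _, tip_i, tip_j, deepest = best

    tip_a, tip_b = rs[tip_i], rs[tip_j]
    vest, oral = (tip_a, tip_b) if tip_a[0] >= tip_b[0] else (tip_b, tip_a)
    conv_v, conv_o = _lateral_extremes(pts)
    return ContourLandmarks(
        vestibular_cusp_tip=vest.copy(),
        oral_cusp_tip=oral.copy(),
        deepest_occlusal_point=rs[deepest].copy(),
        max_convexity_vestibular=conv_v,
        max_convexity_oral=conv_o,
        mode="curvature",
    )


# ---------------------------------------------------------------------------
# enamel-cap band split


def _turning_angles(points: np.ndarray, k: int) -> np.ndarray:
    """|exterior turning angle| at each vertex of a closed polyline, using
    neighbours k steps away to resist discretisation noise."""
    prev = np.roll(points, k, axis=0)
    nxt = np.roll(points, -k, axis=0)
    v1 = points - prev
    v2 = nxt - points
    a1 = np.arctan2(v1[:, 1], v1[:, 0])
    a2 = np.arctan2(v2[:, 1], v2[:, 0])
    turn = np.angle(np.exp(1j * (a2 - a1)))
    return np.abs(turn)


def split_enamel_cap_contour(
    section: SectionContour | Polyline2D,
) -> tuple[Polyline2D, Polyline2D, np.ndarray]:
    """Split a closed enamel-cap band contour at the two cervical enamel
    edges into enamel (upper/outer) and dentine (lower/inner) open arcs.

    The edges are the two sharpest turning points in the lower half of the
    band; they are shared by both output arcs.  Returns (enamel sector,
    dentine sector, edge points (2, 2): vestibular then oral).
    """
    if isinstance(section, SectionContour):
        closed = [p for p in section.polylines if p.closed]
        if len(closed) != 1:
            raise SplitError(
                f"expected one closed band polyline, found {len(closed)}"
            )
        band = closed[0]
    else:
        band = section
        if not band.closed:
            raise SplitError("band contour must be closed")
    pts = band.points
    n = len(pts)
    if n < 8:
        raise SplitError("band contour too short")

    k = max(1, min(n // 20, 5))
    turn = _turning_angles(pts, k)
    y_mid = 0.5 * (pts[:, 1].min() + pts[:, 1].max())
    lower = np.flatnonzero(pts[:, 1] < y_mid)
    if len(lower) < 2:
        raise SplitError("band has no lower half")

    order = lower[np.argsort(-turn[lower])]
    first = int(order[0])
    min_sep = max(3, n // 10)
    second = None
    for cand in order[1:]:
        sep = min((cand - first) % n, (first - cand) % n)
        if sep >= min_sep:
            second = int(cand)
            break
    if second is None or turn[second] < 0.35:  # ~20 degrees: not a sharp cervical tip
        raise SplitError("could not find two acute cervical turning points")

    def snap(idx):
        # the k-step turning angle peaks within k of the true corner; snap to
        # the lowest-reaching, most lateral vertex in that window
        window = [(idx + o) % n for o in range(-k, k + 1)]
        return min(window, key=lambda i: (pts[i, 1], -abs(pts[i, 0]), i))

    first, second = snap(first), snap(second)
    if first == second:
        raise SplitError("cervical turning points collapse onto one vertex")

    i, j = sorted((first, second))
    arc1 = pts[i : j + 1]
    arc2 = np.vstack([pts[j:], pts[: i + 1]])
    # the enamel sector is the one reaching higher
    if arc1[:, 1].max() >= arc2[:, 1].max():
        enamel_pts, dentine_pts = arc1, arc2
    else:
        enamel_pts, dentine_pts = arc2, arc1
    enamel = Polyline2D(enamel_pts.copy(), closed=False, layer="outer")
    dentine = Polyline2D(dentine_pts.copy(), closed=False, layer="inner")
    edges = pts[[i, j]]
    if edges[0, 0] < edges[1, 0]:  # vestibular (positive horizontal) first
        edges = edges[::-1]
    return enamel, dentine, edges.copy()


# ---------------------------------------------------------------------------
# validation and orchestration


def validate_contour(
    section: SectionContour,
    landmarks_result,
    min_height: float = 0.2,
    min_width: float = 0.5,
) -> tuple[bool, str]:
    """Contour selection rule: a section is invalid when landmarking failed,
    the polyline is open, the two-cusp structure is absent, or the contour
    is below the minimal height/width.
    """
    if isinstance(landmarks_result, Exception):
        if isinstance(landmarks_result, SplitError):
            return False, f"band split failed: {landmarks_result}"
        return False, "no occlusal concavity"
    polys = section.polylines if isinstance(section, SectionContour) else [section]
    if not polys:
        return False, "empty section"
    if any(not p.closed for p in polys):
        return False, "open contour"
    pts = np.vstack([p.points for p in polys])
    w = pts[:, 0].max() - pts[:, 0].min()
    h = pts[:, 1].max() - pts[:, 1].min()
    if h < min_height or w < min_width:
        return False, "contour below minimal size"
    if landmarks_result is None or landmarks_result.vestibular_cusp_tip is None:
        return False, "no occlusal concavity"
    return True, "ok"


def landmark_section(
    section: SectionContour,
    mode: str = "euclidean",
    window: float = 0.5,
    min_depth: float = _MIN_DEPTH,
    overrides: dict | None = None,
) -> dict:
    """Detect landmarks on one section for every layer present.

    Returns ``{layer: {"polyline": Polyline2D, "landmarks": ContourLandmarks
    | None, "valid": bool, "reason": str}}``.  Handles three topologies:
    a single closed band (enamel cap: split at the cervical edges), nested
    closed polylines tagged outer/inner, and a lone solid contour.
    """

    def detect(pts, closed):
        if mode == "curvature":
            return find_landmarks_curvature(pts, window=window, closed=closed, min_depth=min_depth)
        return find_landmarks_euclidean(pts, min_depth=min_depth, closed=closed)

    out: dict = {}
    closed_polys = [p for p in section.polylines if p.closed]
    open_polys = [p for p in section.polylines if not p.closed]

    band_layers = None
    if len(closed_polys) == 1 and not open_polys:
        try:
            enamel_arc, dentine_arc, edges = split_enamel_cap_contour(closed_polys[0])
            band_layers = {"enamel": (enamel_arc, edges), "dentine": (dentine_arc, edges)}
        except SplitError:
            band_layers = None

    if band_layers is not None:
        for layer, (arc, edges) in band_layers.items():
            try:
                lm = detect(arc.points, closed=False)
                lm.cervical_enamel_edge_vestibular = edges[0].copy()
                lm.cervical_enamel_edge_oral = edges[1].copy()
                valid, reason = validate_contour(section, lm)
            except LandmarkError as exc:
                lm, (valid, reason) = None, validate_contour(section, exc)
            out[layer] = {"polyline": arc, "landmarks": lm, "valid": valid, "reason": reason}
    else:
        layer_of = {"outer": "enamel", "inner": "dentine", "unknown": "enamel"}
        for p in section.polylines:
            layer = layer_of[p.layer]
            if layer in out:  # keep the largest polyline per layer
                if p.length() <= out[layer]["polyline"].length():
                    continue
            try:
                lm = detect(p.points, closed=p.closed)
                valid, reason = validate_contour(section, lm)
                if not p.closed:
                    valid, reason = False, "open contour"
            except LandmarkError as exc:
                lm, (valid, reason) = None, validate_contour(section, exc)
            out[layer] = {"polyline": p, "landmarks": lm, "valid": valid, "reason": reason}

    if overrides:
        for layer, entry in out.items():
            if entry["landmarks"] is not None and layer in overrides:
                entry["landmarks"].apply_overrides(overrides[layer])
    return out
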