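"""Occlusal border detection and tooth coordinate-frame determination.

The border is the closed high-Gaussian-curvature loop encircling the
central occlusal depression.  The vertical axis is the mean of the border
normals; the mesio-distal axis comes from the major axis of the ellipse
fitted to the projected border, calibrated against the crown's maximal
in-plane extent; the vestibulo-oral axis completes a right-handed frame.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import AmbiguousBorderError, DegenerateFrameError, EllipseFitError, NoOcclusalSurfaceError
from .mesh_io import TriangulatedSurface
from .sectioning import fit_ellipse
from .surface_analysis import CurvatureField, curvature_percentile_mask

log = logging.getLogger(__name__)

_MIN_DEPRESSION = 5         # vertices a concave fossa region must have
_MIN_CONCAVITY = 1e-3       # 1/mm: flat-surface noise must not count as a fossa
_NORMAL_GATE = 0.2          # border normals must roughly face the occlusal side


@dataclass
class OcclusalBorder:
    points: np.ndarray          # (K, 3) ordered closed loop, mm
    vertex_indices: np.ndarray  # (K,) indices into the surface
    normals: np.ndarray         # (K, 3) per-point unit normals
    inside_indices: np.ndarray  # vertices of the enclosed occlusal region
    band_indices: np.ndarray | None = None  # full maximal-K point set (Ob)
    band_normals: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.points)

    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


@dataclass
class ToothFrame:
    origin: np.ndarray             # border centroid, mm
    vertical_axis: np.ndarray      # unit nT, toward the occlusal side
    mesiodistal_axis: np.ndarray   # unit
    vestibulooral_axis: np.ndarray # unit, = vertical x mesiodistal
    iterations_used: int = 1
    converged: bool = True
    calibrated: bool = False       # True when the maximal-extent fallback fired

    def __post_init__(self):
        axes = np.vstack([self.mesiodistal_axis, self.vestibulooral_axis, self.vertical_axis])
        gram = axes @ axes.T - np.eye(3)
        if np.abs(gram).max() > 1e-9:
            raise DegenerateFrameError("axes are not orthonormal")
        if np.linalg.det(axes) < 0:
            raise DegenerateFrameError("frame is not right-handed")

    def to_matrix(self) -> np.ndarray:
        """4x4 rigid transform mapping frame coordinates to world."""
        m = np.eye(4)
        m[:3, 0] = self.mesiodistal_axis
        m[:3, 1] = self.vestibulooral_axis
        m[:3, 2] = self.vertical_axis
        m[:3, 3] = self.origin
        return m


# ---------------------------------------------------------------------------
# helpers


def _vertex_adjacency(surface: TriangulatedSurface):
    e = surface.edges()
    n = surface.n_vertices
    adj = coo_matrix(
        (np.ones(2 * len(e)), (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])),
        shape=(n, n),
    ).tocsr()
    return e, adj


def _components_of(mask: np.ndarray, e: np.ndarray, n: int):
    inmask = np.zeros(n, dtype=bool)
    inmask[mask] = True
    em = e[inmask[e[:, 0]] & inmask[e[:, 1]]]
    remap = -np.ones(n, dtype=np.int64)
    remap[mask] = np.arange(len(mask))
    g = coo_matrix(
        (np.ones(len(em)), (remap[em[:, 0]], remap[em[:, 1]])),
        shape=(len(mask), len(mask)),
    )
    ncomp, labels = connected_components(g, directed=False)
    return [mask[labels == c] for c in range(ncomp)]


def _quantized_gaussian(field: CurvatureField) -> np.ndarray:
    gauss = field.gaussian
    scale = float(np.max(np.abs(gauss)))
    if scale == 0:
        return gauss
    return np.round(gauss / (scale * 1e-6)) * (scale * 1e-6)


# ---------------------------------------------------------------------------
# border detection


def _find_depressions(surface, field, allowed_mask):
    """Connected bowl-like concave regions (kappa1, kappa2 < 0) ordered by
    curvature mass; the occlusal fossa is among the top candidates.

    Raises when none exists (e.g. a sphere).  Exactly tied nearby regions
    (two lobes of one fossa split by a near-saddle seam) are merged.
    """
    gauss = _quantized_gaussian(field)
    concave = np.flatnonzero(
        (field.kappa1 < -_MIN_CONCAVITY) & (field.kappa2 < -_MIN_CONCAVITY) & allowed_mask
    )
    if len(concave) < _MIN_DEPRESSION:
        raise NoOcclusalSurfaceError("no concave occlusal depression on the surface")
    e, adj = _vertex_adjacency(surface)
    # dilate two vertex rings before componentising so thin seams reconnect
    inmask = np.zeros(surface.n_vertices, dtype=bool)
    inmask[concave] = True
    grown = inmask.copy()
    for _ in range(2):
        grown = grown | (adj @ grown.astype(float) > 0)
    comps = []
    for comp in _components_of(np.flatnonzero(grown), e, surface.n_vertices):
        members = comp[inmask[comp]]
        if len(members) >= _MIN_DEPRESSION:
            comps.append(members)
    if not comps:
        raise NoOcclusalSurfaceError("no concave occlusal depression on the surface")
    # agglomerate nearby same-facing regions: lobes of one fossa (split by a
    # near-saddle seam) reunite; regions on opposite sheets never merge
    def stats(c):
        ctr = surface.vertices[c].mean(axis=0)
        diam = 2.0 * np.linalg.norm(surface.vertices[c] - ctr, axis=1).max()
        nrm = field.normals[c].mean(axis=0)
        nrm /= max(np.linalg.norm(nrm), 1e-12)
        return ctr, diam, nrm

    comps.sort(key=lambda c: c[0])
    merged = True
    while merged and len(comps) > 1:
        merged = False
        for i in range(len(comps)):
            for j in range(i + 1, len(comps)):
                ci, di, ni = stats(comps[i])
                cj, dj, nj = stats(comps[j])
                if ni @ nj > 0.5 and np.linalg.norm(ci - cj) <= 0.75 * (di + dj):
                    comps[i] = np.sort(np.concatenate([comps[i], comps[j]]))
                    comps.pop(j)
                    merged = True
                    break
            if merged:
                break
    scores = [float(np.sum(gauss[c])) for c in comps]
    order = sorted(range(len(comps)), key=lambda i: (-scores[i], comps[i][0]))
    return [comps[i] for i in order]


def detect_occlusal_border(
    surface: TriangulatedSurface,
    field: CurvatureField,
    percentile: float = 90.0,
    candidate_vertices: np.ndarray | None = None,
) -> OcclusalBorder:
    """Closed loop of maximal-Gaussian-curvature points encircling the
    central occlusal depression.

    Depression candidates are the dominant connected concave (bowl-like)
    regions.  Around each, the border band is the high-K percentile mask
    filtered by facing direction, height above the fossa and ring radius,
    re-anchored on itself until self-consistent; the candidate whose band
    carries the highest mean Gaussian curvature wins.  The ordered loop is
    the band thinned to one max-K vertex per angular cluster (star-shaped,
    hence simple).  Deterministic and rigid-motion equivariant: the
    angular reference is mesh-intrinsic and curvature ties are broken by
    vertex index on a quantised field.
    """
    surface.validate()
    n = surface.n_vertices
    allowed = np.ones(n, dtype=bool)
    if candidate_vertices is not None:
        allowed[:] = False
        allowed[candidate_vertices] = True

    depressions = _find_depressions(surface, field, allowed)
    gauss = _quantized_gaussian(field)
    mask = curvature_percentile_mask(field, percentile)

    def loop_around(depression):
        weights = np.maximum(gauss[depression], 0) + 1e-12
        center = np.average(surface.vertices[depression], axis=0, weights=weights)
        # a bowl's outward normals point away from the body, toward the
        # occlusal side
        n_d = field.normals[depression].mean(axis=0)
        norm = np.linalg.norm(n_d)
        if norm < 1e-12:
            raise NoOcclusalSurfaceError("depression normals cancel out")
        n_d = n_d / norm

        in_depression = np.zeros(n, dtype=bool)
        in_depression[depression] = True

        # self-consistent passes: the depression centroid/normal only seed
        # the search; the ring re-anchors its own centre and plane normal,
        # so the result is independent of where the anchor sat
        cand2 = None
        for _ in range(3):
            facing = field.normals @ n_d > _NORMAL_GATE
            # the border encircles a depression: its points lie above the
            # depression centre along the occlusal direction
            above = (surface.vertices - center) @ n_d > 0
            cand = mask[facing[mask] & above[mask] & allowed[mask] & ~in_depression[mask]]
            if len(cand) < 3:
                raise NoOcclusalSurfaceError("no high-curvature points around the depression")
            rel = surface.vertices - center
            rel_p = rel - np.outer(rel @ n_d, n_d)
            radius = np.linalg.norm(rel_p, axis=1)
            r_med = float(np.median(radius[cand]))
            keep = (radius[cand] > 0.6 * r_med) & (radius[cand] < 1.45 * r_med)
            cand2 = cand[keep]
            if len(cand2) < 3:
                raise NoOcclusalSurfaceError("border candidates collapse onto the depression")
            ring_center = surface.vertices[cand2].mean(axis=0)
            ring_normal = field.normals[cand2].mean(axis=0)
            ring_norm = np.linalg.norm(ring_normal)
            if ring_norm < 1e-12:
                break
            # recentre laterally on the ring, keep the gate plane at the
            # fossa height so the above-gate still admits the whole ring
            center = ring_center + ((center - ring_center) @ n_d) * n_d
            n_d = ring_normal / ring_norm

        # angular reference: direction to the globally best candidate
        rel = surface.vertices - center
        rel_p = rel - np.outer(rel @ n_d, n_d)
        ref = cand2[np.lexsort((cand2, -gauss[cand2]))[0]]
        e1 = rel_p[ref] / max(np.linalg.norm(rel_p[ref]), 1e-12)
        e2 = np.cross(n_d, e1)
        angle = np.arctan2(rel_p @ e2, rel_p @ e1) % (2 * np.pi)

        # thin near-coincident angles to one point (max K) per cluster so the
        # angle-ordered polygon is star-shaped and therefore simple; cluster
        # boundaries come from the data's angular gaps, which are rigid-
        # motion invariant
        order = cand2[np.lexsort((cand2, angle[cand2]))]
        tol = np.pi / max(len(order), 8)
        ang = angle[order]
        gaps = np.flatnonzero(np.diff(ang) >= tol)
        if len(gaps) == 0:
            clusters = [order]
        else:
            bounds = np.r_[gaps + 1]
            clusters = np.split(order, bounds)
            # wrap-around: first and last cluster may be one
            if (ang[0] + 2 * np.pi) - ang[-1] < tol and len(clusters) > 1:
                clusters[0] = np.concatenate([clusters[-1], clusters[0]])
                clusters.pop()
        loop = []
        for cluster in clusters:
            best = cluster[np.lexsort((cluster, -gauss[cluster]))[0]]
            loop.append((angle[best], int(best)))
        loop.sort()
        return np.asarray([v for _, v in loop], dtype=np.int64), cand2

    # try the most prominent depressions; keep the loop with the highest
    # mean Gaussian curvature (maximal-curvature point set)
    scored = []
    for depression in depressions[:3]:
        try:
            loop, band = loop_around(depression)
        except NoOcclusalSurfaceError:
            continue
        scored.append((float(np.mean(gauss[band])), loop, depression, band))
    if not scored:
        raise NoOcclusalSurfaceError(
            "no closed high-curvature loop encircling a depression was found"
        )
    scored.sort(key=lambda t: (-t[0], t[1][0]))
    # two depression candidates (e.g. lobes of one fossa) may yield nearly
    # the same loop; collapse them before testing for genuine ambiguity
    distinct = []
    for item in scored:
        vertex_set = set(item[1].tolist())
        if any(
            len(vertex_set & kept) / max(len(vertex_set | kept), 1) > 0.8
            for kept in (set(d[1].tolist()) for d in distinct)
        ):
            continue
        distinct.append(item)
    scored = distinct
    if len(scored) > 1 and scored[0][0] == scored[1][0]:
        raise AmbiguousBorderError(
            "multiple equally scored occlusal-border candidates",
            candidates=[scored[0][1], scored[1][1]],
        )
    _, loop, depression, band = scored[0]
    if len(loop) < 3:
        raise NoOcclusalSurfaceError("border loop degenerate")
    return OcclusalBorder(
        points=surface.vertices[loop],
        vertex_indices=loop,
        normals=field.normals[loop],
        inside_indices=depression,
        band_indices=band,
        band_normals=field.normals[band],
    )


# ---------------------------------------------------------------------------
# frame computation


def _max_extent_direction(points2: np.ndarray) -> np.ndarray:
    """Unit 2-vector maximising the projected extent of the point set."""
    from scipy.spatial import ConvexHull

    if len(points2) > 10:
        try:
            points2 = points2[ConvexHull(points2).vertices]
        except Exception:
            pass
    thetas = np.linspace(0.0, np.pi, 1800, endpoint=False)
    dirs = np.column_stack([np.cos(thetas), np.sin(thetas)])
    proj = points2 @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    i = int(np.argmax(widths))
    # parabolic refinement around the best angle
    lo, hi = thetas[i] - np.pi / 1800, thetas[i] + np.pi / 1800
    fine = np.linspace(lo, hi, 201)
    dirs = np.column_stack([np.cos(fine), np.sin(fine)])
    proj = points2 @ dirs.T
    widths = proj.max(axis=0) - proj.min(axis=0)
    theta = fine[int(np.argmax(widths))]
    return np.array([np.cos(theta), np.sin(theta)])


def compute_frame(
    border: OcclusalBorder,
    surface: TriangulatedSurface,
    calibration_angle: float = np.radians(25.0),
) -> ToothFrame:
    """Origin = border centroid; vertical = mean border normal; mesio-distal
    = fitted-ellipse major axis, replaced by the crown's maximal-extent
    direction when the two deviate by more than ``calibration_angle``.
    """
    if len(border) < 3:
        raise DegenerateFrameError("border too short")
    # use the full maximal-K band (Ob) when available: denser and more
    # stable than the thinned ordered loop
    if border.band_indices is not None and len(border.band_indices) > len(border):
        pts = surface.vertices[border.band_indices]
        normals = border.band_normals
    else:
        pts, normals = border.points, border.normals
    origin = pts.mean(axis=0)
    nt = normals.mean(axis=0)
    norm = np.linalg.norm(nt)
    if norm < 1e-12:
        raise DegenerateFrameError("border normals cancel out")
    nt = nt / norm
    if nt @ (origin - surface.centroid()) < 0:
        nt = -nt

    # in-plane basis (any orthonormal pair; final 3D axes are basis-free)
    a = np.array([1.0, 0.0, 0.0]) if abs(nt[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(nt, a)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(nt, e1)

    border2 = np.column_stack([(border.points - origin) @ e1, (border.points - origin) @ e2])
    try:
        ellipse = fit_ellipse(border2)
        md2 = ellipse.major_axis_direction
    except EllipseFitError as exc:
        raise DegenerateFrameError(f"border does not define an ellipse: {exc}") from exc

    all2 = np.column_stack([(surface.vertices - origin) @ e1, (surface.vertices - origin) @ e2])
    ext2 = _max_extent_direction(all2)
    cosang = abs(float(np.clip(md2 @ ext2, -1.0, 1.0)))
    calibrated = np.arccos(cosang) > calibration_angle
    if calibrated:
        log.warning(
            "ellipse major axis deviates %.1f deg from the maximal crown extent; "
            "using the extent direction",
            np.degrees(np.arccos(cosang)),
        )
        md2 = ext2

    md = md2[0] * e1 + md2[1] * e2
    md /= np.linalg.norm(md)
    # sign: positive toward the larger half-extent of the crown
    proj = (surface.vertices - origin) @ md
    if -proj.min() > proj.max():
        md = -md
    vo = np.cross(nt, md)
    vo /= np.linalg.norm(vo)
    md = np.cross(vo, nt)  # exact orthonormality
    return ToothFrame(
        origin=origin,
        vertical_axis=nt,
        mesiodistal_axis=md,
        vestibulooral_axis=vo,
        calibrated=bool(calibrated),
    )


def iterate_orientation(
    surface: TriangulatedSurface,
    field: CurvatureField,
    percentile: float = 90.0,
    max_iterations: int = 10,
    tolerance: float = 0.005,
) -> tuple[OcclusalBorder, ToothFrame]:
    """Alternate border re-selection and frame recomputation.

    After the first pass the loop search is restricted to the crown region
    facing the current +vertical half-space (vertex normal . vertical > 0)
    until the vertical axis settles below ``tolerance`` radians.
    """
    if max_iterations < 1:
        raise ValueError("max_iterations must be >= 1")
    border = detect_occlusal_border(surface, field, percentile)
    frame = compute_frame(border, surface)
    if tolerance >= np.pi:
        frame.iterations_used = 1
        frame.converged = True
        return border, frame

    prev_v = frame.vertical_axis
    best = (np.inf, border, frame, 1)
    for it in range(2, max_iterations + 1):
        visible = np.flatnonzero(field.normals @ prev_v > 0)
        try:
            border = detect_occlusal_border(surface, field, percentile, candidate_vertices=visible)
            frame = compute_frame(border, surface)
        except (NoOcclusalSurfaceError, DegenerateFrameError):
            break
        delta = float(np.arccos(np.clip(abs(prev_v @ frame.vertical_axis), -1.0, 1.0)))
        if delta < best[0]:
            best = (delta, border, frame, it)
        if delta < tolerance:
            frame.iterations_used = it
            frame.converged = True
            return border, frame
        prev_v = frame.vertical_axis
    warnings.warn("orientation did not converge; returning best frame", stacklevel=2)
    _, border, frame, it = best
    frame.iterations_used = it
    frame.converged = False
    return border, frame
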