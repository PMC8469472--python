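"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's own algorithms: the bridge scan
tries every point pair, and the discrete Gaussian curvature uses the
angle-deficit formula instead of quadric fitting.
"""

import numpy as np


def brute_force_bridge(points, closed=True):
    """Exhaustive parallel-tangent construction on a 2D contour.

    Scans every ordered point pair as a candidate upper bridge (no point
    with abscissa between them may lie above the chord), walks the contour
    path joining the pair for the deepest point, and keeps the deepest
    bridge overall.  Returns (tip_left, tip_right, deepest, depth).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    # exhaustive upper-hull membership: a point is on the upper hull iff no
    # chord between points straddling it passes strictly above it
    on_hull = np.ones(n, dtype=bool)
    for u in range(n):
        for w in range(n):
            if pts[u, 0] >= pts[w, 0]:
                continue
            straddled = (pts[:, 0] > pts[u, 0]) & (pts[:, 0] < pts[w, 0])
            if not straddled.any():
                continue
            t = (pts[straddled, 0] - pts[u, 0]) / (pts[w, 0] - pts[u, 0])
            chord_y = pts[u, 1] + t * (pts[w, 1] - pts[u, 1])
            covered = np.flatnonzero(straddled)[chord_y > pts[straddled, 1] + 1e-9]
            on_hull[covered] = False
    best = None
    for i in range(n):
        for j in range(n):
            if i == j or not (on_hull[i] and on_hull[j]):
                continue
            a, c = pts[i], pts[j]
            if a[0] >= c[0]:
                continue
            seg = c - a
            norm = np.hypot(seg[0], seg[1])
            if norm < 1e-12:
                continue
            in_span = pts[(pts[:, 0] > a[0]) & (pts[:, 0] < c[0])]
            if len(in_span):
                off_span = (
                    seg[0] * (a[1] - in_span[:, 1]) - seg[1] * (a[0] - in_span[:, 0])
                ) / norm
                if off_span.min() < -1e-9:  # something pokes above: not a bridge
                    continue
            # walk the contour path(s) joining i and j for the deepest point
            lo, hi = sorted((i, j))
            paths = [list(range(lo + 1, hi))]
            if closed:
                paths.append(list(range(hi + 1, n)) + list(range(0, lo)))
            candidates = []
            for path in paths:
                if not path:
                    continue
                sub = pts[path]
                inside = np.all(
                    (sub[:, 0] >= a[0] - 1e-9) & (sub[:, 0] <= c[0] + 1e-9)
                )
                if not inside:  # the occlusal arc stays between the tips
                    continue
                off = (seg[0] * (a[1] - sub[:, 1]) - seg[1] * (a[0] - sub[:, 0])) / norm
                candidates.append((len(path), float(off.max()), sub[int(off.argmax())]))
            if not candidates:
                continue
            candidates.sort(key=lambda t: t[0])
            _, depth, deepest = candidates[0]
            if best is None or depth > best[3]:
                best = (a.copy(), c.copy(), deepest.copy(), depth)
    if best is None:
        raise ValueError("no bridge on this contour")
    return best


def angle_deficit_gaussian(surface):
    """Discrete Gaussian curvature: angle deficit / mixed area (closed mesh)."""
    v = surface.vertices
    f = surface.faces
    deficit = np.full(len(v), 2.0 * np.pi)
    area = np.zeros(len(v))
    for k in range(3):
        a = v[f[:, k]]
        b = v[f[:, (k + 1) % 3]]
        c = v[f[:, (k + 2) % 3]]
        u1 = b - a
        u2 = c - a
        cosang = np.einsum("ij,ij->i", u1, u2) / (
            np.linalg.norm(u1, axis=1) * np.linalg.norm(u2, axis=1)
        )
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.subtract.at(deficit, f[:, k], ang)
        tri_area = 0.5 * np.linalg.norm(np.cross(u1, u2), axis=1)
        np.add.at(area, f[:, k], tri_area / 3.0)
    return deficit / np.maximum(area, 1e-15)


def shoelace_area(points):
    x, y = np.asarray(points, float).T
    return abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0


def grid_mesh(fn, n=30, extent=1.0):
    """Triangulated graph of z = fn(x, y) over a square grid (open surface)."""
    from ado.mesh_io import TriangulatedSurface

    xs = np.linspace(-extent, extent, n)
    xx, yy = np.meshgrid(xs, xs, indexing="ij")
    zz = fn(xx, yy)
    verts = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    faces = []
    for i in range(n - 1):
        for j in range(n - 1):
            a = i * n + j
            b = a + 1
            c = a + n
            d = c + 1
            faces.append((a, b, d))
            faces.append((a, d, c))
    return TriangulatedSurface(verts, np.asarray(faces, dtype=np.int64))
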