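"""Triangulated tooth-surface data model and PLY/STL/OBJ input/output.

All coordinates are millimetres.  The loader merges duplicate vertices,
drops degenerate faces and makes face winding consistent, so downstream
stages can assume a clean edge-manifold surface.
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyMeshError, MeshFormatError, RepairError

log = logging.getLogger(__name__)

_MERGE_TOL = 1e-9          # mm, duplicate-vertex merge distance
_DEGENERATE_AREA = 1e-12   # mm^2

FORMATS = ("ply", "stl", "obj")


# ---------------------------------------------------------------------------
# data model


@dataclass
class TriangulatedSurface:
    """A triangulated irregular network: vertices (mm) and vertex-index faces."""

    vertices: np.ndarray               # (N, 3) float64
    faces: np.ndarray                  # (M, 3) int64
    normals: np.ndarray | None = None  # (N, 3) optional per-vertex unit normals

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.faces = np.ascontiguousarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (N, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be an (M, 3) array")
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)

    # -- basic quantities ---------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def face_normals(self, normalize: bool = True) -> np.ndarray:
        v = self.vertices
        f = self.faces
        n = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        if normalize:
            lens = np.linalg.norm(n, axis=1)
            lens[lens == 0] = 1.0
            n = n / lens[:, None]
        return n

    def face_areas(self) -> np.ndarray:
        return 0.5 * np.linalg.norm(
            np.cross(
                self.vertices[self.faces[:, 1]] - self.vertices[self.faces[:, 0]],
                self.vertices[self.faces[:, 2]] - self.vertices[self.faces[:, 0]],
            ),
            axis=1,
        )

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex outward normals (unit length)."""
        fn = self.face_normals(normalize=False)  # area weighting via magnitude
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        lens = np.linalg.norm(vn, axis=1)
        lens[lens == 0] = 1.0
        return vn / lens[:, None]

    def edges(self, unique: bool = True) -> np.ndarray:
        e = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0) if unique else e

    def edge_face_counts(self) -> tuple[np.ndarray, np.ndarray]:
        e = self.edges(unique=False)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        return uniq, counts

    def boundary_edges(self) -> np.ndarray:
        uniq, counts = self.edge_face_counts()
        return uniq[counts == 1]

    def is_edge_manifold(self) -> bool:
        _, counts = self.edge_face_counts()
        return bool(np.all(counts <= 2))

    def is_watertight(self) -> bool:
        return self.is_edge_manifold() and len(self.boundary_edges()) == 0

    def mean_edge_length(self) -> float:
        e = self.edges()
        return float(
            np.mean(np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1))
        )

    def centroid(self) -> np.ndarray:
        return self.vertices.mean(axis=0)

    def boundary_loops(self) -> list[list[int]]:
        """Ordered vertex loops of the surface boundary (one list per loop)."""
        be = self.boundary_edges()
        if len(be) == 0:
            return []
        adj: dict[int, list[int]] = {}
        for a, b in be:
            adj.setdefault(int(a), []).append(int(b))
            adj.setdefault(int(b), []).append(int(a))
        seen: set[tuple[int, int]] = set()
        loops = []
        for a0, b0 in be:
            a0, b0 = int(a0), int(b0)
            if (a0, b0) in seen or (b0, a0) in seen:
                continue
            loop = [a0, b0]
            seen.add((a0, b0))
            prev, cur = a0, b0
            while True:
                nbrs = [n for n in adj[cur] if n != prev]
                if not nbrs:
                    break
                nxt = nbrs[0]
                seen.add((cur, nxt))
                if nxt == loop[0]:
                    break
                loop.append(nxt)
                prev, cur = cur, nxt
            loops.append(loop)
        return loops

    def validate(self) -> None:
        """Raise if the surface violates its structural invariants."""
        if self.n_vertices < 4 or self.n_faces < 4:
            raise EmptyMeshError(
                f"surface too small: {self.n_vertices} vertices, {self.n_faces} faces"
            )
        if self.faces.min() < 0 or self.faces.max() >= self.n_vertices:
            raise MeshFormatError("face references out-of-range vertex index")
        if np.any(
            (self.faces[:, 0] == self.faces[:, 1])
            | (self.faces[:, 1] == self.faces[:, 2])
            | (self.faces[:, 2] == self.faces[:, 0])
        ):
            raise MeshFormatError("face references repeated vertex index")
        if np.any(self.face_areas() < _DEGENERATE_AREA):
            raise MeshFormatError("degenerate (zero-area) face present")

    def copy(self) -> "TriangulatedSurface":
        return TriangulatedSurface(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.normals is None else self.normals.copy(),
        )


# ---------------------------------------------------------------------------
# canonicalisation helpers


def _merge_duplicate_vertices(vertices, faces, tol=_MERGE_TOL):
    if len(vertices) == 0:
        return vertices, faces
    tree = cKDTree(vertices)
    pairs = tree.query_pairs(tol, output_type="ndarray")
    remap = np.arange(len(vertices))
    for a, b in pairs:  # union toward the lower index
        ra, rb = remap[a], remap[b]
        while remap[ra] != ra:
            ra = remap[ra]
        while remap[rb] != rb:
            rb = remap[rb]
        lo, hi = min(ra, rb), max(ra, rb)
        remap[hi] = lo
    for i in range(len(remap)):  # path compression
        r = i
        while remap[r] != r:
            r = remap[r]
        remap[i] = r
    keep = np.flatnonzero(remap == np.arange(len(vertices)))
    new_index = np.full(len(vertices), -1, dtype=np.int64)
    new_index[keep] = np.arange(len(keep))
    faces = new_index[remap[faces]]
    return vertices[keep], faces


def _drop_degenerate_faces(vertices, faces):
    if len(faces) == 0:
        return faces
    distinct = (
        (faces[:, 0] != faces[:, 1])
        & (faces[:, 1] != faces[:, 2])
        & (faces[:, 2] != faces[:, 0])
    )
    faces = faces[distinct]
    areas = 0.5 * np.linalg.norm(
        np.cross(
            vertices[faces[:, 1]] - vertices[faces[:, 0]],
            vertices[faces[:, 2]] - vertices[faces[:, 0]],
        ),
        axis=1,
    )
    return faces[areas >= _DEGENERATE_AREA]


def _orient_faces_consistently(vertices, faces):
    """Flip faces so every interior edge is traversed once in each direction.

    BFS over the face-adjacency graph; afterwards closed components are
    flipped globally if their signed volume is negative (outward normals).
    """
    m = len(faces)
    if m == 0:
        return faces
    edge_to_faces: dict[tuple[int, int], list[int]] = {}
    for fi, (a, b, c) in enumerate(faces):
        for u, v in ((a, b), (b, c), (c, a)):
            key = (min(u, v), max(u, v))
            edge_to_faces.setdefault(key, []).append(fi)

    faces = faces.copy()
    visited = np.zeros(m, dtype=bool)
    for seed in range(m):
        if visited[seed]:
            continue
        stack = [seed]
        visited[seed] = True
        comp = [seed]
        while stack:
            fi = stack.pop()
            a, b, c = faces[fi]
            for u, v in ((a, b), (b, c), (c, a)):
                key = (min(u, v), max(u, v))
                for fj in edge_to_faces[key]:
                    if visited[fj]:
                        continue
                    aj, bj, cj = faces[fj]
                    # neighbour should traverse the shared edge as (v, u)
                    if (u, v) in ((aj, bj), (bj, cj), (cj, aj)):
                        faces[fj] = faces[fj][::-1]
                    visited[fj] = True
                    comp.append(fj)
                    stack.append(fj)
        comp = np.asarray(comp)
        tri = vertices[faces[comp]]
        vol = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0
        if vol < 0:
            faces[comp] = faces[comp][:, ::-1]
    return faces


def canonicalize(surface: TriangulatedSurface) -> TriangulatedSurface:
    """Merge duplicates, drop degenerate faces, orient winding consistently."""
    v, f = _merge_duplicate_vertices(surface.vertices, surface.faces)
    f = _drop_degenerate_faces(v, f)
    if len(f) == 0 or len(v) == 0:
        raise EmptyMeshError("mesh is empty after cleanup")
    f = _orient_faces_consistently(v, f)
    return TriangulatedSurface(v, f)


# ---------------------------------------------------------------------------
# readers


def _detect_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower().lstrip(".")
        if fmt not in FORMATS:
            raise MeshFormatError(f"unsupported format {fmt!r}")
        return fmt
    ext = path.suffix.lower().lstrip(".")
    if ext in FORMATS:
        return ext
    raise MeshFormatError(f"cannot infer mesh format from {path.name!r}")


def _read_ply(data: bytes):
    try:
        header_end = data.index(b"end_header\n") + len(b"end_header\n")
    except ValueError as exc:
        raise MeshFormatError("PLY missing end_header") from exc
    header = data[:header_end].decode("ascii", errors="replace").splitlines()
    if not header or header[0].strip() != "ply":
        raise MeshFormatError("not a PLY file")
    fmt = None
    elements: list[tuple[str, int, list]] = []  # (name, count, props)
    for line in header[1:]:
        tok = line.strip().split()
        if not tok or tok[0] == "comment":
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            elements.append((tok[1], int(tok[2]), []))
        elif tok[0] == "property":
            if not elements:
                raise MeshFormatError("PLY property before element")
            elements[-1][2].append(tok[1:])
    if fmt not in ("ascii", "binary_little_endian"):
        raise MeshFormatError(f"unsupported PLY format {fmt!r}")

    _np = {
        "char": "i1", "int8": "i1", "uchar": "u1", "uint8": "u1",
        "short": "i2", "int16": "i2", "ushort": "u2", "uint16": "u2",
        "int": "i4", "int32": "i4", "uint": "u4", "uint32": "u4",
        "float": "f4", "float32": "f4", "double": "f8", "float64": "f8",
    }
    body = data[header_end:]
    vertices = None
    faces = None

    if fmt == "ascii":
        text = body.decode("ascii", errors="replace").split()
        pos = 0
        for name, count, props in elements:
            if any(p[0] == "list" for p in props):
                rows = []
                for _ in range(count):
                    n = int(float(text[pos])); pos += 1
                    rows.append([int(float(x)) for x in text[pos:pos + n]])
                    pos += n
                    # trailing non-list properties after the list are not supported
                if name == "face":
                    faces = rows
            else:
                width = len(props)
                vals = np.array(text[pos:pos + count * width], dtype=np.float64)
                pos += count * width
                vals = vals.reshape(count, width)
                if name == "vertex":
                    names = [p[1] for p in props]
                    idx = [names.index(k) for k in ("x", "y", "z")]
                    vertices = vals[:, idx]
    else:
        offset = 0
        for name, count, props in elements:
            if any(p[0] == "list" for p in props):
                list_prop = next(p for p in props if p[0] == "list")
                cnt_dt = np.dtype("<" + _np[list_prop[1]])
                idx_dt = np.dtype("<" + _np[list_prop[2]])
                rows = []
                for _ in range(count):
                    n = int(np.frombuffer(body, cnt_dt, 1, offset)[0])
                    offset += cnt_dt.itemsize
                    rows.append(np.frombuffer(body, idx_dt, n, offset).tolist())
                    offset += idx_dt.itemsize * n
                if name == "face":
                    faces = rows
            else:
                dt = np.dtype([(p[1], "<" + _np[p[0]]) for p in props])
                arr = np.frombuffer(body, dt, count, offset)
                offset += dt.itemsize * count
                if name == "vertex":
                    vertices = np.column_stack(
                        [arr["x"], arr["y"], arr["z"]]
                    ).astype(np.float64)
    if vertices is None or faces is None:
        raise MeshFormatError("PLY lacks vertex or face element")
    tri = []
    for row in faces:
        for k in range(1, len(row) - 1):  # fan-triangulate polygons
            tri.append((row[0], row[k], row[k + 1]))
    return np.asarray(vertices), np.asarray(tri, dtype=np.int64)


def _read_stl(data: bytes):
    is_ascii = data[:5] == b"solid"
    if is_ascii:
        # binary files may also begin with "solid"; verify by size
        if len(data) >= 84:
            n = struct.unpack("<I", data[80:84])[0]
            if len(data) == 84 + 50 * n:
                is_ascii = False
    if is_ascii:
        tokens = data.decode("ascii", errors="replace").split()
        pts = []
        it = iter(range(len(tokens)))
        i = 0
        while i < len(tokens):
            if tokens[i] == "vertex":
                pts.append([float(tokens[i + 1]), float(tokens[i + 2]), float(tokens[i + 3])])
                i += 4
            else:
                i += 1
        pts = np.asarray(pts, dtype=np.float64)
    else:
        if len(data) < 84:
            raise MeshFormatError("binary STL truncated")
        n = struct.unpack("<I", data[80:84])[0]
        if len(data) < 84 + 50 * n:
            raise MeshFormatError("binary STL truncated")
        rec = np.frombuffer(data, dtype=np.uint8, count=50 * n, offset=84).reshape(n, 50)
        tri = rec[:, 12:48].copy().view("<f4").reshape(n, 3, 3)
        pts = tri.reshape(-1, 3).astype(np.float64)
    if len(pts) == 0 or len(pts) % 3 != 0:
        raise MeshFormatError("STL has no complete triangles")
    faces = np.arange(len(pts), dtype=np.int64).reshape(-1, 3)
    return pts, faces


def _read_obj(data: bytes):
    vertices = []
    faces = []
    for raw in data.decode("utf-8", errors="replace").splitlines():
        tok = raw.split()
        if not tok:
            continue
        if tok[0] == "v":
            vertices.append([float(tok[1]), float(tok[2]), float(tok[3])])
        elif tok[0] == "f":
            idx = []
            for t in tok[1:]:
                s = t.split("/")[0]
                i = int(s)
                idx.append(i - 1 if i > 0 else len(vertices) + i)
            for k in range(1, len(idx) - 1):
                faces.append((idx[0], idx[k], idx[k + 1]))
    if not vertices or not faces:
        raise MeshFormatError("OBJ lacks v/f records")
    return np.asarray(vertices, dtype=np.float64), np.asarray(faces, dtype=np.int64)


def load_surface(path, format: str | None = None) -> TriangulatedSurface:
    """Load a PLY/STL/OBJ surface, canonicalised (mm units assumed)."""
    path = Path(path)
    fmt = _detect_format(path, format)
    try:
        data = path.read_bytes()
    except OSError as exc:
        raise MeshFormatError(f"cannot read {path}: {exc}") from exc
    reader = {"ply": _read_ply, "stl": _read_stl, "obj": _read_obj}[fmt]
    try:
        vertices, faces = reader(data)
    except MeshFormatError:
        raise
    except Exception as exc:
        raise MeshFormatError(f"failed to parse {path} as {fmt}: {exc}") from exc
    if len(vertices) == 0 or len(faces) == 0:
        raise EmptyMeshError(f"{path} contains an empty mesh")
    surface = canonicalize(TriangulatedSurface(vertices, faces))
    surface.validate()
    return surface


# ---------------------------------------------------------------------------
# writers


def write_surface(surface: TriangulatedSurface, path, format: str | None = None) -> None:
    """Write a surface; round-trips within 1e-6 mm for all three formats."""
    path = Path(path)
    fmt = _detect_format(path, format)
    if fmt == "stl" and not surface.is_edge_manifold():
        log.warning("writing non-manifold surface to STL %s", path)
    v, f = surface.vertices, surface.faces
    lines: list[str] = []
    if fmt == "ply":
        lines += [
            "ply", "format ascii 1.0",
            f"element vertex {len(v)}",
            "property double x", "property double y", "property double z",
            f"element face {len(f)}",
            "property list uchar int vertex_indices",
            "end_header",
        ]
        lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in v]
        lines += [f"3 {a} {b} {c}" for a, b, c in f]
    elif fmt == "obj":
        lines += [f"v {x:.17g} {y:.17g} {z:.17g}" for x, y, z in v]
        lines += [f"f {a + 1} {b + 1} {c + 1}" for a, b, c in f]
    else:  # ascii STL
        fn = surface.face_normals()
        lines.append("solid ado")
        for (a, b, c), n in zip(f, fn):
            lines.append(f" facet normal {n[0]:.17g} {n[1]:.17g} {n[2]:.17g}")
            lines.append("  outer loop")
            for i in (a, b, c):
                x, y, z = v[i]
                lines.append(f"   vertex {x:.17g} {y:.17g} {z:.17g}")
            lines.append("  endloop")
            lines.append(" endfacet")
        lines.append("endsolid ado")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise MeshFormatError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# repair


def _fill_small_holes(surface: TriangulatedSurface, max_perimeter: float):
    """Triangulate boundary loops shorter than max_perimeter (fan to centroid).

    The cervical opening of an enamel cap has a large perimeter and is
    deliberately left open by the default cap.
    """
    loops = surface.boundary_loops()
    if not loops:
        return surface
    v = surface.vertices
    new_vertices = [v]
    new_faces = [surface.faces]
    next_index = len(v)
    for loop in loops:
        pts = v[loop]
        perim = float(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1).sum())
        if perim >= max_perimeter:
            continue
        if len(loop) == 3:
            new_faces.append(np.array([loop[::-1]], dtype=np.int64))
            continue
        center = pts.mean(axis=0)
        new_vertices.append(center[None, :])
        tri = [
            (loop[(k + 1) % len(loop)], loop[k], next_index)
            for k in range(len(loop))
        ]
        new_faces.append(np.asarray(tri, dtype=np.int64))
        next_index += 1
    out = TriangulatedSurface(np.vstack(new_vertices), np.vstack(new_faces))
    return TriangulatedSurface(out.vertices, _orient_faces_consistently(out.vertices, out.faces))


def _laplacian_smooth(surface: TriangulatedSurface, iterations: int,
                      lam: float = 0.5, mu: float = -0.53):
    """Taubin lambda/mu smoothing: removes noise without the shrinkage a
    plain umbrella operator would cause.  Boundary vertices stay fixed."""
    if iterations <= 0:
        return surface
    v = surface.vertices.copy()
    e = surface.edges()
    boundary = np.unique(surface.boundary_edges())
    interior = np.ones(len(v), dtype=bool)
    interior[boundary] = False
    deg = np.zeros(len(v))
    np.add.at(deg, e[:, 0], 1.0)
    np.add.at(deg, e[:, 1], 1.0)
    deg[deg == 0] = 1.0

    def step(v, factor):
        acc = np.zeros_like(v)
        np.add.at(acc, e[:, 0], v[e[:, 1]])
        np.add.at(acc, e[:, 1], v[e[:, 0]])
        target = acc / deg[:, None]
        v[interior] += factor * (target[interior] - v[interior])
        return v

    for _ in range(iterations):
        v = step(v, lam)
        v = step(v, mu)
    return TriangulatedSurface(v, surface.faces.copy())


def _quadric_decimate(surface: TriangulatedSurface, target_faces: int, tol: float):
    """Greedy quadric-error edge collapse down to target_faces.

    Collapses to edge midpoints; skips collapses that would break the
    boundary, flip normals or exceed the quadric-error tolerance.
    """
    import heapq

    v = [p for p in surface.vertices]
    quadrics = [np.zeros((4, 4)) for _ in v]
    for (a, b, c) in surface.faces:
        p0, p1, p2 = surface.vertices[[a, b, c]]
        n = np.cross(p1 - p0, p2 - p0)
        area = np.linalg.norm(n)
        if area < 1e-15:
            continue
        n = n / area
        plane = np.append(n, -n.dot(p0))
        q = np.outer(plane, plane) * area
        for i in (a, b, c):
            quadrics[i] += q
    face_set = {tuple(f) for f in map(tuple, surface.faces)}
    vert_faces: dict[int, set] = {}
    for f in face_set:
        for i in f:
            vert_faces.setdefault(i, set()).add(f)
    boundary = set(np.unique(surface.boundary_edges()).tolist())
    alive = [True] * len(v)

    def cost(a, b):
        mid = 0.5 * (v[a] + v[b])
        h = np.append(mid, 1.0)
        return float(h @ (quadrics[a] + quadrics[b]) @ h), mid

    heap = []
    for a, b in surface.edges():
        a, b = int(a), int(b)
        c, _ = cost(a, b)
        heapq.heappush(heap, (c, a, b))

    n_faces = len(face_set)
    while heap and n_faces > target_faces:
        c, a, b = heapq.heappop(heap)
        if not (alive[a] and alive[b]):
            continue
        if a in boundary or b in boundary:
            continue
        fa, fb = vert_faces.get(a, set()), vert_faces.get(b, set())
        shared = [f for f in fa if b in f]
        if len(shared) != 2:  # non-manifold or stale edge
            continue
        cc, mid = cost(a, b)
        if cc > c + 1e-12:
            heapq.heappush(heap, (cc, a, b))
            continue
        if cc > tol:
            continue
        # link condition: neighbours of a and b (excluding shared-face apexes)
        na = {i for f in fa for i in f} - {a, b}
        nb = {i for f in fb for i in f} - {a, b}
        apexes = {i for f in shared for i in f} - {a, b}
        if (na & nb) - apexes:
            continue
        # normal-flip check on surviving faces
        ok = True
        for f in (fa | fb) - set(shared):
            pts_old = [v[i] for i in f]
            pts_new = [mid if i in (a, b) else v[i] for i in f]
            n_old = np.cross(pts_old[1] - pts_old[0], pts_old[2] - pts_old[0])
            n_new = np.cross(pts_new[1] - pts_new[0], pts_new[2] - pts_new[0])
            if n_old.dot(n_new) <= 0:
                ok = False
                break
        if not ok:
            continue
        # perform collapse: b -> a, a moved to midpoint
        v[a] = mid
        quadrics[a] = quadrics[a] + quadrics[b]
        alive[b] = False
        for f in shared:
            for i in f:
                vert_faces[i].discard(f)
            face_set.discard(f)
            n_faces -= 1
        for f in list(fb):
            if b not in f:
                continue
            newf = tuple(a if i == b else i for i in f)
            for i in f:
                vert_faces[i].discard(f)
            face_set.discard(f)
            for i in newf:
                vert_faces.setdefault(i, set()).add(newf)
            face_set.add(newf)
        for nbr in {i for f in vert_faces.get(a, set()) for i in f} - {a}:
            cn, _ = cost(a, nbr)
            heapq.heappush(heap, (cn, min(a, nbr), max(a, nbr)))

    used = sorted({i for f in face_set for i in f})
    remap = {i: k for k, i in enumerate(used)}
    nv = np.asarray([v[i] for i in used])
    nf = np.asarray([[remap[i] for i in f] for f in face_set], dtype=np.int64)
    out = TriangulatedSurface(nv, nf)
    return TriangulatedSurface(nv, _orient_faces_consistently(nv, out.faces))


def repair_surface(
    surface: TriangulatedSurface,
    fill_holes: bool = False,
    smooth_iterations: int = 0,
    target_face_count: int | None = None,
    hole_perimeter: float = 2.0,
    decimation_tolerance: float = 0.01,
) -> TriangulatedSurface:
    """Patch small perforations, smooth, and optionally decimate.

    Boundary loops with perimeter >= ``hole_perimeter`` (mm) are kept open:
    an enamel cap's cervical opening must never be filled.
    """
    surface.validate()
    out = canonicalize(surface)
    uniq, counts = out.edge_face_counts()
    if np.any(counts > 2):
        bad = uniq[counts > 2]
        raise RepairError(
            f"{len(bad)} non-manifold edges cannot be repaired",
            offending_edges=[tuple(e) for e in bad],
        )
    if fill_holes:
        out = _fill_small_holes(out, hole_perimeter)
    if smooth_iterations:
        out = _laplacian_smooth(out, smooth_iterations)
    if target_face_count is not None and target_face_count < out.n_faces:
        out = _quadric_decimate(out, int(target_face_count), decimation_tolerance)
    out.validate()
    return out
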