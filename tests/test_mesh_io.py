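import numpy as np
import pytest

from ado.errors import EmptyMeshError, MeshFormatError, RepairError
from ado.mesh_io import (
    TriangulatedSurface,
    canonicalize,
    load_surface,
    repair_surface,
    write_surface,
)
from ado.synthetic import icosphere


def tetrahedron():
    v = np.array(
        [[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
    )
    f = np.array([[0, 2, 1], [0, 1, 3], [0, 3, 2], [1, 2, 3]], dtype=np.int64)
    return TriangulatedSurface(v, f)


def canonical_sets(surface):
    verts = {tuple(np.round(p, 9)) for p in surface.vertices}
    faces = {
        frozenset(tuple(np.round(surface.vertices[i], 9)) for i in f)
        for f in surface.faces
    }
    return verts, faces


class TestLoadWrite:
    def test_tetrahedron_stl_roundtrip(self, tmp_path):
        path = tmp_path / "tet.stl"
        write_surface(tetrahedron(), path)
        loaded = load_surface(path)
        assert loaded.n_vertices == 4
        assert loaded.n_faces == 4

    @pytest.mark.parametrize("fmt", ["ply", "stl", "obj"])
    def test_roundtrip_within_tolerance(self, tmp_path, fmt):
        sphere = icosphere(1.7, 2)
        path = tmp_path / f"s.{fmt}"
        write_surface(sphere, path)
        loaded = load_surface(path)
        assert loaded.n_faces == sphere.n_faces
        from scipy.spatial import cKDTree

        d, _ = cKDTree(sphere.vertices).query(loaded.vertices)
        assert d.max() < 1e-6

    def test_ply_and_stl_same_geometry(self, tmp_path):
        surf = icosphere(1.0, 1)
        p1, p2 = tmp_path / "a.ply", tmp_path / "a.stl"
        write_surface(surf, p1)
        write_surface(surf, p2)
        assert canonical_sets(load_surface(p1)) == canonical_sets(load_surface(p2))

    def test_synthetic_fixture_vertex_count(self, tmp_path, coarse_fixture):
        path = tmp_path / "shell.ply"
        write_surface(coarse_fixture.shell, path)
        loaded = load_surface(path)
        assert loaded.n_vertices == coarse_fixture.ground_truth.n_vertices["shell"]

    def test_obj_preserves_face_count(self, tmp_path):
        surf = icosphere(1.0, 2)
        path = tmp_path / "s.obj"
        write_surface(surf, path)
        assert load_surface(path).n_faces == surf.n_faces

    def test_binary_ply_reader(self, tmp_path):
        surf = tetrahedron()
        path = tmp_path / "bin.ply"
        header = (
            "ply\nformat binary_little_endian 1.0\n"
            f"element vertex {surf.n_vertices}\n"
            "property float x\nproperty float y\nproperty float z\n"
            f"element face {surf.n_faces}\n"
            "property list uchar int vertex_indices\nend_header\n"
        ).encode()
        body = surf.vertices.astype("<f4").tobytes()
        for f in surf.faces:
            body += np.uint8(3).tobytes() + f.astype("<i4").tobytes()
        path.write_bytes(header + body)
        loaded = load_surface(path)
        assert loaded.n_vertices == 4 and loaded.n_faces == 4

    def test_binary_stl_reader(self, tmp_path):
        surf = tetrahedron()
        tri = surf.vertices[surf.faces].astype("<f4")
        rec = np.zeros(len(tri), dtype=np.dtype("(12,)<f4, <u2"))
        rec["f0"][:, 3:] = tri.reshape(len(tri), 9)
        path = tmp_path / "bin.stl"
        path.write_bytes(b"\0" * 80 + np.uint32(len(tri)).tobytes() + rec.tobytes())
        loaded = load_surface(path)
        assert loaded.n_vertices == 4 and loaded.n_faces == 4

    def test_unreadable_file_raises(self, tmp_path):
        bad = tmp_path / "bad.ply"
        bad.write_text("not a mesh at all\n")
        with pytest.raises(MeshFormatError):
            load_surface(bad)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(MeshFormatError):
            load_surface(tmp_path / "nope.stl")

    def test_empty_mesh_raises(self, tmp_path):
        path = tmp_path / "empty.obj"
        path.write_text("# empty\n")
        with pytest.raises((MeshFormatError, EmptyMeshError)):
            load_surface(path)

    def test_unknown_format_raises(self, tmp_path):
        with pytest.raises(MeshFormatError):
            load_surface(tmp_path / "mesh.xyz")

    def test_stl_write_non_manifold_warns_but_writes(self, tmp_path, caplog):
        v = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0], [1, 1, 1]],
            dtype=float,
        )
        # three faces sharing one edge: non-manifold
        f = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4], [2, 3, 5]], dtype=np.int64)
        surf = TriangulatedSurface(v, f)
        path = tmp_path / "nm.stl"
        with caplog.at_level("WARNING"):
            write_surface(surf, path)
        assert path.exists()
        assert any("non-manifold" in r.message for r in caplog.records)

    def test_duplicate_vertices_merged(self, tmp_path):
        # tetrahedron written face-by-face (12 duplicated vertices)
        surf = tetrahedron()
        path = tmp_path / "dup.obj"
        lines = []
        for a, b, c in surf.faces:
            for i in (a, b, c):
                x, y, z = surf.vertices[i]
                lines.append(f"v {x} {y} {z}")
        for k in range(4):
            lines.append(f"f {3 * k + 1} {3 * k + 2} {3 * k + 3}")
        path.write_text("\n".join(lines) + "\n")
        loaded = load_surface(path)
        assert loaded.n_vertices == 4

    def test_winding_made_consistent(self):
        surf = tetrahedron()
        flipped = surf.faces.copy()
        flipped[2] = flipped[2][::-1]
        fixed = canonicalize(TriangulatedSurface(surf.vertices, flipped))
        # consistent outward orientation implies positive signed volume
        tri = fixed.vertices[fixed.faces]
        vol = np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6
        assert vol > 0


class TestRepair:
    def test_closed_surface_unchanged(self):
        sphere = icosphere(1.0, 2)
        out = repair_surface(sphere, fill_holes=True)
        assert out.n_vertices == sphere.n_vertices
        assert out.n_faces == sphere.n_faces

    def test_single_hole_patched(self):
        sphere = icosphere(1.0, 2)
        holed = TriangulatedSurface(sphere.vertices, sphere.faces[1:])
        assert len(holed.boundary_edges()) == 3
        out = repair_surface(holed, fill_holes=True)
        assert len(out.boundary_edges()) == 0

    def test_large_opening_never_filled(self, coarse_fixture):
        # the outer sheet alone has the big cervical opening
        shell = coarse_fixture.shell
        out = repair_surface(shell, fill_holes=True)
        assert out.n_faces == shell.n_faces  # watertight already: no-op
        sphere = icosphere(5.0, 3)
        cap = sphere.faces[sphere.vertices[sphere.faces].mean(axis=1)[:, 2] < 0.9 * 5]
        opened = TriangulatedSurface(sphere.vertices, cap)
        n_boundary = len(opened.boundary_edges())
        assert n_boundary > 0
        out = repair_surface(opened, fill_holes=True, hole_perimeter=2.0)
        assert len(out.boundary_edges()) == n_boundary

    def test_smoothing_reduces_noise(self):
        sphere = icosphere(1.0, 3)
        rng = np.random.default_rng(0)
        noisy = TriangulatedSurface(
            sphere.vertices + rng.normal(0, 0.01, sphere.vertices.shape), sphere.faces
        )
        before = np.abs(np.linalg.norm(noisy.vertices, axis=1) - 1.0).mean()
        out = repair_surface(noisy, smooth_iterations=10)
        after = np.abs(np.linalg.norm(out.vertices, axis=1) - 1.0).mean()
        assert after < before

    def test_decimation_reaches_target_and_stays_closed(self):
        sphere = icosphere(1.0, 3)
        out = repair_surface(sphere, target_face_count=400)
        assert out.n_faces <= 520  # near target; collapse granularity is 2 faces
        assert out.is_watertight()
        # Hausdorff-style drift: decimated vertices stay near the sphere
        assert np.abs(np.linalg.norm(out.vertices, axis=1) - 1.0).max() < 0.05

    def test_repair_idempotent(self):
        sphere = icosphere(1.0, 2)
        holed = TriangulatedSurface(sphere.vertices, sphere.faces[1:])
        once = repair_surface(holed, fill_holes=True)
        twice = repair_surface(once, fill_holes=True)
        assert once.n_faces == twice.n_faces
        assert np.abs(once.vertices.shape[0] - twice.vertices.shape[0]) == 0

    def test_non_manifold_raises_with_edges(self):
        v = np.array(
            [[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, -1, 0], [2, 0, 0], [0, 2, 0], [0, 0, 2]],
            dtype=float,
        )
        f = np.array(
            [[0, 1, 2], [0, 1, 3], [0, 1, 4], [5, 6, 7]], dtype=np.int64
        )
        with pytest.raises(RepairError) as err:
            repair_surface(TriangulatedSurface(v, f))
        assert len(err.value.offending_edges) >= 1


class TestInvariants:
    def test_validate_rejects_degenerate_face(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 1, 0]], dtype=float)
        f = np.array([[0, 1, 2], [0, 1, 3], [1, 2, 3], [0, 2, 3]], dtype=np.int64)
        with pytest.raises(MeshFormatError):
            TriangulatedSurface(v, f).validate()

    def test_boundary_loops_of_open_sphere(self):
        sphere = icosphere(1.0, 2)
        holed = TriangulatedSurface(sphere.vertices, sphere.faces[1:])
        loops = holed.boundary_loops()
        assert len(loops) == 1
        assert len(loops[0]) == 3
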