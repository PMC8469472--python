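import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracle_utils import shoelace_area

from ado.errors import EllipseFitError
from ado.mesh_io import TriangulatedSurface
from ado.orientation import ToothFrame
from ado.sectioning import SectionSet, cut_surface, fit_ellipse, generate_planes
from ado.synthetic import icosphere


def canonical_frame(origin=(0.0, 0.0, 0.0)):
    return ToothFrame(
        origin=np.asarray(origin, float),
        vertical_axis=np.array([0.0, 0.0, 1.0]),
        mesiodistal_axis=np.array([1.0, 0.0, 0.0]),
        vestibulooral_axis=np.array([0.0, 1.0, 0.0]),
    )


def ellipse_points(a, b, theta=0.0, center=(0.0, 0.0), n=100):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([a * np.cos(t), b * np.sin(t)])
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    return pts @ rot.T + np.asarray(center)


class TestFitEllipse:
    def test_exact_axis_aligned(self):
        e = fit_ellipse(ellipse_points(5.0, 3.0))
        assert abs(e.semi_major - 5.0) < 1e-6
        assert abs(e.semi_minor - 3.0) < 1e-6
        assert abs(abs(e.major_axis_direction[0]) - 1.0) < 1e-6

    def test_circle_tie_break(self):
        e = fit_ellipse(ellipse_points(2.0, 2.0))
        assert abs(e.semi_major - 2.0) < 1e-6
        assert abs(e.semi_minor - 2.0) < 1e-6
        assert np.allclose(e.major_axis_direction, [1.0, 0.0])

    def test_rotated_30_degrees(self):
        theta = np.radians(30.0)
        e = fit_ellipse(ellipse_points(5.0, 3.0, theta=theta, center=(2.0, -1.0)))
        expected = np.array([np.cos(theta), np.sin(theta)])
        err = np.arccos(np.clip(abs(e.major_axis_direction @ expected), -1, 1))
        assert err < 1e-4
        assert np.allclose(e.center, [2.0, -1.0], atol=1e-6)

    def test_too_few_points(self):
        with pytest.raises(EllipseFitError):
            fit_ellipse(ellipse_points(5.0, 3.0)[:4])

    def test_collinear_points(self):
        pts = np.column_stack([np.linspace(0, 1, 20), np.linspace(0, 2, 20)])
        with pytest.raises(EllipseFitError):
            fit_ellipse(pts)

    @settings(max_examples=25, deadline=None)
    @given(
        a=st.floats(1.0, 10.0),
        ratio=st.floats(0.2, 0.95),
        theta=st.floats(0.0, np.pi),
        cx=st.floats(-5.0, 5.0),
        cy=st.floats(-5.0, 5.0),
    )
    def test_recovers_parameters(self, a, ratio, theta, cx, cy):
        b = a * ratio
        e = fit_ellipse(ellipse_points(a, b, theta=theta, center=(cx, cy), n=120))
        assert abs(e.semi_major - a) < 1e-5 * max(1.0, a)
        assert abs(e.semi_minor - b) < 1e-5 * max(1.0, a)
        assert np.allclose(e.center, [cx, cy], atol=1e-5)


class TestGeneratePlanes:
    def test_80_sections_equal_gaps(self, unit_sphere_coarse):
        frame = canonical_frame()
        planes = generate_planes(frame, None, unit_sphere_coarse, 80)
        assert planes.ns == 80
        gaps = np.diff(planes.plane_positions)
        assert len(gaps) == 79
        assert np.allclose(gaps, planes.spacing, atol=1e-9)
        assert abs(abs(planes.plane_normal @ frame.mesiodistal_axis) - 1.0) < 1e-12

    def test_single_plane_at_midpoint(self, unit_sphere_coarse):
        planes = generate_planes(canonical_frame(), None, unit_sphere_coarse, 1)
        proj = unit_sphere_coarse.vertices[:, 0]
        assert abs(planes.plane_positions[0] - (proj.min() + proj.max()) / 2) < 1e-9

    def test_interior_placement(self, unit_sphere_coarse):
        planes = generate_planes(canonical_frame(), None, unit_sphere_coarse, 5)
        proj = unit_sphere_coarse.vertices[:, 0]
        assert planes.plane_positions[0] > proj.min()
        assert planes.plane_positions[-1] < proj.max()

    def test_ns_zero_rejected(self, unit_sphere_coarse):
        with pytest.raises(ValueError):
            generate_planes(canonical_frame(), None, unit_sphere_coarse, 0)

    def test_sectionset_invariants(self):
        with pytest.raises(ValueError):
            SectionSet(3, np.array([0.0, 0.5, 0.7]), np.array([1.0, 0, 0]), 0.5)


class TestCutSurface:
    def test_great_circle(self, unit_sphere):
        planes = generate_planes(canonical_frame(), None, unit_sphere, 1)
        contours = cut_surface(unit_sphere, planes, canonical_frame())
        assert len(contours) == 1
        polys = contours[0].polylines
        assert len(polys) == 1
        p = polys[0]
        assert p.closed
        r = np.linalg.norm(p.points, axis=1)
        # cut points lie on mesh chords, slightly inside the sphere
        assert np.abs(r - 1.0).max() < 1e-3
        assert abs(p.area() - np.pi) / np.pi < 0.005

    def test_plane_missing_mesh(self, unit_sphere_coarse):
        frame = canonical_frame(origin=(10.0, 0.0, 0.0))
        planes = SectionSet(1, np.array([5.0]), np.array([1.0, 0.0, 0.0]), 1.0)
        contours = cut_surface(unit_sphere_coarse, planes, frame)
        assert contours[0].polylines == []

    def test_two_solid_mid_crown_nested(self, coarse_fixture):
        outer, inner = coarse_fixture.outer, coarse_fixture.inner
        combined = TriangulatedSurface(
            np.vstack([outer.vertices, inner.vertices]),
            np.vstack([outer.faces, inner.faces + outer.n_vertices]),
        )
        planes = generate_planes(canonical_frame(), None, combined, 1)
        contours = cut_surface(combined, planes, canonical_frame())
        closed = [p for p in contours[0].polylines if p.closed]
        assert len(closed) == 2
        layers = sorted(p.layer for p in closed)
        assert layers == ["inner", "outer"]

    def test_shell_horizontal_mid_cut_nested_rings(self, coarse_fixture, coarse_spec):
        # horizontal plane at mid-crown: the shell is an annular tube there
        shell = coarse_fixture.shell
        frame = ToothFrame(
            origin=np.array([0.0, 0.0, 2.0]),
            vertical_axis=np.array([1.0, 0.0, 0.0]),
            mesiodistal_axis=np.array([0.0, 0.0, 1.0]),
            vestibulooral_axis=np.array([0.0, -1.0, 0.0]),
        )
        planes = SectionSet(1, np.array([0.0]), np.array([0.0, 0.0, 1.0]), 1.0)
        contours = cut_surface(shell, planes, frame)
        closed = [p for p in contours[0].polylines if p.closed]
        assert len(closed) == 2
        assert sorted(p.layer for p in closed) == ["inner", "outer"]
        a, b = closed[0].points, closed[1].points
        gap = float(np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2).min())
        # wall thickness at mid-crown: the base offset times local boost
        assert gap == pytest.approx(coarse_spec.enamel_thickness, rel=0.35)

    def test_transverse_shell_cut_is_single_band(self, default_fixture, pipeline_result):
        mid = len(pipeline_result.contours) // 2
        polys = pipeline_result.contours[mid].polylines
        assert len([p for p in polys if p.closed]) == 1

    def test_watertight_cut_all_closed(self, pipeline_result):
        for contour in pipeline_result.contours:
            for p in contour.polylines:
                assert p.closed

    def test_deterministic_rerun(self, coarse_fixture):
        shell = coarse_fixture.shell
        planes = generate_planes(canonical_frame(), None, shell, 10)
        c1 = cut_surface(shell, planes, canonical_frame())
        c2 = cut_surface(shell, planes, canonical_frame())
        for s1, s2 in zip(c1, c2):
            assert len(s1.polylines) == len(s2.polylines)
            for p1, p2 in zip(s1.polylines, s2.polylines):
                assert np.array_equal(p1.points, p2.points)

    def test_sphere_cut_area_converges(self):
        # refinement shrinks the cut-area error
        errs = []
        for sub in (2, 3, 4):
            sph = icosphere(1.0, sub)
            planes = generate_planes(canonical_frame(), None, sph, 1)
            poly = cut_surface(sph, planes, canonical_frame())[0].polylines[0]
            errs.append(abs(poly.area() - np.pi))
        assert errs[2] < errs[1] < errs[0]

    def test_polylines_simple(self, pipeline_result):
        for contour in pipeline_result.contours[::8]:
            for p in contour.polylines:
                assert p.is_simple()
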