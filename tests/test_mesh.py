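"""Simplified representations: polyline, double ribbon, tube, mesh I/O."""

import io
import logging
import math

import numpy as np
import pytest
import trimesh

from dnaxis import (TriangleMesh, build_dna, export_mesh, import_mesh,
                    polyline_rep, ribbon_mesh, rmf, tube_mesh, uniform_sample)

from conftest import circle_path_of_length, random_smooth_path, straight_path


def winding_consistent(mesh: TriangleMesh) -> bool:
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                         process=False)
    return bool(tm.is_winding_consistent)


class TestPolyline:
    def test_open_count_and_values(self):
        model = build_dna(straight_path(34.0))
        pts = polyline_rep(model.frames)
        assert len(pts) == len(model.frames) == 11
        np.testing.assert_array_equal(pts, model.frames.origins)

    def test_closed_appends_first_point(self):
        model = build_dna(circle_path_of_length(100.0))
        pts = polyline_rep(model.frames)
        assert len(pts) == len(model.frames) + 1
        np.testing.assert_array_equal(pts[-1], pts[0])

    def test_straight_model_collinear(self):
        model = build_dna(straight_path(68.0))
        pts = polyline_rep(model.frames)
        assert np.abs(pts[:, 1:]).max() < 1e-9


class TestRibbon:
    def test_vertex_count(self):
        model = build_dna(straight_path(170.0))
        mesh = ribbon_mesh(model.frames, model.schedule)
        assert mesh.n_vertices == 2 * len(model.frames) * 2

    def test_edge_azimuth_period_is_pitch(self):
        # on a straight axis the outer edge direction rotates by the twist
        # step; 10.4 steps advance the azimuth by exactly one full turn
        model = build_dna(straight_path(340.0))
        mesh = ribbon_mesh(model.frames, model.schedule)
        n = len(model.frames)
        outer = mesh.vertices[n : 2 * n] - model.frames.origins
        az = np.unwrap(np.arctan2(outer[:, 2], outer[:, 1]))
        step = np.diff(az)
        np.testing.assert_allclose(step, 2 * math.pi / 10.4, atol=1e-9)
        # interpolated azimuth at "pair 11.4" differs from pair 1 by 2 pi
        az_11_4 = az[10] + 0.4 * (az[11] - az[10])
        assert az_11_4 - az[0] == pytest.approx(2 * math.pi, abs=1e-9)

    def test_vertices_within_half_width(self):
        model = build_dna(straight_path(102.0))
        width = 9.0
        mesh = ribbon_mesh(model.frames, model.schedule, width=width)
        d = np.abs(np.linalg.norm(mesh.vertices[:, 1:], axis=1))
        assert d.max() <= width / 2 + 1e-9

    def test_unwinding_straightens_ribbon_region(self):
        # zero net twist between pairs 10 and 20: the outer edge azimuth at
        # both pairs coincides, making the local unwinding visible
        cons = {10: 0.0, 20: -(10) * 2 * math.pi / 10.4}
        model = build_dna(straight_path(102.0), cons)
        mesh = ribbon_mesh(model.frames, model.schedule)
        n = len(model.frames)
        outer = mesh.vertices[n : 2 * n] - model.frames.origins
        az = np.arctan2(outer[:, 2], outer[:, 1])
        assert math.cos(az[19] - az[9]) == pytest.approx(1.0, abs=1e-9)

    def test_winding_consistent_and_nondegenerate(self, rng):
        model = build_dna(random_smooth_path(rng))
        mesh = ribbon_mesh(model.frames, model.schedule)
        assert winding_consistent(mesh)
        assert mesh.areas().min() > 1e-12

    def test_subdivided_sections(self):
        model = build_dna(straight_path(34.0))
        mesh = ribbon_mesh(model.frames, model.schedule, sides_per_bp=4)
        n = len(model.frames)
        assert mesh.n_vertices == 2 * 2 * ((n - 1) * 4 + 1)


class TestTube:
    def test_straight_tube_ring_radius_exact(self):
        mesh = tube_mesh(straight_path(34.0), radius=5.0)
        ring_vertices = mesh.vertices[:-2]  # caps excluded
        r = np.linalg.norm(ring_vertices[:, 1:], axis=1)
        np.testing.assert_allclose(r, 5.0, atol=1e-9)

    def test_open_vertex_count(self):
        path = straight_path(34.0)
        sides = 12
        mesh = tube_mesh(path, radius=3.0, sides=sides)
        rings = len(uniform_sample(path, 3.4))
        assert mesh.n_vertices == rings * sides + 2

    def test_closed_tube_is_a_torus(self):
        mesh = tube_mesh(circle_path_of_length(150.0), radius=4.0)
        v = mesh.n_vertices
        f = mesh.n_triangles
        edges = {
            frozenset(e)
            for tri in mesh.triangles
            for e in ((tri[0], tri[1]), (tri[1], tri[2]), (tri[2], tri[0]))
        }
        assert v - len(edges) + f == 0  # Euler characteristic of a torus
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                             process=False)
        assert tm.is_winding_consistent
        assert tm.is_watertight

    def test_open_tube_watertight_with_caps(self):
        mesh = tube_mesh(straight_path(34.0), radius=3.0)
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                             process=False)
        assert tm.is_watertight
        assert tm.is_winding_consistent

    def test_rigid_equivariance(self, rng):
        path = random_smooth_path(rng)
        mesh = tube_mesh(path, radius=3.0)
        shift = np.array([10.0, -20.0, 5.0])
        shifted = type(path)(
            [type(s)(s.control_points + shift) for s in path.segments]
        )
        mesh2 = tube_mesh(shifted, radius=3.0)
        np.testing.assert_allclose(mesh2.vertices, mesh.vertices + shift,
                                   atol=1e-6)


class TestMeshIO:
    def triangle(self, colors=None):
        return TriangleMesh(
            vertices=[[0, 0, 0], [1, 0, 0], [0, 1, 0]],
            triangles=[[0, 1, 2]],
            colors=colors,
        )

    @pytest.mark.parametrize("fmt", ["obj", "vrml"])
    def test_single_triangle_round_trip(self, fmt):
        buf = io.StringIO()
        export_mesh(self.triangle(), buf, format=fmt)
        back = import_mesh(buf.getvalue(), format=fmt)
        assert back.n_vertices == 3 and back.n_triangles == 1
        np.testing.assert_allclose(back.vertices, self.triangle().vertices,
                                   atol=1e-6)

    def test_tube_obj_vertex_count_round_trip(self):
        mesh = tube_mesh(straight_path(34.0), radius=3.0)
        buf = io.StringIO()
        export_mesh(mesh, buf, format="obj")
        back = import_mesh(buf.getvalue(), format="obj")
        assert back.n_vertices == mesh.n_vertices
        assert back.n_triangles == mesh.n_triangles

    def test_vrml_carries_per_vertex_color(self):
        colors = [[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]
        buf = io.StringIO()
        export_mesh(self.triangle(colors), buf, format="vrml")
        text = buf.getvalue()
        assert "colorPerVertex TRUE" in text and "Color" in text
        back = import_mesh(text, format="vrml")
        np.testing.assert_allclose(back.colors, colors, atol=1e-4)

    def test_obj_drops_colors_with_warning(self, caplog):
        buf = io.StringIO()
        with caplog.at_level(logging.WARNING, logger="dnaxis.mesh"):
            export_mesh(self.triangle([[1, 0, 0]] * 3), buf, format="obj")
        assert "color" in caplog.text.lower()
        assert import_mesh(buf.getvalue(), format="obj").colors is None
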