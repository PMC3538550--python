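"""Shared fixtures: canonical axis-curve geometries and frame-twist helpers."""

import math

import numpy as np
import pytest

from dnaxis import BezierSegment, CurvePath, interpolate_points

#: cubic Bézier tangent-handle factor for a quarter-circle arc
CIRCLE_K = 4.0 / 3.0 * math.tan(math.pi / 8.0)


def circle_path(radius: float, plane: str = "xy", closed: bool = True) -> CurvePath:
    """Circle approximated by four cubic arcs (radial error < 3e-4 relative)."""

    def embed(c, s):
        if plane == "xy":
            return np.array([c, s, 0.0])
        if plane == "xz":
            return np.array([c, 0.0, s])
        raise ValueError(plane)

    segs = []
    for q in range(4):
        a0, a1 = q * math.pi / 2, (q + 1) * math.pi / 2
        p0 = embed(math.cos(a0), math.sin(a0)) * radius
        p3 = embed(math.cos(a1), math.sin(a1)) * radius
        t0 = embed(-math.sin(a0), math.cos(a0))
        t1 = embed(-math.sin(a1), math.cos(a1))
        segs.append(
            BezierSegment(
                np.array([p0, p0 + CIRCLE_K * radius * t0,
                          p3 - CIRCLE_K * radius * t1, p3])
            )
        )
    return CurvePath(segs, closed=closed)


def circle_path_of_length(length: float, plane: str = "xy") -> CurvePath:
    """Closed circle-like path rescaled to an exact arc length."""
    base = circle_path(1.0, plane=plane)
    scale = length / base.arc_length()
    return CurvePath(
        [BezierSegment(s.control_points * scale) for s in base.segments],
        closed=True,
    )


def straight_path(length: float) -> CurvePath:
    return CurvePath(
        [BezierSegment([[0.0, 0.0, 0.0], [length / 3, 0, 0],
                        [2 * length / 3, 0, 0], [length, 0, 0]])]
    )


def helix_path(n: int = 80, radius: float = 50.0, pitch: float = 100.0,
               turns: float = 2.0) -> CurvePath:
    """Gently curved helical axis (curvature radius ≫ base-pair rise)."""
    t = np.linspace(0.0, 2 * math.pi * turns, n)
    pts = np.column_stack(
        [radius * np.cos(t), radius * np.sin(t), pitch * t / (2 * math.pi)]
    )
    return interpolate_points(pts)


def random_smooth_path(rng: np.random.Generator, n_beads: int = 8,
                       step: float = 25.0) -> CurvePath:
    """Random smooth open curve: interpolated correlated random walk."""
    directions = rng.normal(size=(n_beads, 3))
    directions[0] = [1.0, 0.0, 0.0]
    for i in range(1, n_beads):
        directions[i] = directions[i - 1] + 0.7 * directions[i]
        directions[i] /= np.linalg.norm(directions[i])
    pts = np.vstack([[0, 0, 0], np.cumsum(directions * step, axis=0)])
    return interpolate_points(pts)


def total_frame_twist_deg(fr) -> float:
    """Accumulated rotation of the normal about the tangent, measured
    against exact single-rotation parallel transport between samples."""
    tw = 0.0
    for i in range(len(fr) - 1):
        t0, t1 = fr.tangents[i], fr.tangents[i + 1]
        n0, n1 = fr.normals[i], fr.normals[i + 1]
        axis = np.cross(t0, t1)
        s = np.linalg.norm(axis)
        if s < 1e-15:
            ptn = n0
        else:
            axis = axis / s
            ang = math.atan2(s, float(np.dot(t0, t1)))
            ptn = (n0 * math.cos(ang) + np.cross(axis, n0) * math.sin(ang)
                   + axis * float(np.dot(axis, n0)) * (1 - math.cos(ang)))
        tw += math.degrees(
            math.atan2(float(np.dot(np.cross(ptn, n1), t1)),
                       float(np.dot(ptn, n1)))
        )
    return tw


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
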