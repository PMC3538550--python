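"""Curve representation, evaluation, arc length and the two samplings."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dnaxis import (BezierSegment, CurvePath, CurveTooShortError,
                    DegenerateCurveError, InputError, adaptive_sample,
                    arc_length, eval_point, eval_tangent, interpolate_points,
                    uniform_sample)

from conftest import circle_path, circle_path_of_length, random_smooth_path, \
    straight_path


def straight_cubic():
    return CurvePath([BezierSegment([[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0]])])


def quadratic_arch():
    return CurvePath([BezierSegment([[0, 0, 0], [1, 1, 0], [2, 0, 0]])])


class TestEvaluation:
    @pytest.mark.parametrize(
        "path_fn,u,expected",
        [
            (straight_cubic, 0.5, [15, 0, 0]),
            (quadratic_arch, 0.5, [1, 0.5, 0]),   # (P0 + 2 P1 + P2) / 4
            (straight_cubic, 0.0, [0, 0, 0]),
            (straight_cubic, 1.0, [30, 0, 0]),
            (quadratic_arch, 0.0, [0, 0, 0]),
        ],
    )
    def test_point_closed_forms(self, path_fn, u, expected):
        np.testing.assert_allclose(eval_point(path_fn(), u), expected, atol=1e-12)

    def test_point_outside_domain_rejected(self):
        with pytest.raises(InputError):
            eval_point(straight_cubic(), 1.5)
        with pytest.raises(InputError):
            eval_point(straight_cubic(), -0.1)

    @pytest.mark.parametrize(
        "path_fn,u,expected",
        [
            (straight_cubic, 0.3, [1, 0, 0]),
            (quadratic_arch, 0.5, [1, 0, 0]),  # symmetric arch apex
        ],
    )
    def test_tangent_closed_forms(self, path_fn, u, expected):
        np.testing.assert_allclose(eval_tangent(path_fn(), u), expected, atol=1e-12)

    def test_tangent_at_end_is_last_control_leg(self):
        path = CurvePath(
            [BezierSegment([[0, 0, 0], [5, 5, 0], [10, 5, 0], [13, 9, 0]])]
        )
        expected = np.array([3.0, 4.0, 0.0]) / 5.0
        np.testing.assert_allclose(eval_tangent(path, 1.0), expected, atol=1e-12)

    def test_degenerate_tangent_raises_with_segment(self):
        path = CurvePath([BezierSegment([[1, 2, 3]] * 4)])
        with pytest.raises(DegenerateCurveError, match="segment 0"):
            eval_tangent(path, 0.5)

    def test_multisegment_junction_continuity_enforced(self):
        with pytest.raises(InputError, match="junction"):
            CurvePath(
                [
                    BezierSegment([[0, 0, 0], [1, 0, 0], [2, 0, 0]]),
                    BezierSegment([[5, 0, 0], [6, 0, 0], [7, 0, 0]]),
                ]
            )


class TestArcLength:
    def test_straight_cubic(self):
        assert arc_length(straight_cubic()) == pytest.approx(30.0, rel=1e-9)

    def test_quarter_circle_matches_chord_sum_oracle(self):
        path = circle_path(10.0, closed=False)
        path = CurvePath(path.segments[:1])  # one quarter arc
        ts = np.linspace(0.0, 1.0, 100_001)
        pts = path.segments[0].point(ts)
        oracle = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
        assert arc_length(path) == pytest.approx(oracle, rel=1e-4)

    def test_degenerate_path_has_zero_length(self):
        path = CurvePath([BezierSegment([[1, 1, 1]] * 4)])
        assert arc_length(path) == 0.0


class TestAdaptiveSampling:
    def test_straight_path_gives_two_points(self):
        s = adaptive_sample(straight_cubic(), 5.0)
        assert len(s.points) == 2
        np.testing.assert_allclose(s.points[0], [0, 0, 0])
        np.testing.assert_allclose(s.points[-1], [30, 0, 0])

    def test_closed_circle_respects_threshold(self):
        path = circle_path(50.0)
        s = adaptive_sample(path, 5.0)
        pts = s.points
        chords = np.diff(pts, axis=0)
        chords = np.vstack([chords, pts[1] - pts[0]])  # wrap (ends coincide)
        for i in range(1, len(chords)):
            c = np.dot(chords[i - 1], chords[i])
            c /= np.linalg.norm(chords[i - 1]) * np.linalg.norm(chords[i])
            assert math.degrees(math.acos(np.clip(c, -1, 1))) <= 5.0 + 1e-9

    def test_points_lie_on_curve(self):
        path = circle_path(50.0)
        s = adaptive_sample(path, 10.0)
        for u, p in zip(s.params, s.points):
            np.testing.assert_allclose(p, path.point(u), atol=1e-12)

    def test_halving_threshold_never_coarsens(self, rng):
        path = random_smooth_path(rng)
        n_prev = None
        for thr in (20.0, 10.0, 5.0, 2.5):
            n = len(adaptive_sample(path, thr).points)
            if n_prev is not None:
                assert n >= n_prev
            n_prev = n


class TestUniformSampling:
    def test_straight_34A_gives_11_samples(self):
        path = straight_path(34.0)
        s = uniform_sample(path, 3.4)
        assert len(s) == 11
        np.testing.assert_allclose(s.points[:, 0], 3.4 * np.arange(11), atol=1e-9)
        np.testing.assert_allclose(s.tangents, [[1, 0, 0]] * 11, atol=1e-12)

    def test_open_remainder_dropped(self):
        s = uniform_sample(straight_path(35.5), 3.4)
        assert len(s) == 11  # 34.0 covered, 1.5 Å remainder dropped
        assert s.arc_lengths[-1] == pytest.approx(34.0)

    def test_gap_uniformity_on_random_smooth_paths(self, rng):
        for _ in range(20):
            path = random_smooth_path(rng)
            s = uniform_sample(path, 3.4)
            gaps = np.diff(s.arc_lengths)
            assert np.abs(gaps - s.spacing).max() <= 1e-3
            assert gaps.std() <= 1e-3
            # arc-length positions really sit on the curve: chord <= arc gap
            chords = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
            assert np.all(chords <= s.spacing + 1e-9)

    def test_closed_100A_circle(self):
        path = circle_path_of_length(100.0)
        s = uniform_sample(path, 3.4)
        assert len(s) == 29  # round(100 / 3.4)
        assert s.spacing == pytest.approx(100.0 / 29, rel=1e-9)
        # the sampling closes: one more spacing lands back on the start
        wrap_gap = np.linalg.norm(
            path.points_at_params(path.params_at_arclength([29 * s.spacing]))[0]
            - s.points[0]
        )
        assert wrap_gap < 1e-3

    def test_too_short_curve_rejected(self):
        with pytest.raises(CurveTooShortError):
            uniform_sample(straight_path(2.0), 3.4)


class TestInterpolation:
    def test_two_points_gives_straight_segment(self):
        path = interpolate_points([[0, 0, 0], [10, 0, 0]])
        us = np.linspace(0, 1, 17)
        pts = path.points_at_params(us)
        np.testing.assert_allclose(pts[:, 1:], 0.0, atol=1e-12)
        np.testing.assert_allclose(pts[:, 0], 10 * us, atol=1e-9)

    def test_passes_through_all_beads(self, rng):
        pts = np.cumsum(rng.normal(0, 5, size=(10, 3)), axis=0)
        path = interpolate_points(pts)
        for i, p in enumerate(pts):
            np.testing.assert_allclose(path.point(i / 9), p, atol=1e-9)

    def test_closed_loop_passes_through_and_closes(self, rng):
        t = np.linspace(0, 2 * np.pi, 9)[:-1]
        pts = np.column_stack([np.cos(t), np.sin(t), 0 * t]) * 40
        path = interpolate_points(pts, closed=True)
        assert path.closed
        for i, p in enumerate(pts):
            np.testing.assert_allclose(path.point(i / len(pts)), p, atol=1e-9)

    def test_collinear_beads_stay_collinear(self):
        pts = np.outer(np.array([0, 1.0, 2.5, 4.0, 7.0]), [1, 2, 3])
        path = interpolate_points(pts)
        samples = path.points_at_params(np.linspace(0, 1, 50))
        d = np.array([1, 2, 3]) / np.linalg.norm([1, 2, 3])
        off = samples - np.outer(samples @ d, d)
        assert np.abs(off).max() < 1e-9

    @pytest.mark.parametrize("bad", [
        [[0, 0, 0]],
        [[0, 0, 0], [0, 0, 0], [1, 1, 1]],
    ])
    def test_invalid_inputs_rejected(self, bad):
        with pytest.raises(InputError):
            interpolate_points(bad)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rigid_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.cumsum(rng.normal(0, 5, size=(6, 3)), axis=0)
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ])
        shift = rng.normal(0, 50, size=3)
        a = interpolate_points(pts)
        b = interpolate_points(pts @ rot.T + shift)
        us = np.linspace(0, 1, 23)
        np.testing.assert_allclose(
            b.points_at_params(us), a.points_at_params(us) @ rot.T + shift,
            atol=1e-9,
        )
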