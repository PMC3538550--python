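"""Piecewise Bézier axis curves and their samplings.

The DNA double helix is modeled around a smooth space curve (the helical
axis) represented as a chain of quadratic or cubic Bézier segments, open or
closed.  Two samplings of the curve are used downstream:

* an *adaptive* sampling — a polyline whose consecutive chords turn by at
  most a user threshold, for lightweight display of the axis;
* a *uniform* (arc-length) sampling with a spacing of one helical rise
  (3.4 Å by default), whose points anchor the base pairs.

Coarse-grained bead sequences (one point per monomer) are promoted to a
smooth interpolating piecewise-cubic curve with a centripetal Catmull–Rom
construction, so simulation output can be rebuilt at atomic resolution.

All coordinates are in Ångström.  The global curve parameter ``u`` runs in
[0, 1], split uniformly across segments; arc-length queries go through
per-segment cumulative length tables inverted by Newton iteration with a
bisection-grade bracket (tolerance well below 1e-6 Å).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.integrate import quad

from .errors import CurveTooShortError, DegenerateCurveError, InputError

__all__ = [
    "BezierSegment",
    "CurvePath",
    "AdaptiveSampling",
    "UniformSampling",
    "eval_point",
    "eval_tangent",
    "arc_length",
    "adaptive_sample",
    "uniform_sample",
    "interpolate_points",
]

# Gauss–Legendre nodes reused by the arc-length tables.
_GL_X, _GL_W = leggauss(8)

#: Default helical rise between base pairs (Å).
DEFAULT_SPACING = 3.4

#: Default adaptive-sampling turn-angle threshold (degrees).
DEFAULT_MAX_TURN_DEG = 5.0


@dataclass(frozen=True)
class BezierSegment:
    """One quadratic (3 control points) or cubic (4) Bézier segment."""

    control_points: np.ndarray

    def __post_init__(self) -> None:
        cp = np.asarray(self.control_points, dtype=float)
        if cp.ndim != 2 or cp.shape[1] != 3 or cp.shape[0] not in (3, 4):
            raise InputError(
                "a Bézier segment needs 3 (quadratic) or 4 (cubic) 3D control "
                f"points, got array of shape {cp.shape}"
            )
        if not np.all(np.isfinite(cp)):
            raise InputError("control points must be finite")
        object.__setattr__(self, "control_points", cp)

    @property
    def degree(self) -> int:
        return self.control_points.shape[0] - 1

    def point(self, t):
        """De Casteljau evaluation at local parameter(s) ``t`` in [0, 1]."""
        t = np.asarray(t, dtype=float)
        levels = [np.broadcast_to(p, t.shape + (3,)) for p in self.control_points]
        tt = t[..., None]
        while len(levels) > 1:
            levels = [
                (1.0 - tt) * a + tt * b for a, b in zip(levels[:-1], levels[1:])
            ]
        return levels[0]

    def derivative(self, t):
        """d/dt of the segment at local parameter(s) ``t``."""
        t = np.asarray(t, dtype=float)
        cp = self.control_points
        n = self.degree
        diffs = n * (cp[1:] - cp[:-1])
        levels = [np.broadcast_to(d, t.shape + (3,)) for d in diffs]
        tt = t[..., None]
        while len(levels) > 1:
            levels = [
                (1.0 - tt) * a + tt * b for a, b in zip(levels[:-1], levels[1:])
            ]
        return levels[0]

    def speed(self, t):
        return np.linalg.norm(self.derivative(t), axis=-1)


class CurvePath:
    """A positionally continuous chain of Bézier segments, open or closed."""

    def __init__(self, segments: Sequence[BezierSegment], closed: bool = False):
        segments = [
            s if isinstance(s, BezierSegment) else BezierSegment(s) for s in segments
        ]
        if not segments:
            raise InputError("a curve path needs at least one segment")
        for k in range(len(segments) - 1):
            a = segments[k].control_points[-1]
            b = segments[k + 1].control_points[0]
            if np.linalg.norm(a - b) > 1e-6:
                raise InputError(
                    f"segments {k} and {k + 1} do not share their junction "
                    f"control point ({a} vs {b})"
                )
        if closed:
            a = segments[-1].control_points[-1]
            b = segments[0].control_points[0]
            if np.linalg.norm(a - b) > 1e-6:
                raise InputError(
                    "closed path: last segment must end at the first segment's start"
                )
        self.segments = tuple(segments)
        self.closed = bool(closed)
        self._tables = None  # lazy per-segment arc-length tables

    # ---- parameterization ------------------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def _locate(self, u: float) -> tuple[int, float]:
        if not (0.0 <= u <= 1.0):
            raise InputError(f"curve parameter u={u} outside [0, 1]")
        scaled = u * self.n_segments
        idx = min(int(scaled), self.n_segments - 1)
        return idx, scaled - idx

    def point(self, u: float) -> np.ndarray:
        idx, t = self._locate(float(u))
        return self.segments[idx].point(t)

    def tangent(self, u: float) -> np.ndarray:
        idx, t = self._locate(float(u))
        seg = self.segments[idx]
        d = seg.derivative(t)
        norm = np.linalg.norm(d)
        if norm < 1e-12:
            # coincident control points: symmetric finite difference in u
            h = 1e-6
            lo, hi = max(t - h, 0.0), min(t + h, 1.0)
            d = seg.point(hi) - seg.point(lo)
            norm = np.linalg.norm(d)
            if norm < 1e-12:
                raise DegenerateCurveError(
                    f"tangent undefined on segment {idx} at local t={t:.6f} "
                    "(coincident control points)"
                )
        return d / norm

    # ---- arc length ------------------------------------------------------

    def _build_tables(self) -> None:
        """Cumulative arc-length tables: 64 panels per segment, GL-8 each."""
        panels = 64
        edges = np.linspace(0.0, 1.0, panels + 1)
        mid = 0.5 * (edges[:-1] + edges[1:])
        half = 0.5 * (edges[1:] - edges[:-1])
        tables = []
        total = 0.0
        seg_cum = [0.0]
        for seg in self.segments:
            nodes = mid[:, None] + half[:, None] * _GL_X[None, :]
            speeds = seg.speed(nodes)
            panel_len = half * (speeds * _GL_W[None, :]).sum(axis=1)
            cum = np.concatenate([[0.0], np.cumsum(panel_len)])
            tables.append((edges, cum))
            total += cum[-1]
            seg_cum.append(total)
        self._tables = (tables, np.asarray(seg_cum))

    def _ensure_tables(self):
        if self._tables is None:
            self._build_tables()
        return self._tables

    def arc_length(self) -> float:
        """Total arc length by adaptive quadrature (relative tol ≤ 1e-9)."""
        total = 0.0
        for seg in self.segments:
            if np.allclose(seg.control_points, seg.control_points[0]):
                continue  # zero-length segment; quad would churn on it
            val, _ = quad(lambda t, s=seg: float(s.speed(t)), 0.0, 1.0,
                          epsabs=1e-10, epsrel=1e-9, limit=200)
            total += val
        return total

    def _segment_arclength(self, idx: int, t) -> np.ndarray:
        """Arc length from segment start to local parameter(s) t (vectorized)."""
        tables, _ = self._ensure_tables()
        edges, cum = tables[idx]
        seg = self.segments[idx]
        t = np.asarray(t, dtype=float)
        j = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
        a = edges[j]
        mid = 0.5 * (a + t)
        half = 0.5 * (t - a)
        nodes = mid[..., None] + half[..., None] * _GL_X
        partial = half * (seg.speed(nodes) * _GL_W).sum(axis=-1)
        return cum[j] + partial

    def params_at_arclength(self, s_values) -> np.ndarray:
        """Invert arc length → global parameter u, vectorized over targets.

        Newton iteration seeded from the panel tables; each target stays
        bracketed inside its panel, so four iterations reach ~1e-12 Å.
        """
        tables, seg_cum = self._ensure_tables()
        s_values = np.atleast_1d(np.asarray(s_values, dtype=float))
        total = seg_cum[-1]
        s_clip = np.clip(s_values, 0.0, total)
        out = np.empty_like(s_clip)
        seg_idx = np.clip(
            np.searchsorted(seg_cum, s_clip, side="right") - 1, 0, self.n_segments - 1
        )
        for idx in range(self.n_segments):
            mask = seg_idx == idx
            if not mask.any():
                continue
            seg = self.segments[idx]
            edges, cum = tables[idx]
            local_s = s_clip[mask] - seg_cum[idx]
            local_s = np.clip(local_s, 0.0, cum[-1])
            j = np.clip(np.searchsorted(cum, local_s, side="right") - 1,
                        0, len(cum) - 2)
            # linear seed within the panel, then Newton on the true integral
            denom = np.where(cum[j + 1] > cum[j], cum[j + 1] - cum[j], 1.0)
            t = edges[j] + (edges[j + 1] - edges[j]) * (local_s - cum[j]) / denom
            lo, hi = edges[j], edges[j + 1]
            for _ in range(5):
                f = self._segment_arclength(idx, t) - local_s
                sp = np.maximum(seg.speed(t), 1e-12)
                t = np.clip(t - f / sp, lo, hi)
            out[mask] = (idx + t) / self.n_segments
        return out

    def points_at_params(self, us) -> np.ndarray:
        """Vectorized :meth:`point` over an array of global parameters."""
        return self._eval_many(us, "point")

    def tangents_at_params(self, us) -> np.ndarray:
        """Vectorized unit tangents over an array of global parameters."""
        d = self._eval_many(us, "derivative")
        norms = np.linalg.norm(d, axis=-1, keepdims=True)
        small = norms[:, 0] < 1e-12
        if small.any():
            us = np.atleast_1d(np.asarray(us, dtype=float))
            for k in np.flatnonzero(small):
                d[k] = self.tangent(us[k])  # degenerate fallback, may raise
                norms[k] = 1.0
        return d / norms

    def _eval_many(self, us, which: str) -> np.ndarray:
        us = np.atleast_1d(np.asarray(us, dtype=float))
        if us.size and (us.min() < 0.0 or us.max() > 1.0):
            raise InputError("curve parameters must lie in [0, 1]")
        scaled = us * self.n_segments
        idx = np.minimum(scaled.astype(int), self.n_segments - 1)
        t = scaled - idx
        out = np.empty((len(us), 3))
        for k in range(self.n_segments):
            mask = idx == k
            if mask.any():
                out[mask] = getattr(self.segments[k], which)(t[mask])
        return out


@dataclass(frozen=True)
class AdaptiveSampling:
    """Polyline on the curve whose consecutive chords turn by ≤ max_turn_deg."""

    points: np.ndarray
    params: np.ndarray
    max_turn_deg: float
    closed: bool = False


@dataclass(frozen=True)
class UniformSampling:
    """Equal-arc-length samples o_i with unit tangents t_i.

    ``spacing`` is the realized spacing: the requested one on open curves,
    and L / round(L / requested) on closed curves so the sampling closes
    exactly.
    """

    points: np.ndarray
    tangents: np.ndarray
    arc_lengths: np.ndarray
    spacing: float
    closed: bool = False

    def __len__(self) -> int:
        return len(self.points)


# --------------------------------------------------------------------------
# module-level operations
# --------------------------------------------------------------------------

def eval_point(path: CurvePath, u: float) -> np.ndarray:
    """Point on the path at global parameter ``u`` in [0, 1]."""
    return path.point(u)


def eval_tangent(path: CurvePath, u: float) -> np.ndarray:
    """Unit tangent at global parameter ``u``, in the direction of increasing u."""
    return path.tangent(u)


def arc_length(path: CurvePath) -> float:
    """Total arc length of the path in Å."""
    return path.arc_length()


def _turn_angle(v1: np.ndarray, v2: np.ndarray) -> float:
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 < 1e-15 or n2 < 1e-15:
        return 0.0
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def adaptive_sample(
    path: CurvePath, max_turn_deg: float = DEFAULT_MAX_TURN_DEG
) -> AdaptiveSampling:
    """Polyline approximation with bounded turning between consecutive chords.

    Parameter intervals are subdivided while the tangent swings across an
    interval by more than half the threshold; a verification pass then
    bisects around any vertex whose measured chord-to-chord angle still
    exceeds the threshold, so the output invariant holds exactly.
    """
    if max_turn_deg <= 0:
        raise InputError("max_turn_deg must be positive")

    nseg = path.n_segments
    params: list[float] = []

    def refine(u1: float, u2: float, depth: int) -> None:
        m = 0.5 * (u1 + u2)
        if depth < 30:
            t1 = path.tangent(u1)
            tm = path.tangent(m)
            t2 = path.tangent(u2)
            swing = _turn_angle(t1, tm) + _turn_angle(tm, t2)
            if swing > 0.5 * max_turn_deg:
                refine(u1, m, depth + 1)
                refine(m, u2, depth + 1)
                return
        params.append(u2)

    params.append(0.0)
    for k in range(nseg):
        refine(k / nseg, (k + 1) / nseg, 0)

    # verification pass on actual chord angles (wraps across the seam when closed)
    for _ in range(40):
        params = sorted(set(params))
        pts = np.array([path.point(u) for u in params])
        # for closed paths params span 0..1 with coincident endpoints, so the
        # seam turning is the angle between the last and first chords
        chords = list(np.diff(pts, axis=0))
        bad = None
        for i in range(1, len(chords)):
            if _turn_angle(chords[i - 1], chords[i]) > max_turn_deg:
                bad = i  # offending vertex sits between chords i-1 and i
                break
        if bad is not None:
            lo = params[bad - 1]
            hi = params[bad + 1] if bad + 1 < len(params) else 1.0
            params.extend([0.5 * (lo + params[bad]), 0.5 * (params[bad] + hi)])
            continue
        if (
            path.closed
            and len(chords) > 1
            and _turn_angle(chords[-1], chords[0]) > max_turn_deg
        ):
            # seam start vertex: split the first and last parameter intervals
            params.extend(
                [0.5 * (params[0] + params[1]), 0.5 * (params[-1] + 1.0)]
            )
            continue
        break

    params_arr = np.asarray(sorted(set(params)))
    pts = np.array([path.point(u) for u in params_arr])
    return AdaptiveSampling(
        points=pts, params=params_arr, max_turn_deg=max_turn_deg, closed=path.closed
    )


def uniform_sample(path: CurvePath, spacing: float = DEFAULT_SPACING) -> UniformSampling:
    """Arc-length-uniform samples with unit tangents.

    Open curves: samples at 0, s, 2s, …; a trailing remainder shorter than
    one spacing is dropped.  Closed curves: the spacing is adjusted to
    L / round(L / spacing) so the sampling closes exactly (the last sample
    is one adjusted spacing before the start, which is not repeated).
    """
    if spacing <= 0:
        raise InputError("spacing must be positive")
    L = path.arc_length()
    if path.closed:
        if L < 2 * spacing:
            raise CurveTooShortError(
                f"closed curve of length {L:.3f} Å is shorter than two spacings"
            )
        n = int(round(L / spacing))
        s = L / n
        targets = s * np.arange(n)
    else:
        if L < spacing:
            raise CurveTooShortError(
                f"curve of length {L:.3f} Å is shorter than one spacing "
                f"({spacing} Å)"
            )
        n = int(np.floor(L / spacing + 1e-6))
        s = spacing
        targets = np.minimum(s * np.arange(n + 1), L)
    us = path.params_at_arclength(targets)
    pts = path.points_at_params(us)
    tans = path.tangents_at_params(us)
    return UniformSampling(
        points=pts, tangents=tans, arc_lengths=targets, spacing=float(s),
        closed=path.closed,
    )


def interpolate_points(points, closed: bool = False) -> CurvePath:
    """Smooth piecewise-cubic curve through an ordered bead sequence.

    Centripetal Catmull–Rom construction: knot increments are the square
    roots of the chord lengths, which avoids cusps and self-intersections on
    unevenly spaced beads; each span is emitted as a cubic Bézier segment,
    so the result plugs into the rest of the pipeline unchanged.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError("expected an (n, 3) array of points")
    if len(pts) < 2:
        raise InputError("need at least 2 points to interpolate")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg < 1e-9):
        raise InputError("consecutive duplicate points in bead sequence")
    if closed and np.linalg.norm(pts[0] - pts[-1]) < 1e-9:
        pts = pts[:-1]
        if len(pts) < 2:
            raise InputError("need at least 2 distinct points to interpolate")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)

    n = len(pts)
    if closed:
        dt = np.sqrt(np.concatenate([seg, [np.linalg.norm(pts[0] - pts[-1])]]))
        if dt[-1] < 1e-9:
            raise InputError("closed bead loop: first and last points coincide")
        tangents = np.empty_like(pts)
        for i in range(n):
            dt_prev = dt[(i - 1) % n]
            dt_next = dt[i]
            p_prev, p_next = pts[(i - 1) % n], pts[(i + 1) % n]
            tangents[i] = (
                (pts[i] - p_prev) / dt_prev * dt_next
                + (p_next - pts[i]) / dt_next * dt_prev
            ) / (dt_prev + dt_next)
        spans = [(i, (i + 1) % n) for i in range(n)]
        span_dt = dt
    else:
        dt = np.sqrt(seg)
        tangents = np.empty_like(pts)
        tangents[0] = (pts[1] - pts[0]) / dt[0]
        tangents[-1] = (pts[-1] - pts[-2]) / dt[-1]
        for i in range(1, n - 1):
            tangents[i] = (
                (pts[i] - pts[i - 1]) / dt[i - 1] * dt[i]
                + (pts[i + 1] - pts[i]) / dt[i] * dt[i - 1]
            ) / (dt[i - 1] + dt[i])
        spans = [(i, i + 1) for i in range(n - 1)]
        span_dt = dt

    segments = []
    for k, (i, j) in enumerate(spans):
        h = span_dt[k]
        b0 = pts[i]
        b3 = pts[j]
        b1 = pts[i] + tangents[i] * h / 3.0
        b2 = pts[j] - tangents[j] * h / 3.0
        segments.append(BezierSegment(np.array([b0, b1, b2, b3])))
    return CurvePath(segments, closed=closed)
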