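"""Bounding-sphere hierarchy over the frame sequence: LoD and picking.

A binary tree is built over the base-pair anchor points: each node covers a
contiguous index range, splits it into two halves of equal length (±1), and
stores a sphere bounding the anchors of its range (centroid center, exact
max-distance radius).  Splitting stops at about ten base pairs per leaf.

The tree serves two queries:

* :func:`classify_lod` — choose a display representation per range from the
  viewer distance: beyond ``far`` a simple line, beyond ``near`` a double
  ribbon, otherwise atomic.  The decision rule is defined per *leaf*
  sphere; internal nodes carry conservative bounds on their descendant
  leaves' sphere distances, so the traversal prunes whole subtrees exactly
  when every leaf below classifies identically.
* :func:`pick_base_pair` — which base pair a ray hits, pruning subtrees
  whose sphere (inflated by the hit radius) the ray misses.

Indices are 1-based to match base-pair numbering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InputError

__all__ = ["HierarchyNode", "build_hierarchy", "classify_lod", "pick_base_pair",
           "LEAF_SIZE"]

#: "about ten base pairs": split while a node holds more than this many
LEAF_SIZE = 10

ATOMIC, RIBBON, LINE = "atomic", "ribbon", "line"

#: default viewer-distance thresholds (Å) between representations
DEFAULT_NEAR = 500.0
DEFAULT_FAR = 5000.0


@dataclass
class HierarchyNode:
    """Node over anchor indices [lo, hi] (1-based, inclusive)."""

    lo: int
    hi: int
    center: np.ndarray
    radius: float
    left: Optional["HierarchyNode"] = None
    right: Optional["HierarchyNode"] = None
    # conservative bounds over descendant leaf spheres (center distance ± radius)
    leaf_reach_hi: float = 0.0   # max over leaves of |C - Cl| + Rl
    leaf_reach_lo: float = 0.0   # max over leaves of |C - Cl| - Rl
    _points: np.ndarray = field(default=None, repr=False)

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def size(self) -> int:
        return self.hi - self.lo + 1

    def points(self) -> np.ndarray:
        """Anchor points covered by this node."""
        return self._points[self.lo - 1 : self.hi]


def _anchor_points(frames) -> np.ndarray:
    if hasattr(frames, "origins"):
        return np.asarray(frames.origins, dtype=float)
    return np.atleast_2d(np.asarray(frames, dtype=float))


def build_hierarchy(frames) -> HierarchyNode:
    """Binary bounding-sphere tree over a frame sequence (or (N,3) points)."""
    points = _anchor_points(frames)
    if len(points) < 1:
        raise InputError("need at least one frame to build a hierarchy")

    def make(lo: int, hi: int) -> HierarchyNode:
        pts = points[lo - 1 : hi]
        center = pts.mean(axis=0)
        radius = float(np.sqrt(((pts - center) ** 2).sum(axis=1).max()))
        node = HierarchyNode(lo=lo, hi=hi, center=center, radius=radius,
                             _points=points)
        m = hi - lo + 1
        if m > LEAF_SIZE:
            mid = lo + (m + 1) // 2 - 1  # left child gets ceil(m/2)
            node.left = make(lo, mid)
            node.right = make(mid + 1, hi)
            hi_reach, lo_reach = [], []
            for child in (node.left, node.right):
                d = float(np.linalg.norm(child.center - center))
                hi_reach.append(d + child.leaf_reach_hi)
                lo_reach.append(d + child.leaf_reach_lo)
            node.leaf_reach_hi = max(hi_reach)
            node.leaf_reach_lo = max(lo_reach)
        else:
            node.leaf_reach_hi = radius
            node.leaf_reach_lo = -radius
        return node

    return make(1, len(points))


def _leaf_class(dist: float, near: float, far: float) -> str:
    if dist > far:
        return LINE
    if dist > near:
        return RIBBON
    return ATOMIC


def classify_lod(root: HierarchyNode, viewpoint, near: float = DEFAULT_NEAR,
                 far: float = DEFAULT_FAR) -> list[tuple[int, int, str]]:
    """Disjoint (lo, hi, representation) ranges covering the whole strand.

    A leaf is classified by the distance from the viewpoint to its bounding
    sphere; internal nodes are pruned only when their conservative bounds
    prove all descendant leaves share one class, so the result equals a
    per-leaf brute-force test exactly.
    """
    if not near < far:
        raise InputError("need near < far")
    viewpoint = np.asarray(viewpoint, dtype=float)
    out: list[tuple[int, int, str]] = []

    def visit(node: HierarchyNode) -> None:
        d = float(np.linalg.norm(viewpoint - node.center))
        if node.is_leaf:
            out.append((node.lo, node.hi, _leaf_class(d - node.radius, near, far)))
            return
        # every descendant leaf's sphere distance lies within these bounds
        d_min = d - node.leaf_reach_hi
        d_max = d + node.leaf_reach_lo
        if d_min > far:
            out.append((node.lo, node.hi, LINE))
            return
        if d_min > near and d_max <= far:
            out.append((node.lo, node.hi, RIBBON))
            return
        if d_max <= near:
            out.append((node.lo, node.hi, ATOMIC))
            return
        visit(node.left)
        visit(node.right)

    visit(root)
    # merge neighbouring ranges that ended up with the same representation
    merged: list[tuple[int, int, str]] = []
    for lo, hi, cls in out:
        if merged and merged[-1][2] == cls and merged[-1][1] + 1 == lo:
            merged[-1] = (merged[-1][0], hi, cls)
        else:
            merged.append((lo, hi, cls))
    return merged


def _ray_point_distance(origin: np.ndarray, direction: np.ndarray,
                        pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance of points to the ray and distance of points to the origin."""
    rel = pts - origin
    t = rel @ direction
    t = np.maximum(t, 0.0)
    closest = origin + t[..., None] * direction
    return np.linalg.norm(pts - closest, axis=-1), np.linalg.norm(rel, axis=-1)


def pick_base_pair(root: HierarchyNode, origin, direction,
                   hit_radius: float = 10.0) -> int | None:
    """Base pair whose anchor lies within ``hit_radius`` of the ray.

    Among qualifying anchors the one nearest the ray origin wins; ties go
    to the smaller index.  Returns ``None`` when nothing is hit.
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm < 1e-12:
        raise InputError("ray direction must be nonzero")
    direction = direction / norm

    best: tuple[float, int] | None = None

    def visit(node: HierarchyNode) -> None:
        nonlocal best
        d_ray, _ = _ray_point_distance(origin, direction, node.center[None, :])
        if d_ray[0] > node.radius + hit_radius:
            return
        if node.is_leaf:
            pts = node.points()
            dist, d0 = _ray_point_distance(origin, direction, pts)
            for k in np.flatnonzero(dist <= hit_radius):
                cand = (float(d0[k]), node.lo + int(k))
                if best is None or cand < best:
                    best = cand
            return
        visit(node.left)
        visit(node.right)

    visit(root)
    return None if best is None else best[1]
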