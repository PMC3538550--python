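"""Simplified strand representations: polyline, double ribbon, tube.

Three geometric stand-ins for the atomic model, used when the strand is
far from the viewer or when a purely geometric export is wanted:

* a polyline through the base-pair anchors (the "thick line" view);
* a helicoidal double ribbon — two ribbons, half a turn apart in phase,
  each swept from the axis point outward along the twist-schedule
  direction, so local unwinding is visible in the ribbon view;
* a tube of fixed radius swept along a curve with rotation-minimizing
  rings, for disordered linkers.

Meshes are plain indexed triangle sets with optional per-vertex color and
export to VRML97 (IndexedFaceSet) or Wavefront OBJ; both can be re-read
for round-tripping.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .curves import CurvePath, uniform_sample
from .errors import InputError
from .frames import FrameSequence, rmf
from .model import TwistSchedule

__all__ = ["TriangleMesh", "polyline_rep", "ribbon_mesh", "tube_mesh",
           "export_mesh", "import_mesh"]

log = logging.getLogger(__name__)

DEFAULT_RIBBON_WIDTH = 9.0   # Å, visual default
DEFAULT_TUBE_SIDES = 12
DEFAULT_RING_SPACING = 3.4   # Å


@dataclass
class TriangleMesh:
    """Indexed triangle mesh; vertices in Å."""

    vertices: np.ndarray
    triangles: np.ndarray
    colors: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=int).reshape(-1, 3)
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.vertices)
        ):
            raise InputError("triangle indices out of range")
        if self.colors is not None:
            self.colors = np.asarray(self.colors, dtype=float).reshape(-1, 3)
            if len(self.colors) != len(self.vertices):
                raise InputError("need one color per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def areas(self) -> np.ndarray:
        v = self.vertices
        t = self.triangles
        return 0.5 * np.linalg.norm(
            np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]]), axis=1
        )


def _drop_degenerate(tris: list[tuple[int, int, int]],
                     vertices: np.ndarray) -> np.ndarray:
    tris_arr = np.asarray(tris, dtype=int)
    v = vertices
    areas = 0.5 * np.linalg.norm(
        np.cross(v[tris_arr[:, 1]] - v[tris_arr[:, 0]],
                 v[tris_arr[:, 2]] - v[tris_arr[:, 0]]), axis=1
    )
    return tris_arr[areas > 1e-12]


def polyline_rep(frames: FrameSequence) -> np.ndarray:
    """Anchor points in order; a closed strand repeats the first at the end."""
    if len(frames) < 2:
        raise InputError("need at least 2 frames")
    pts = frames.origins
    if frames.closed:
        pts = np.vstack([pts, pts[:1]])
    return pts.copy()


def ribbon_mesh(frames: FrameSequence, schedule: TwistSchedule,
                width: float = DEFAULT_RIBBON_WIDTH,
                sides_per_bp: int = 1) -> TriangleMesh:
    """Helicoidal double ribbon driven by the twist schedule.

    Ribbon k ∈ {0, 1} at section i spans from the axis point o_i to
    o_i + (width/2)·d_i where d_i = cos(θ_i + kπ)·n_i + sin(θ_i + kπ)·b_i;
    with the default schedule the edge returns to its starting azimuth
    every 10.4 base pairs.  ``sides_per_bp`` > 1 interpolates extra
    cross-sections between consecutive pairs.
    """
    n = len(frames)
    if n < 2:
        raise InputError("need at least 2 frames")
    if len(schedule) != n:
        raise InputError("schedule length must match frame count")
    if sides_per_bp < 1:
        raise InputError("sides_per_bp must be >= 1")

    o = frames.origins
    nv = frames.normals
    bv = frames.binormals
    th = np.asarray(schedule.angles, dtype=float)
    k = int(sides_per_bp)
    if k > 1:
        # linear interpolation of origins/angles, re-orthonormalized directions
        spans = n if frames.closed else n - 1
        f = np.arange(k) / k
        idx = np.arange(spans)
        nxt = (idx + 1) % n
        wrap_step = schedule.step if frames.closed else 0.0
        th_next = np.where(nxt == 0, th[idx] + wrap_step, th[nxt])
        o_s = (o[idx, None, :] * (1 - f)[None, :, None]
               + o[nxt, None, :] * f[None, :, None]).reshape(-1, 3)
        n_s = (nv[idx, None, :] * (1 - f)[None, :, None]
               + nv[nxt, None, :] * f[None, :, None]).reshape(-1, 3)
        b_s = (bv[idx, None, :] * (1 - f)[None, :, None]
               + bv[nxt, None, :] * f[None, :, None]).reshape(-1, 3)
        th_s = (th[idx, None] * (1 - f)[None, :]
                + th_next[:, None] * f[None, :]).reshape(-1)
        if not frames.closed:
            o_s = np.vstack([o_s, o[-1:]])
            n_s = np.vstack([n_s, nv[-1:]])
            b_s = np.vstack([b_s, bv[-1:]])
            th_s = np.append(th_s, th[-1])
        n_s /= np.linalg.norm(n_s, axis=1, keepdims=True)
        b_s /= np.linalg.norm(b_s, axis=1, keepdims=True)
    else:
        o_s, n_s, b_s, th_s = o, nv, bv, th

    m = len(o_s)
    verts = []
    tris: list[tuple[int, int, int]] = []
    half = 0.5 * width
    for ribbon in range(2):
        phase = th_s + ribbon * np.pi
        d = np.cos(phase)[:, None] * n_s + np.sin(phase)[:, None] * b_s
        inner = o_s
        outer = o_s + half * d
        base = 2 * m * ribbon
        verts.append(inner)
        verts.append(outer)
        # vertex layout per ribbon: [inner 0..m-1, outer 0..m-1]
        spans = m if frames.closed else m - 1
        for i in range(spans):
            j = (i + 1) % m
            vi, vo = base + i, base + m + i
            wi, wo = base + j, base + m + j
            tris.append((vi, vo, wo))
            tris.append((vi, wo, wi))
    vertices = np.vstack(verts)
    return TriangleMesh(vertices=vertices,
                        triangles=_drop_degenerate(tris, vertices))


def tube_mesh(path: CurvePath, radius: float,
              ring_spacing: float = DEFAULT_RING_SPACING,
              sides: int = DEFAULT_TUBE_SIDES) -> TriangleMesh:
    """Tube of fixed radius swept along the curve on RMF rings.

    Open tubes are capped with an apex fan at each end; closed paths weld
    the last ring to the first (torus topology).
    """
    if radius <= 0:
        raise InputError("radius must be positive")
    if sides < 3:
        raise InputError("need at least 3 sides")
    sampling = uniform_sample(path, spacing=ring_spacing)
    fr = rmf(sampling)
    o, nv, bv = fr.origins, fr.normals, fr.binormals
    rings = len(o)
    alpha = 2 * np.pi * np.arange(sides) / sides
    ca, sa = np.cos(alpha), np.sin(alpha)
    ring_verts = (
        o[:, None, :]
        + radius * (ca[None, :, None] * nv[:, None, :]
                    + sa[None, :, None] * bv[:, None, :])
    ).reshape(-1, 3)

    tris: list[tuple[int, int, int]] = []
    spans = rings if path.closed else rings - 1
    for i in range(spans):
        j = (i + 1) % rings
        for a in range(sides):
            b = (a + 1) % sides
            v00 = i * sides + a
            v01 = i * sides + b
            v10 = j * sides + a
            v11 = j * sides + b
            tris.append((v00, v01, v11))
            tris.append((v00, v11, v10))
    if path.closed:
        vertices = ring_verts
    else:
        start_apex = len(ring_verts)
        end_apex = start_apex + 1
        vertices = np.vstack([ring_verts, o[:1], o[-1:]])
        for a in range(sides):
            b = (a + 1) % sides
            tris.append((start_apex, b, a))
            tris.append((end_apex, (rings - 1) * sides + a, (rings - 1) * sides + b))
    return TriangleMesh(vertices=vertices, triangles=_drop_degenerate(tris, vertices))


# ---------------------------------------------------------------------------
# export / import
# ---------------------------------------------------------------------------

def export_mesh(mesh: TriangleMesh, sink, format: str = "obj") -> None:
    """Write a mesh as VRML97 (with per-vertex color) or Wavefront OBJ."""
    format = format.lower()
    if format not in ("obj", "vrml"):
        raise InputError(f"unknown mesh format {format!r}")
    own, fh = _open_sink(sink)
    try:
        if format == "obj":
            if mesh.colors is not None:
                log.warning("OBJ export drops per-vertex colors")
            for v in mesh.vertices:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for t in mesh.triangles:
                fh.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")
        else:
            fh.write("#VRML V2.0 utf8\n")
            fh.write("Shape {\n  geometry IndexedFaceSet {\n")
            fh.write("    coord Coordinate { point [\n")
            fh.write(",\n".join(
                f"      {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}" for v in mesh.vertices
            ))
            fh.write("\n    ] }\n")
            if mesh.colors is not None:
                fh.write("    colorPerVertex TRUE\n")
                fh.write("    color Color { color [\n")
                fh.write(",\n".join(
                    f"      {c[0]:.4f} {c[1]:.4f} {c[2]:.4f}" for c in mesh.colors
                ))
                fh.write("\n    ] }\n")
            fh.write("    coordIndex [\n")
            fh.write(",\n".join(
                f"      {t[0]}, {t[1]}, {t[2]}, -1" for t in mesh.triangles
            ))
            fh.write("\n    ]\n  }\n}\n")
    finally:
        if own:
            fh.close()


def import_mesh(source, format: str | None = None) -> TriangleMesh:
    """Read back a mesh written by :func:`export_mesh` (OBJ or VRML97)."""
    text, name = _read_text(source)
    if format is None:
        ext = os.path.splitext(name)[1].lower()
        if ext in (".wrl", ".vrml"):
            format = "vrml"
        elif ext == ".obj":
            format = "obj"
        else:
            format = "vrml" if text.lstrip().startswith("#VRML") else "obj"
    format = format.lower()
    if format == "obj":
        verts, tris = [], []
        for ln, line in enumerate(text.splitlines(), start=1):
            parts = line.split()
            if not parts:
                continue
            if parts[0] == "v":
                verts.append([float(p) for p in parts[1:4]])
            elif parts[0] == "f":
                idx = [int(p.split("/")[0]) - 1 for p in parts[1:]]
                if len(idx) != 3:
                    raise InputError(f"line {ln}: only triangle faces supported")
                tris.append(idx)
        if not verts:
            raise InputError("no vertices found in OBJ input")
        return TriangleMesh(vertices=np.array(verts), triangles=np.array(tris))
    if format != "vrml":
        raise InputError(f"unknown mesh format {format!r}")
    pts = _vrml_block(text, r"point\s*\[(.*?)\]")
    if pts is None:
        raise InputError("no Coordinate point block found in VRML input")
    verts = np.array(pts, dtype=float).reshape(-1, 3)
    idx_block = re.search(r"coordIndex\s*\[(.*?)\]", text, re.S)
    if idx_block is None:
        raise InputError("no coordIndex block found in VRML input")
    raw = [int(v) for v in re.findall(r"-?\d+", idx_block.group(1))]
    tris, face = [], []
    for v in raw:
        if v == -1:
            if len(face) != 3:
                raise InputError("only triangle faces supported in VRML input")
            tris.append(face)
            face = []
        else:
            face.append(v)
    if face:
        tris.append(face)
    colors = None
    cblock = re.search(r"color\s*\[(.*?)\]", text, re.S)
    if cblock is not None:
        colors = np.array(
            [float(v) for v in re.findall(r"-?\d+\.?\d*(?:[eE][-+]?\d+)?",
                                          cblock.group(1))],
            dtype=float,
        ).reshape(-1, 3)
    return TriangleMesh(vertices=verts, triangles=np.array(tris), colors=colors)


def _vrml_block(text: str, pattern: str):
    m = re.search(pattern, text, re.S)
    if m is None:
        return None
    return [float(v) for v in re.findall(r"-?\d+\.?\d*(?:[eE][-+]?\d+)?",
                                         m.group(1))]


def _open_sink(sink):
    if isinstance(sink, (str, os.PathLike)):
        return True, open(sink, "w")
    return False, sink


def _read_text(source) -> tuple[str, str]:
    if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
        if not os.path.exists(source):
            raise InputError(f"no such file: {source}")
        with open(source) as fh:
            return fh.read(), str(source)
    if isinstance(source, str):
        return source, ""
    if hasattr(source, "read"):
        return source.read(), getattr(source, "name", "")
    raise InputError(f"cannot read from {type(source).__name__}")
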