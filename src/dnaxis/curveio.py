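"""Reading and writing curve descriptions and twist-constraint lists.

Curve files are YAML::

    closed: false
    segments:
      - [[0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0]]
      - [[30, 0, 0], [40, 0, 0], [50, 10, 0]]

Each segment row lists 3 (quadratic) or 4 (cubic) control points in Å;
consecutive segments must share their junction point.

Twist-constraint files are plain text, one ``index angle_deg`` pair per
line (1-based base-pair index, offset in degrees); blank lines and ``#``
comments are ignored.  Angles are converted to radians on read.
"""

from __future__ import annotations

import math
import os

import numpy as np
import yaml

from .curves import BezierSegment, CurvePath
from .errors import InputError
from .model import TwistConstraintSet

__all__ = ["read_curve_file", "write_curve_file", "read_twist_constraints"]


def read_curve_file(source) -> CurvePath:
    """Load a CurvePath from a YAML curve file (path, text or file-like)."""
    text = _read_text(source)
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise InputError(f"invalid curve file: {exc}") from exc
    if not isinstance(data, dict) or "segments" not in data:
        raise InputError("curve file must be a mapping with a 'segments' list")
    segments = []
    for k, row in enumerate(data["segments"]):
        try:
            segments.append(BezierSegment(np.asarray(row, dtype=float)))
        except (TypeError, ValueError, InputError) as exc:
            raise InputError(f"segment {k}: {exc}") from exc
    return CurvePath(segments, closed=bool(data.get("closed", False)))


def write_curve_file(path: CurvePath, sink) -> None:
    """Write a CurvePath as a YAML curve file."""
    data = {
        "closed": path.closed,
        "segments": [
            [[float(c) for c in p] for p in seg.control_points]
            for seg in path.segments
        ],
    }
    text = yaml.safe_dump(data, sort_keys=False, default_flow_style=None)
    if isinstance(sink, (str, os.PathLike)):
        with open(sink, "w") as fh:
            fh.write(text)
    else:
        sink.write(text)


def read_twist_constraints(source) -> TwistConstraintSet:
    """Parse ``index angle_deg`` lines into a TwistConstraintSet (radians)."""
    text = _read_text(source)
    entries: dict[int, float] = {}
    for ln, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        parts = stripped.split()
        if len(parts) != 2:
            raise InputError(
                f"line {ln}: expected 'index angle_deg', got {stripped!r}"
            )
        try:
            idx = int(parts[0])
            ang = float(parts[1])
        except ValueError as exc:
            raise InputError(f"line {ln}: {exc}") from exc
        if idx in entries:
            raise InputError(f"line {ln}: duplicate constraint for base pair {idx}")
        entries[idx] = math.radians(ang)
    return TwistConstraintSet(entries)


def _read_text(source) -> str:
    if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
        if os.path.exists(source):
            with open(source) as fh:
                return fh.read()
        if isinstance(source, os.PathLike) or ":" not in str(source):
            raise InputError(f"no such file: {source}")
        return str(source)
    if isinstance(source, str):
        return source
    if hasattr(source, "read"):
        return source.read()
    raise InputError(f"cannot read from {type(source).__name__}")
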