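"""All-atom B-DNA model assembly: twist schedule, sequence, instantiation.

Each base pair i (1-based) is placed at frame f_i of the rotation-
minimizing sequence and rotated about the tangent by

    θ_i = (i − 1) · 2π / bp_per_turn + a_i

where 10.4 bp/turn is the default B-form pitch and a_i is a user twist
offset.  Offsets are given at a sparse set of constrained pairs and
linearly interpolated in index between them; outside the first/last
constraint the offset is held constant.  Closing a strand whose length is
not a multiple of 10.4 requires the pitch to differ slightly: for closed
strands the default pitch becomes N / round(N / 10.4) so the default twist
sums to an exact integer number of turns.

The nucleotide sequence defaults to the generic repeat (ACTG)*; an
explicit sequence may be supplied instead.  Atom coordinates are generated
lazily, one base pair at a time, from the four in-memory templates —
memory stays proportional to the number of frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .curves import CurvePath, uniform_sample
from .errors import InputError
from .frames import Frame, FrameSequence, rmf
from .templates import (BASE_PAIR_TEMPLATES, BasePairTemplate, COMPLEMENT,
                        PAIR_FOR_BASE, TemplateAtom)

__all__ = [
    "TwistConstraintSet",
    "TwistSchedule",
    "PlacedAtom",
    "DNAModel",
    "twist_schedule",
    "assign_sequence",
    "instantiate_base_pair",
    "build_dna",
]

DEFAULT_BP_PER_TURN = 10.4


class TwistConstraintSet:
    """Sparse map: 1-based base-pair index → twist offset a_i (radians)."""

    def __init__(self, entries: Mapping[int, float] | Iterable[tuple[int, float]] = ()):
        entries = dict(entries)
        for i in entries:
            if not isinstance(i, (int, np.integer)) or i < 1:
                raise InputError(f"constraint index {i!r} must be a 1-based integer")
        self.entries: dict[int, float] = {
            int(i): float(a) for i, a in sorted(entries.items())
        }

    def __len__(self) -> int:
        return len(self.entries)

    def __bool__(self) -> bool:
        return bool(self.entries)

    def indices(self) -> list[int]:
        return list(self.entries)

    def validate(self, n_bp: int) -> None:
        for i in self.entries:
            if i > n_bp:
                raise InputError(
                    f"twist constraint index {i} out of range for {n_bp} base pairs"
                )


@dataclass(frozen=True)
class TwistSchedule:
    """Per-base-pair total rotation about the tangent.

    ``angles[i-1] = default + offset`` for pair i; ``bp_per_turn`` is the
    effective pitch (adjusted on closed strands), ``offsets`` the
    interpolated user term.
    """

    angles: np.ndarray
    bp_per_turn: float
    offsets: np.ndarray
    closed: bool = False

    def __len__(self) -> int:
        return len(self.angles)

    @property
    def step(self) -> float:
        """Default twist increment between consecutive pairs (radians)."""
        return 2.0 * math.pi / self.bp_per_turn


def twist_schedule(
    n_bp: int,
    constraints: TwistConstraintSet | Mapping[int, float] | None = None,
    bp_per_turn: float = DEFAULT_BP_PER_TURN,
    closed: bool = False,
) -> TwistSchedule:
    """Total rotation θ_i for each base pair.

    The default term is (i−1)·2π/bp_per_turn; on closed strands the pitch
    is adjusted to N/round(N/bp_per_turn) so the default twist closes on an
    integer number of turns.  User offsets are linearly interpolated in
    index between constrained pairs and held constant outside them.
    """
    if n_bp < 1:
        raise InputError("need at least one base pair")
    if bp_per_turn <= 0:
        raise InputError("bp_per_turn must be positive")
    if constraints is None:
        constraints = TwistConstraintSet()
    elif not isinstance(constraints, TwistConstraintSet):
        constraints = TwistConstraintSet(constraints)
    constraints.validate(n_bp)

    eff = bp_per_turn
    if closed:
        turns = max(1, int(round(n_bp / bp_per_turn)))
        eff = n_bp / turns
    idx = np.arange(n_bp, dtype=float)
    default = idx * (2.0 * math.pi / eff)

    if constraints:
        ci = np.array(constraints.indices(), dtype=float)
        ca = np.array([constraints.entries[int(i)] for i in ci])
        offsets = np.interp(idx + 1.0, ci, ca)  # constant beyond the ends
    else:
        offsets = np.zeros(n_bp)
    return TwistSchedule(
        angles=default + offsets, bp_per_turn=eff, offsets=offsets, closed=closed
    )


def assign_sequence(n_bp: int, sequence: str | None = None) -> list[str]:
    """Pair ids for each index: generic (ACTG)* or a user sequence.

    The sequence letters are the leading-strand (strand I) bases; each pair
    id is that base followed by its Watson–Crick complement.
    """
    if n_bp < 1:
        raise InputError("need at least one base pair")
    if sequence is None:
        generic = "ACTG"
        bases = [generic[i % 4] for i in range(n_bp)]
    else:
        sequence = sequence.strip().upper()
        if len(sequence) != n_bp:
            raise InputError(
                f"sequence length {len(sequence)} does not match {n_bp} base pairs"
            )
        bad = set(sequence) - set("ACGT")
        if bad:
            raise InputError(f"sequence contains non-ACGT letters: {sorted(bad)}")
        bases = list(sequence)
    return [PAIR_FOR_BASE[b] for b in bases]


@dataclass(frozen=True)
class PlacedAtom:
    """One template atom instantiated in global coordinates."""

    name: str
    element: str
    res_name: str
    strand: str
    position: np.ndarray


def _pair_rotation(frame: Frame, theta: float) -> np.ndarray:
    """Local→global linear map: rotate by theta about local z, then map
    local (x, y, z) onto (n, b, t)."""
    c, s = math.cos(theta), math.sin(theta)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    basis = np.column_stack([frame.n, frame.b, frame.t])
    return basis @ rot


def instantiate_base_pair(
    template: BasePairTemplate, frame: Frame, theta: float
) -> list[PlacedAtom]:
    """Rigidly place one base-pair template at a frame with twist theta."""
    coords = transform_coords(template.coords, frame, theta)
    return [
        PlacedAtom(a.name, a.element, a.res_name, a.strand, xyz)
        for a, xyz in zip(template.atoms, coords)
    ]


def transform_coords(local: np.ndarray, frame: Frame, theta: float) -> np.ndarray:
    """Apply the pair placement (twist + frame rigid motion) to raw coords."""
    m = _pair_rotation(frame, theta)
    return local @ m.T + frame.o


class DNAModel:
    """A built strand: frames + twist schedule + sequence, atoms on demand.

    Only the per-pair frames, angles and pair ids are stored; atom
    coordinates are produced lazily by :meth:`base_pair_atoms` /
    :meth:`pair_coords`, so memory is proportional to N plus the four
    shared templates.
    """

    def __init__(
        self,
        frames: FrameSequence,
        schedule: TwistSchedule,
        sequence: Sequence[str],
        closed: bool = False,
        templates: Mapping[str, BasePairTemplate] = BASE_PAIR_TEMPLATES,
    ):
        n = len(frames)
        if not (len(schedule) == n == len(sequence)):
            raise InputError(
                f"frames ({n}), schedule ({len(schedule)}) and sequence "
                f"({len(sequence)}) must share one length"
            )
        self.frames = frames
        self.schedule = schedule
        self.sequence = list(sequence)
        self.closed = bool(closed)
        self.templates = templates

    @property
    def n_base_pairs(self) -> int:
        return len(self.sequence)

    @property
    def n_atoms(self) -> int:
        return sum(self.templates[p].n_atoms for p in self.sequence)

    def template(self, i: int) -> BasePairTemplate:
        return self.templates[self.sequence[i - 1]]

    def pair_coords(self, i: int) -> np.ndarray:
        """Global coordinates of base pair i (1-based), template atom order."""
        if not (1 <= i <= self.n_base_pairs):
            raise InputError(f"base-pair index {i} out of range")
        tpl = self.template(i)
        return transform_coords(
            tpl.coords, self.frames.frame(i - 1), float(self.schedule.angles[i - 1])
        )

    def base_pair_atoms(self, i: int) -> list[PlacedAtom]:
        """Placed atoms of base pair i (1-based)."""
        tpl = self.template(i)
        coords = self.pair_coords(i)
        return [
            PlacedAtom(a.name, a.element, a.res_name, a.strand, xyz)
            for a, xyz in zip(tpl.atoms, coords)
        ]

    def iter_atoms(self) -> Iterator[PlacedAtom]:
        for i in range(1, self.n_base_pairs + 1):
            yield from self.base_pair_atoms(i)


def build_dna(
    path: CurvePath,
    constraints: TwistConstraintSet | Mapping[int, float] | None = None,
    *,
    spacing: float = 3.4,
    bp_per_turn: float = DEFAULT_BP_PER_TURN,
    closed: bool | None = None,
    sequence: str | None = None,
) -> DNAModel:
    """Full pipeline: uniform sampling → RMF → twist schedule → model."""
    if closed is None:
        closed = path.closed
    sampling = uniform_sample(path, spacing=spacing)
    frame_seq = rmf(sampling, closed=closed)
    n = len(frame_seq)
    schedule = twist_schedule(n, constraints, bp_per_turn=bp_per_turn, closed=closed)
    seq = assign_sequence(n, sequence)
    return DNAModel(frames=frame_seq, schedule=schedule, sequence=seq, closed=closed)
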