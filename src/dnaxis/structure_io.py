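"""PDB export of built models and coarse-grained point import.

Export writes fixed-column PDB v3 coordinate records: strand I as chain A
in 5'→3' order (residues 1..N along the build direction), strand II as
chain B in its own 5'→3' order (pair N first), a TER record closing each
chain, and END.  Coordinates are printed to 3 decimals; re-parsing and
re-writing a file reproduces it byte for byte.

Import reads bead sequences for back-mapping: whitespace ``x y z`` text or
the coordinate fields of PDB ATOM/HETATM records, in file order.  Only a
minimal fixed-column PDB read is provided — coordinates and identity, no
chemistry.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass
from typing import Iterable, Sequence, TextIO

import numpy as np

from .errors import InputError
from .model import DNAModel
from .templates import STRAND_I, STRAND_II

__all__ = ["AtomRecord", "export_pdb", "write_pdb_records", "read_pdb_atoms",
           "import_points"]

log = logging.getLogger(__name__)

_SERIAL_MOD = 100000
_RESSEQ_MOD = 10000


@dataclass(frozen=True)
class AtomRecord:
    """One ATOM record (coordinates in Å)."""

    serial: int
    name: str
    res_name: str
    chain_id: str
    res_seq: int
    position: np.ndarray
    occupancy: float = 1.0
    temp_factor: float = 0.0
    element: str = ""


def _atom_name_field(name: str) -> str:
    # element symbols of one letter start in column 14
    if len(name) < 4:
        return f" {name:<3s}"
    return f"{name:<4s}"


def _format_atom(rec: AtomRecord) -> str:
    x, y, z = rec.position
    return (
        f"ATOM  {rec.serial:5d} {_atom_name_field(rec.name)} "
        f"{rec.res_name:>3s} {rec.chain_id}{rec.res_seq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{rec.occupancy:6.2f}{rec.temp_factor:6.2f}"
        f"          {rec.element:>2s}"
    )


def _format_ter(serial: int, rec: AtomRecord) -> str:
    return (
        f"TER   {serial:5d}      {rec.res_name:>3s} "
        f"{rec.chain_id}{rec.res_seq:4d}"
    )


def write_pdb_records(records: Sequence[AtomRecord], sink) -> None:
    """Write ATOM records with a TER after every chain, then END.

    Serial and residue numbers are written exactly as given; a chain break
    is any change of ``chain_id`` between consecutive records.
    """
    own, fh = _open_sink(sink)
    try:
        prev: AtomRecord | None = None
        for rec in records:
            if prev is not None and rec.chain_id != prev.chain_id:
                fh.write(_format_ter((prev.serial + 1) % _SERIAL_MOD, prev) + "\n")
            fh.write(_format_atom(rec) + "\n")
            prev = rec
        if prev is not None:
            fh.write(_format_ter((prev.serial + 1) % _SERIAL_MOD, prev) + "\n")
        fh.write("END\n")
    finally:
        if own:
            fh.close()


def _model_records(model: DNAModel) -> Iterable[AtomRecord]:
    n = model.n_base_pairs
    serial = 0
    warned = False

    def bump() -> int:
        nonlocal serial, warned
        serial += 1
        if serial > 99999 and not warned:
            log.warning(
                "more than 99,999 atom serials: numbers wrap modulo 100000"
            )
            warned = True
        return serial % _SERIAL_MOD

    res_warned = False

    def resseq(r: int) -> int:
        nonlocal res_warned
        if r > 9999 and not res_warned:
            log.warning("more than 9,999 residues: numbers wrap modulo 10000")
            res_warned = True
        return r % _RESSEQ_MOD

    # chain A: strand I, pair order 1..N (its 5'->3' direction)
    for i in range(1, n + 1):
        tpl = model.template(i)
        coords = model.pair_coords(i)
        for a, xyz in zip(tpl.atoms, coords):
            if a.strand != STRAND_I:
                continue
            yield AtomRecord(bump(), a.name, a.res_name, "A", resseq(i), xyz,
                             element=a.element)
    serial += 1  # TER consumes a serial
    # chain B: strand II, pair order N..1 (its own 5'->3' direction)
    for r, i in enumerate(range(n, 0, -1), start=1):
        tpl = model.template(i)
        coords = model.pair_coords(i)
        for a, xyz in zip(tpl.atoms, coords):
            if a.strand != STRAND_II:
                continue
            yield AtomRecord(bump(), a.name, a.res_name, "B", resseq(r), xyz,
                             element=a.element)


def export_pdb(model: DNAModel, sink) -> None:
    """Write a built model as a two-chain PDB file (see module docstring)."""
    write_pdb_records(list(_model_records(model)), sink)


def read_pdb_atoms(source) -> list[AtomRecord]:
    """Minimal fixed-column parse of ATOM/HETATM records, in file order."""
    text = _read_source(source)
    records: list[AtomRecord] = []
    for ln, line in enumerate(text.splitlines(), start=1):
        tag = line[:6]
        if tag not in ("ATOM  ", "HETATM"):
            continue
        try:
            records.append(
                AtomRecord(
                    serial=int(line[6:11]),
                    name=line[12:16].strip(),
                    res_name=line[17:20].strip(),
                    chain_id=line[21],
                    res_seq=int(line[22:26]),
                    position=np.array(
                        [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                    ),
                    occupancy=float(line[54:60]) if line[54:60].strip() else 1.0,
                    temp_factor=float(line[60:66]) if line[60:66].strip() else 0.0,
                    element=line[76:78].strip() if len(line) >= 78 else "",
                )
            )
        except (ValueError, IndexError) as exc:
            raise InputError(f"malformed PDB record at line {ln}: {exc}") from exc
    return records


def import_points(source, format: str | None = None) -> np.ndarray:
    """Ordered 3D points from xyz text or PDB coordinate records.

    ``format`` is ``"xyz"`` or ``"pdb"``; when omitted it is sniffed from a
    file extension or from the presence of ATOM/HETATM records.
    """
    text = _read_source(source)
    if format is None:
        name = source if isinstance(source, (str, os.PathLike)) else ""
        ext = os.path.splitext(str(name))[1].lower()
        if ext in (".pdb", ".ent"):
            format = "pdb"
        elif ext == ".xyz":
            format = "xyz"
        else:
            format = "pdb" if any(
                ln[:6] in ("ATOM  ", "HETATM") for ln in text.splitlines()
            ) else "xyz"
    if format == "pdb":
        records = read_pdb_atoms(text)
        if not records:
            raise InputError("no ATOM/HETATM records found")
        return np.array([r.position for r in records])
    if format != "xyz":
        raise InputError(f"unknown point format {format!r}")
    points = []
    for ln, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        parts = stripped.split()
        if len(parts) < 3:
            raise InputError(f"line {ln}: expected 3 coordinates, got {len(parts)}")
        try:
            points.append([float(v) for v in parts[:3]])
        except ValueError as exc:
            raise InputError(f"line {ln}: {exc}") from exc
    if not points:
        raise InputError("no points found in input")
    return np.asarray(points)


# ---------------------------------------------------------------------------

def _open_sink(sink) -> tuple[bool, TextIO]:
    if isinstance(sink, (str, os.PathLike)):
        return True, open(sink, "w")
    return False, sink


def _read_source(source) -> str:
    if isinstance(source, (str, os.PathLike)) and "\n" not in str(source):
        if os.path.exists(source):
            with open(source) as fh:
                return fh.read()
        if isinstance(source, os.PathLike) or " " not in str(source):
            raise InputError(f"no such file: {source}")
        return str(source)
    if isinstance(source, str):
        return source
    if hasattr(source, "read"):
        return source.read()
    raise InputError(f"cannot read from {type(source).__name__}")
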