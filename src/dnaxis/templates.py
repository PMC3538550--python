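"""Base-pair templates: one idealized atomic model per pair AT, TA, CG, GC.

Each template holds the heavy atoms of a Watson–Crick pair in a local
reference frame: helix axis = local z through the origin, base-pair plane
≈ local xy, strand-I backbone on the +y side.  Strand II is the dyad image
of strand I geometry (x, −y, −z), which makes the two strands antiparallel
and preserves backbone connectivity under the helix symmetry.

Only these four templates are kept in memory; a model of N base pairs
stores frames and angles, never instantiated atoms, so million-base-pair
strands stay cheap.

Residue names follow PDB v3 deoxynucleotide nomenclature (DA/DT/DC/DG);
the thymine methyl is C7.  The templates are idealized, generated once
from standard bond geometry under the 10.4 bp/turn, 3.4 Å-rise B-form
helix (see ``_bp_geometry``); as with any rigid-template construction,
O3'–P bonds between neighboring residues stretch where the axis curves
sharply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ._bp_geometry import BACKBONE_ATOMS, BASE_ATOMS

__all__ = ["TemplateAtom", "BasePairTemplate", "BASE_PAIR_TEMPLATES",
           "COMPLEMENT", "PAIR_FOR_BASE"]

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PAIR_FOR_BASE = {"A": "AT", "T": "TA", "C": "CG", "G": "GC"}

#: strand tags: strand I carries the leading base, strand II its complement
STRAND_I, STRAND_II = "I", "II"


@dataclass(frozen=True)
class TemplateAtom:
    name: str
    element: str
    res_name: str
    strand: str


@dataclass(frozen=True)
class BasePairTemplate:
    """Atoms of one idealized base pair in the local pair frame."""

    pair_id: str
    atoms: tuple[TemplateAtom, ...]
    coords: np.ndarray  # (n_atoms, 3), Å

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def strand_indices(self, strand: str) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.strand == strand])


def _element(name: str) -> str:
    return name[0] if name[0].isalpha() else name[1]


def _nucleotide(base: str, strand: str) -> tuple[list[TemplateAtom], np.ndarray]:
    """Backbone + base heavy atoms of one nucleotide in the pair frame."""
    res_name = "D" + base
    atoms: list[TemplateAtom] = []
    xyz: list[tuple[float, float, float]] = []
    for name, x, y, z in BACKBONE_ATOMS:
        atoms.append(TemplateAtom(name, _element(name), res_name, strand))
        xyz.append((x, y, z))
    for name, x, y, z in BASE_ATOMS[base]:
        atoms.append(TemplateAtom(name, _element(name), res_name, strand))
        xyz.append((x, y, z))
    coords = np.asarray(xyz, dtype=float)
    if strand == STRAND_II:
        coords = coords * np.array([1.0, -1.0, -1.0])  # dyad flip
    return atoms, coords


def _build_pair(pair_id: str) -> BasePairTemplate:
    lead, comp = pair_id[0], pair_id[1]
    atoms_i, coords_i = _nucleotide(lead, STRAND_I)
    atoms_ii, coords_ii = _nucleotide(comp, STRAND_II)
    return BasePairTemplate(
        pair_id=pair_id,
        atoms=tuple(atoms_i + atoms_ii),
        coords=np.vstack([coords_i, coords_ii]),
    )


BASE_PAIR_TEMPLATES: Mapping[str, BasePairTemplate] = {
    pid: _build_pair(pid) for pid in ("AT", "TA", "CG", "GC")
}
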