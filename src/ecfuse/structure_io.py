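"""Reading protein backbones from PDB files and computing phi/psi torsion angles.

The structural branch of the predictor works on the joint distribution of the
backbone torsion angles phi (rotation about N-CA) and psi (rotation about
CA-C), i.e. the Ramachandran plot. This module provides the backbone model
(:class:`ProteinStructure`), the PDB reader, the signed-dihedral primitive and
the per-protein torsion extraction, pooling the angles of all chains.

Conventions
-----------
* Angles are in degrees, in the half-open interval [-180, 180); +180 maps
  to -180 so that histogram binning is unambiguous.
* Dihedral sign follows the IUPAC convention: looking from the second atom
  toward the third, a clockwise rotation of the far bond is positive.
* Only the first MODEL of a multi-model file is read; for alternate locations
  the highest-occupancy conformer is kept (ties: first listed).
* A C(i)-N(i+1) distance above ``chain_break_distance`` (default 2.5 A, vs. a
  1.33 A peptide bond) terminates the torsion segment as if at a chain end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Residue",
    "Chain",
    "ProteinStructure",
    "TorsionAngleSet",
    "StructureError",
    "GeometryError",
    "parse_pdb",
    "dihedral",
    "compute_backbone_torsions",
    "write_torsions_csv",
]

BACKBONE_ATOMS = ("N", "CA", "C")

#: Maximum C(i)-N(i+1) distance (Angstrom) still treated as a peptide bond.
DEFAULT_CHAIN_BREAK_DISTANCE = 2.5


class StructureError(ValueError):
    """Raised for unusable structure input (no ATOM records, no backbone...)."""


class GeometryError(ValueError):
    """Raised for degenerate dihedral geometry (zero-length or collinear bonds)."""


@dataclass
class Residue:
    """One amino-acid residue with (possibly incomplete) backbone coordinates."""

    name: str
    seq_position: int
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ProteinStructure:
    """Ordered chains of residues with N/CA/C coordinates in Angstrom."""

    id: str
    chains: list[Chain] = field(default_factory=list)

    @property
    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains)


@dataclass
class TorsionAngleSet:
    """Per-residue (phi, psi) pairs in degrees, pooled over all chains.

    Every angle lies in [-180, 180).
    """

    pairs: np.ndarray  # shape (n, 2)

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def phi(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def psi(self) -> np.ndarray:
        return self.pairs[:, 1]


def wrap_angle(angle: float | np.ndarray) -> float | np.ndarray:
    """Map an angle in degrees into [-180, 180)."""
    return (np.asarray(angle) + 180.0) % 360.0 - 180.0


def parse_pdb(path: str | Path, structure_id: str | None = None) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Keeps ATOM records for N, CA and C only; HETATM records, waters and
    hydrogens are ignored. Multi-model files contribute only their first
    model; alternate locations resolve to the highest-occupancy conformer.

    Raises
    ------
    StructureError
        If the file cannot be parsed or contains no residue with a complete
        N/CA/C backbone.
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if structure_id is None:
        structure_id = path.stem
    parser = PDBParser(QUIET=True)
    try:
        bio_structure = parser.get_structure(structure_id, str(path))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise StructureError(f"cannot parse PDB file {path}: {exc}") from exc

    try:
        model = next(iter(bio_structure))
    except StopIteration:
        raise StructureError(f"no model in PDB file {path}")

    chains: list[Chain] = []
    for bio_chain in model:
        residues: list[Residue] = []
        for bio_res in bio_chain:
            hetflag, resseq, _icode = bio_res.get_id()
            if hetflag.strip():  # HETATM (waters, ligands)
                continue
            atoms: dict[str, np.ndarray] = {}
            for name in BACKBONE_ATOMS:
                if name in bio_res:
                    atom = bio_res[name]
                    # DisorderedAtom resolves to the highest-occupancy altloc
                    atoms[name] = np.array(atom.get_coord(), dtype=float)
            residues.append(Residue(bio_res.get_resname(), resseq, atoms))
        if residues:
            chains.append(Chain(bio_chain.id, residues))

    structure = ProteinStructure(structure_id, chains)
    if not any(r.has_backbone for c in structure.chains for r in c.residues):
        raise StructureError(f"no residue with complete N/CA/C backbone in {path}")
    return structure


def dihedral(
    p1: Sequence[float],
    p2: Sequence[float],
    p3: Sequence[float],
    p4: Sequence[float],
) -> float:
    """Signed dihedral angle (degrees) of the chain p1-p2-p3-p4 in [-180, 180).

    Positive when, looking from p2 toward p3, the bond p3->p4 is rotated
    clockwise relative to p1->p2 (IUPAC convention).

    Raises
    ------
    GeometryError
        If consecutive points coincide or the three bond vectors are
        collinear, leaving the angle undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-12:
            raise GeometryError("zero-length bond in dihedral")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise GeometryError("collinear bond vectors in dihedral")
    # atan2 formulation is numerically stable near 0 and 180 degrees
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def _segments(
    residues: Iterable[Residue], chain_break_distance: float
) -> list[list[Residue]]:
    """Split a chain into runs of complete, peptide-bonded residues."""
    segments: list[list[Residue]] = []
    current: list[Residue] = []
    for res in residues:
        if not res.has_backbone:
            if current:
                segments.append(current)
                current = []
            continue
        if current:
            prev = current[-1]
            gap = np.linalg.norm(res.atoms["N"] - prev.atoms["C"])
            if gap > chain_break_distance:
                segments.append(current)
                current = []
        current.append(res)
    if current:
        segments.append(current)
    return segments


def compute_backbone_torsions(
    structure: ProteinStructure,
    chain_break_distance: float = DEFAULT_CHAIN_BREAK_DISTANCE,
) -> TorsionAngleSet:
    """Compute all (phi, psi) pairs of a structure, pooled over chains.

    For residue i of a contiguous segment, phi = dihedral(C(i-1), N(i),
    CA(i), C(i)) and psi = dihedral(N(i), CA(i), C(i), N(i+1)); only
    residues with both angles defined contribute, so a segment of n
    residues yields n - 2 pairs.

    Raises
    ------
    StructureError
        If no residue yields a complete (phi, psi) pair.
    """
    pairs: list[tuple[float, float]] = []
    for chain in structure.chains:
        for seg in _segments(chain.residues, chain_break_distance):
            for prev, res, nxt in zip(seg, seg[1:], seg[2:]):
                phi = dihedral(
                    prev.atoms["C"], res.atoms["N"], res.atoms["CA"], res.atoms["C"]
                )
                psi = dihedral(
                    res.atoms["N"], res.atoms["CA"], res.atoms["C"], nxt.atoms["N"]
                )
                pairs.append((phi, psi))
    if not pairs:
        raise StructureError(
            f"structure {structure.id!r} yields no complete (phi, psi) pair"
        )
    return TorsionAngleSet(np.array(pairs))


def write_torsions_csv(torsions: TorsionAngleSet, path: str | Path) -> None:
    """Write a TorsionAngleSet as a 2-column CSV (phi, psi) in degrees."""
    import pandas as pd

    pd.DataFrame(torsions.pairs, columns=["phi", "psi"]).to_csv(path, index=False)
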