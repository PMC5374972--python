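"""Synthetic enzymes: paired structures, sequences and EC-class labels.

The generator produces desk-scale datasets with the same shape as the real
classification problem — PDB structures, FASTA sequences and a label table
over the six EC top-level classes, with optional multi-label memberships —
while keeping the class signal fully controllable:

* Structure: each class carries its own mixture of 2D Gaussians over
  (phi, psi), built from Ramachandran-plausible basins (alpha-helix near
  (-60, -45), beta-sheet near (-120, 120), left-handed helix near (60, 45)).
  Torsions sampled from the class mixture are turned into 3D coordinates by
  sequential internal-to-Cartesian (NeRF) construction with ideal peptide
  geometry, so the written PDB file round-trips through the torsion
  extraction.
* Sequence: a background draw over the 20 amino acids with one distinctive
  motif per carried class inserted at a random position, giving the
  Smith-Waterman branch a clean within-class similarity signal.

The generator emulates class-dependent torsion distributions and
motif-bearing sequences only; it makes no attempt at physically realistic
side chains, packing, or sequence-structure consistency beyond the labels.

``scramble_motifs`` and ``randomize_torsions`` degrade one modality at a
time: the former scrambles the motif-class association (each enzyme gets a
randomly chosen class's motif), the latter replaces the class torsion
mixtures by uniform angles. Both are used to probe how the optimal fusion
weight alpha moves toward the intact information source.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .sequence_similarity import AMINO_ACIDS, SequenceRecord, write_fasta
from .structure_io import Chain, ProteinStructure, Residue, TorsionAngleSet

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "build_backbone_from_torsions",
    "generate_dataset",
    "write_dataset",
    "write_pdb",
    "DEFAULT_BASINS",
    "DEFAULT_CLASS_MIXTURES",
    "DEFAULT_MOTIFS",
]

# Ideal backbone geometry (Angstrom / degrees), standard peptide values
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
OMEGA = 180.0

# Ramachandran-region basins: (phi mean, psi mean, standard deviation), degrees.
# Six distinct centers drawn from populated regions of the plot (alpha-helix,
# beta-sheet, left-handed helix, polyproline-II, extended, and the bridge
# region between helix and sheet).
DEFAULT_BASINS = {
    "helix": (-60.0, -45.0, 10.0),
    "sheet": (-120.0, 130.0, 10.0),
    "left": (60.0, 45.0, 10.0),
    "ppii": (-70.0, 150.0, 10.0),
    "extended": (-150.0, -60.0, 10.0),
    "bridge": (-90.0, 10.0, 10.0),
}

# Per-class mixture weights over the six basins, one dominant basin per class.
# Because each class owns its basin, the pooled mixture of a multi-label
# enzyme (the average of its classes' mixtures) stays distinguishable from
# every single class and from every other class pair.
DEFAULT_CLASS_MIXTURES = {
    x: tuple(0.85 if b == x - 1 else 0.03 for b in range(6)) for x in range(1, 7)
}

# One distinctive 10-mer motif per class, built from low-background-frequency
# residues so local alignment separates the classes cleanly.
DEFAULT_MOTIFS = {
    1: "WCWHHWCWHW",
    2: "MYMFFYMYFM",
    3: "HPHWWPHPWH",
    4: "CFCYYFCYFC",
    5: "WMWPPMWPMW",
    6: "YHYCCHYHCY",
}


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic dataset; seed-deterministic."""

    n_per_class: Sequence[int] = (50, 50, 50, 50, 50, 50)
    multi_label_fraction: float = 0.0
    #: probability over the number of extra labels for multi-label enzymes
    extra_label_distribution: Sequence[float] = (1.0,)  # P(1 extra), P(2 extra), ...
    class_mixtures: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIXTURES)
    )
    basins: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BASINS)
    )
    sequence_length_range: tuple[int, int] = (80, 160)
    motifs: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    #: background amino-acid distribution; None = uniform over the 20 residues
    background_frequencies: Sequence[float] | None = None
    n_residues_range: tuple[int, int] = (60, 120)
    scramble_motifs: bool = False
    randomize_torsions: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_class) != 6 or any(n < 0 for n in self.n_per_class):
            raise ValueError("n_per_class must be six non-negative counts")
        if not 0.0 <= self.multi_label_fraction <= 1.0:
            raise ValueError("multi_label_fraction must lie in [0, 1]")
        for x, w in self.class_mixtures.items():
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"mixture weights of class {x} do not sum to 1")
        if self.sequence_length_range[0] < max(len(m) for m in self.motifs.values()) * 4:
            raise ValueError("sequences too short to carry up to four motifs")


@dataclass
class SyntheticDataset:
    """In-memory synthetic dataset: structures, sequences and labels."""

    structures: list[ProteinStructure]
    sequences: list[SequenceRecord]
    labels: pd.DataFrame  # index: enzyme id, columns: EC1..EC6 (0/1)

    def __len__(self) -> int:
        return len(self.structures)

    @property
    def label_matrix(self) -> np.ndarray:
        return self.labels.to_numpy(dtype=int)


def _place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond_length: float, bond_angle: float, torsion: float,
) -> np.ndarray:
    """NeRF: position d so that |cd| = bond_length, angle(b,c,d) = bond_angle
    and dihedral(a,b,c,d) = torsion (degrees)."""
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def build_backbone_from_torsions(
    phi_psi: TorsionAngleSet | np.ndarray,
    n_residues: int,
    structure_id: str = "synthetic",
    residue_name: str = "ALA",
) -> ProteinStructure:
    """Build an ideal-geometry backbone realizing the prescribed torsions.

    ``phi_psi`` holds the (phi, psi) pairs of the n_residues - 2 interior
    residues (the first residue has no phi, the last no psi). Recomputing
    torsions from the returned structure recovers the prescription.
    """
    pairs = np.asarray(getattr(phi_psi, "pairs", phi_psi), dtype=float).reshape(-1, 2)
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if len(pairs) != n_residues - 2:
        raise ValueError(
            f"expected {n_residues - 2} torsion pairs for {n_residues} residues, "
            f"got {len(pairs)}"
        )
    # terminal torsions are geometrically free; fixed to helix-like values
    psi = np.concatenate([[-45.0], pairs[:, 1]])  # psi_1 .. psi_{n-1}
    phi = np.concatenate([pairs[:, 0], [-60.0]])  # phi_2 .. phi_n

    coords: list[np.ndarray] = [
        np.zeros(3),  # N1
        np.array([BOND_N_CA, 0.0, 0.0]),  # CA1
    ]
    theta = np.radians(ANGLE_N_CA_C)
    coords.append(
        coords[1] + BOND_CA_C * np.array([-np.cos(theta), np.sin(theta), 0.0])
    )  # C1
    for i in range(1, n_residues):
        # N(i+1): torsion psi_i about CA(i)-C(i)
        coords.append(
            _place_atom(coords[-3], coords[-2], coords[-1], BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        )
        # CA(i+1): torsion omega about C(i)-N(i+1)
        coords.append(
            _place_atom(coords[-3], coords[-2], coords[-1], BOND_N_CA, ANGLE_C_N_CA, OMEGA)
        )
        # C(i+1): torsion phi_{i+1} about N(i+1)-CA(i+1)
        coords.append(
            _place_atom(coords[-3], coords[-2], coords[-1], BOND_CA_C, ANGLE_N_CA_C, phi[i - 1])
        )
    residues = [
        Residue(
            residue_name,
            i + 1,
            {
                "N": coords[3 * i],
                "CA": coords[3 * i + 1],
                "C": coords[3 * i + 2],
            },
        )
        for i in range(n_residues)
    ]
    return ProteinStructure(structure_id, [Chain("A", residues)])


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write a minimal PDB file (ATOM/TER/END, wwPDB fixed-width columns)."""
    lines = []
    serial = 1
    for chain in structure.chains:
        for res in chain.residues:
            for name in ("N", "CA", "C"):
                if name not in res.atoms:
                    continue
                x, y, z = res.atoms[name]
                lines.append(
                    f"ATOM  {serial:>5} {name:^4} {res.name:<3} {chain.chain_id}"
                    f"{res.seq_position:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
                    f"{1.0:6.2f}{0.0:6.2f}          {name[0]:>2}  "
                )
                serial += 1
        lines.append(f"TER   {serial:>5}      {chain.residues[-1].name:<3} "
                     f"{chain.chain_id}{chain.residues[-1].seq_position:>4}")
        serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def _sample_torsions(
    rng: np.random.Generator,
    n_pairs: int,
    classes: Sequence[int],
    spec: SyntheticSpec,
) -> np.ndarray:
    """Draw (phi, psi) pairs from the pooled mixture of the carried classes."""
    if spec.randomize_torsions:
        return rng.uniform(-180.0, 179.999, size=(n_pairs, 2))
    basin_names = list(spec.basins)
    weights = np.mean([spec.class_mixtures[c] for c in classes], axis=0)
    choices = rng.choice(len(basin_names), size=n_pairs, p=weights)
    out = np.empty((n_pairs, 2))
    for i, bi in enumerate(choices):
        phi0, psi0, sd = spec.basins[basin_names[bi]]
        out[i, 0] = phi0 + rng.normal(0.0, sd)
        out[i, 1] = psi0 + rng.normal(0.0, sd)
    return np.clip(out, -180.0, 179.999)


def _sample_sequence(
    rng: np.random.Generator,
    classes: Sequence[int],
    spec: SyntheticSpec,
) -> str:
    lo, hi = spec.sequence_length_range
    length = int(rng.integers(lo, hi + 1))
    p = spec.background_frequencies
    seq = list(rng.choice(list(AMINO_ACIDS), size=length, p=p))
    # non-overlapping motif slots, one per carried class
    slots = sorted(classes)
    motif_lens = [len(spec.motifs[c]) for c in slots]
    positions: list[int] = []
    taken: list[tuple[int, int]] = []
    for mlen in motif_lens:
        for _ in range(200):
            pos = int(rng.integers(0, length - mlen + 1))
            if all(pos + mlen <= s or pos >= e for s, e in taken):
                break
        positions.append(pos)
        taken.append((pos, pos + mlen))
    for c, pos in zip(slots, positions):
        if spec.scramble_motifs:
            # degrade the sequence modality: insert a motif drawn at random,
            # decoupling motif identity from the carried class
            c = int(rng.integers(1, 7))
        motif = spec.motifs[c]
        seq[pos : pos + len(motif)] = list(motif)
    return "".join(seq)


def _sample_label_sets(rng: np.random.Generator, spec: SyntheticSpec) -> list[list[int]]:
    """One class set per enzyme; primary class counts follow n_per_class."""
    label_sets: list[list[int]] = []
    for c, n in zip(range(1, 7), spec.n_per_class):
        for _ in range(n):
            classes = [c]
            if rng.random() < spec.multi_label_fraction:
                n_extra = 1 + rng.choice(
                    len(spec.extra_label_distribution), p=spec.extra_label_distribution
                )
                others = [x for x in range(1, 7) if x != c]
                extra = rng.choice(others, size=min(n_extra, 5), replace=False)
                classes.extend(int(x) for x in extra)
            label_sets.append(sorted(classes))
    return label_sets


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the full paired dataset; fully determined by ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    label_sets = _sample_label_sets(rng, spec)
    structures: list[ProteinStructure] = []
    sequences: list[SequenceRecord] = []
    rows = np.zeros((len(label_sets), 6), dtype=int)
    ids = []
    for i, classes in enumerate(label_sets):
        enzyme_id = f"SYN{i:04d}"
        ids.append(enzyme_id)
        rows[i, [c - 1 for c in classes]] = 1
        n_res = int(rng.integers(*spec.n_residues_range))
        torsions = _sample_torsions(rng, n_res - 2, classes, spec)
        structures.append(
            build_backbone_from_torsions(torsions, n_res, structure_id=enzyme_id)
        )
        sequences.append(SequenceRecord(enzyme_id, _sample_sequence(rng, classes, spec)))
    labels = pd.DataFrame(rows, index=ids, columns=[f"EC{x}" for x in range(1, 7)])
    labels.index.name = "id"
    return SyntheticDataset(structures, sequences, labels)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write PDB files, a FASTA file and the label CSV under ``out_dir``."""
    out_dir = Path(out_dir)
    pdb_dir = out_dir / "pdb"
    pdb_dir.mkdir(parents=True, exist_ok=True)
    for structure in dataset.structures:
        write_pdb(structure, pdb_dir / f"{structure.id}.pdb")
    fasta = out_dir / "sequences.fasta"
    write_fasta(dataset.sequences, fasta)
    labels = out_dir / "labels.csv"
    dataset.labels.to_csv(labels)
    return {"pdb_dir": pdb_dir, "fasta": fasta, "labels": labels}
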