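"""Core molecular containers shared by every pipeline stage.

The pipeline deliberately carries a small, explicit structure model — atoms
with Cartesian coordinates in Angstrom, an integer formal charge per atom,
and an explicit bond table — because every downstream stage (binding-site
cutout, capping, the classical toy surface, engine job files) needs exactly
these fields and nothing else.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np

# record classes an atom can belong to
PROTEIN = "protein"
WATER = "water"
ION = "ion"
LIGAND = "ligand"
CAP = "cap"

WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "H2O"}
ION_RESNAMES = {"CA", "ZN", "MG", "NA", "K", "CL", "MN", "FE"}
ION_CHARGES = {"CA": 2, "ZN": 2, "MG": 2, "MN": 2, "FE": 2, "NA": 1, "K": 1, "CL": -1}

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# minimal periodic-table support: covalent radii (A) for bond perception and
# element validation; extend as needed
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "CL": 1.02, "BR": 1.20, "I": 1.39, "NA": 1.66, "K": 2.03,
    "CA": 1.76, "MG": 1.41, "ZN": 1.22, "MN": 1.39, "FE": 1.32, "B": 0.84,
    "SE": 1.20,
}

VALID_ELEMENTS = set(COVALENT_RADII)


def normalize_element(sym: str) -> str:
    """Canonical capitalization ('CL' -> 'Cl'); raises on unknown symbols."""
    s = sym.strip()
    if s.upper() not in VALID_ELEMENTS:
        raise ValueError(f"unknown element symbol {sym!r}")
    return s[:1].upper() + s[1:].lower()


@dataclass
class Atom:
    element: str
    name: str
    coords: np.ndarray  # (3,) Cartesian, Angstrom
    res_name: str = "UNK"
    res_seq: int = 1
    chain_id: str = "A"
    formal_charge: int = 0
    record_class: str = LIGAND

    def __post_init__(self) -> None:
        self.element = normalize_element(self.element)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.name!r}: coordinates must be 3 finite numbers")

    @property
    def is_heavy(self) -> bool:
        return self.element != "H"

    def copy(self) -> "Atom":
        return replace(self, coords=self.coords.copy())


ResidueKey = tuple[str, int]  # (chain id, residue sequence number)


@dataclass
class MolecularSystem:
    """Atoms, bonds and formal charges of a receptor, ligand or complex."""

    atoms: list[Atom] = field(default_factory=list)
    bonds: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, order)
    ss_elements: list[tuple[str, str, int, int]] = field(default_factory=list)
    # ss_elements: (kind 'helix'|'sheet', chain id, first res_seq, last res_seq)

    def __post_init__(self) -> None:
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bond ({i},{j}) references invalid atom indices")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float).reshape(len(self.atoms), 3)
        for a, x in zip(self.atoms, xyz):
            a.coords = x.copy()

    @property
    def total_charge(self) -> int:
        return int(sum(a.formal_charge for a in self.atoms))

    @property
    def heavy_indices(self) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.atoms) if a.is_heavy], dtype=int)

    def residues(self) -> dict[ResidueKey, list[int]]:
        """Ordered residue index: (chain, res_seq) -> atom indices, file order."""
        out: dict[ResidueKey, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault((a.chain_id, a.res_seq), []).append(i)
        return out

    def residue_class(self, key: ResidueKey) -> str:
        idx = self.residues()[key]
        return self.atoms[idx[0]].record_class

    def iter_protein_residues(self) -> Iterator[tuple[ResidueKey, list[int]]]:
        for key, idx in self.residues().items():
            if self.atoms[idx[0]].record_class == PROTEIN:
                yield key, idx

    def subset(self, indices: list[int]) -> "MolecularSystem":
        """New system with the given atoms (order preserved) and induced bonds."""
        index_map = {old: new for new, old in enumerate(indices)}
        atoms = [self.atoms[i].copy() for i in indices]
        bonds = [
            (index_map[i], index_map[j], o)
            for i, j, o in self.bonds
            if i in index_map and j in index_map
        ]
        return MolecularSystem(atoms=atoms, bonds=bonds, ss_elements=list(self.ss_elements))

    def merged_with(self, other: "MolecularSystem") -> "MolecularSystem":
        off = len(self.atoms)
        atoms = [a.copy() for a in self.atoms] + [a.copy() for a in other.atoms]
        bonds = list(self.bonds) + [(i + off, j + off, o) for i, j, o in other.bonds]
        return MolecularSystem(atoms=atoms, bonds=bonds, ss_elements=list(self.ss_elements))

    def copy(self) -> "MolecularSystem":
        return MolecularSystem(
            atoms=[a.copy() for a in self.atoms],
            bonds=list(self.bonds),
            ss_elements=list(self.ss_elements),
        )

    def content_hash(self) -> str:
        """Stable hash of geometry + composition, used as a cache key."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.round(self.coords, 6).tobytes())
        h.update(",".join(f"{a.element}{a.formal_charge}" for a in self.atoms).encode())
        h.update(str(sorted((min(i, j), max(i, j), o) for i, j, o in self.bonds)).encode())
        return h.hexdigest()


@dataclass
class DockedPose:
    """One docked conformation of one molecule state.

    A library molecule may be present as several states (protonation,
    chirality); each state contributes exactly one pose — its lowest
    docking-energy conformation.
    """

    state_id: str
    parent_id: str
    ligand: MolecularSystem
    docking_energy: float | None = None
    is_ligand: bool = False


@dataclass
class LibraryManifest:
    """state id -> (parent molecule id, ligand/decoy label)."""

    rows: dict[str, tuple[str, bool]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pass

    @classmethod
    def from_records(cls, records: list[tuple[str, str, str]]) -> "LibraryManifest":
        rows: dict[str, tuple[str, bool]] = {}
        for state_id, parent_id, label in records:
            if state_id in rows:
                raise ValueError(f"duplicate state id {state_id!r} in manifest")
            lab = label.strip().lower()
            if lab not in {"ligand", "decoy"}:
                raise ValueError(f"manifest label for {state_id!r} must be ligand/decoy, got {label!r}")
            rows[state_id] = (parent_id, lab == "ligand")
        return cls(rows=rows)

    def __contains__(self, state_id: str) -> bool:
        return state_id in self.rows

    def parent(self, state_id: str) -> str:
        return self.rows[state_id][0]

    def is_ligand(self, state_id: str) -> bool:
        return self.rows[state_id][1]


def perceive_bonds(system: MolecularSystem, scale: float = 1.25) -> None:
    """Distance-based covalent bond perception (in place; single bonds).

    Two atoms are bonded when their separation is below ``scale`` times the
    sum of covalent radii. Water/ion atoms never bond to other residues.
    """
    from scipy.spatial import cKDTree

    n = len(system.atoms)
    if n < 2:
        return
    xyz = system.coords
    radii = np.array([COVALENT_RADII[a.element.upper()] for a in system.atoms])
    tree = cKDTree(xyz)
    existing = {(min(i, j), max(i, j)) for i, j, _ in system.bonds}
    pairs = tree.query_pairs(r=scale * 2.1)
    for i, j in sorted(pairs):
        ai, aj = system.atoms[i], system.atoms[j]
        if ai.record_class == ION or aj.record_class == ION:
            continue
        if (ai.record_class == WATER or aj.record_class == WATER) and (
            (ai.chain_id, ai.res_seq) != (aj.chain_id, aj.res_seq)
        ):
            continue
        if ai.element == "H" and aj.element == "H":
            continue
        cut = scale * (radii[i] + radii[j])
        if np.linalg.norm(xyz[i] - xyz[j]) <= cut and (i, j) not in existing:
            system.bonds.append((i, j, 1))
            existing.add((i, j))
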