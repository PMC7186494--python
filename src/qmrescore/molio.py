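"""Reading and writing molecular structures and docked pose libraries.

PDB handling works directly on the fixed-column coordinate records so that
parse errors can name the offending line, element inference follows an
explicit rule table, and cap hydrogens survive a round trip via their
segment id. Pose libraries (SDF/MOL2) go through RDKit; the library manifest
is a required tab-separated sidecar (state_id, parent_id, label) because
collapsing protonation/chirality states to parent molecules needs an
explicit mapping.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    CAP,
    ION,
    ION_CHARGES,
    ION_RESNAMES,
    LIGAND,
    PROTEIN,
    STANDARD_AA,
    WATER,
    WATER_RESNAMES,
    Atom,
    DockedPose,
    LibraryManifest,
    MolecularSystem,
    perceive_bonds,
)

logger = logging.getLogger(__name__)

CAP_SEGID = "CAPH"

# Sidechain atoms that carry the formal charge of a charged residue, in
# order of preference; the last entry of each list is a fallback for
# reduced-alphabet models that only have a single pseudo-sidechain atom.
CHARGE_BEARER = {
    "ASP": ["OD2", "OD1", "CG", "CB"],
    "GLU": ["OE2", "OE1", "CD", "CB"],
    "LYS": ["NZ", "CE", "CB"],
    "ARG": ["NH2", "NH1", "CZ", "CB"],
}
RESIDUE_CHARGE = {"ASP": -1, "GLU": -1, "LYS": 1, "ARG": 1}

_TWO_LETTER = {"CL", "BR", "SE", "ZN", "MG", "NA", "FE", "MN"}


class ParseError(ValueError):
    pass


def infer_element(atom_name: str, res_name: str, is_het: bool) -> str:
    """Element from a PDB atom name when the element column is absent.

    Fixed rule table: (1) single-atom ion residues (resolves the classic
    ``CA`` ambiguity — carbon-alpha inside an amino acid, calcium in its own
    HETATM residue); (2) leading digits stripped, a leading H is hydrogen;
    (3) known two-letter symbols; (4) first alphabetic character.
    """
    res = res_name.strip().upper()
    name = atom_name.strip().upper()
    if is_het and res in ION_RESNAMES and name == res:
        return res[:1] + res[1:].lower()
    stripped = name.lstrip("0123456789")
    if not stripped:
        raise ParseError(f"cannot infer element for atom name {atom_name!r}")
    if stripped[0] == "H":
        return "H"
    if stripped[:2] in {"CL", "BR"}:
        return stripped[0] + stripped[1].lower()
    return stripped[0]


def _classify(res_name: str, is_het: bool, element: str) -> str:
    res = res_name.strip().upper()
    if res in WATER_RESNAMES:
        return WATER
    if is_het and res in ION_RESNAMES and element.upper() in ION_RESNAMES:
        return ION
    if is_het:
        return LIGAND
    return PROTEIN


def read_pdb(path: str | Path) -> MolecularSystem:
    """Read a PDB v3 coordinate file into a :class:`MolecularSystem`.

    ATOM/HETATM, CONECT, HELIX and SHEET records are honored; peptide bonds
    between consecutive residues and intra-residue bonds are perceived from
    geometry. Waters and ions are classified by residue name.
    """
    path = Path(path)
    atoms: list[Atom] = []
    serial_to_index: dict[int, int] = {}
    conect: list[tuple[int, int]] = []
    ss: list[tuple[str, str, int, int]] = []
    cap_flags: list[bool] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in {"ATOM", "HETATM"}:
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    res_name = line[17:20].strip()
                    chain = line[21].strip() or "A"
                    res_seq = int(line[22:26])
                    xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
                except (ValueError, IndexError) as exc:
                    raise ParseError(f"{path.name}, line {lineno}: malformed {rec} record ({exc})")
                elem_field = line[76:78].strip() if len(line) >= 78 else ""
                is_het = rec == "HETATM"
                if elem_field:
                    element = elem_field
                else:
                    element = infer_element(name, res_name, is_het)
                charge = 0
                if len(line) >= 80:
                    cf = line[78:80].strip()
                    if cf:
                        digits = cf.rstrip("+-")
                        sign = -1 if cf.endswith("-") else 1
                        charge = sign * int(digits or "1")
                segid = line[72:76].strip() if len(line) >= 76 else ""
                cls = CAP if segid == CAP_SEGID else _classify(res_name, is_het, element)
                try:
                    atom = Atom(element, name, np.array(xyz), res_name, res_seq, chain, charge, cls)
                except ValueError as exc:
                    raise ParseError(f"{path.name}, line {lineno}: {exc}")
                serial_to_index[serial] = len(atoms)
                atoms.append(atom)
                cap_flags.append(cls == CAP)
            elif rec == "CONECT":
                fields = [line[i : i + 5].strip() for i in range(6, 27, 5)]
                nums = [int(f) for f in fields if f]
                if len(nums) >= 2:
                    conect.extend((nums[0], other) for other in nums[1:])
            elif rec == "HELIX":
                try:
                    ss.append(("helix", line[19].strip() or "A", int(line[21:25]), int(line[33:37])))
                except ValueError:
                    pass
            elif rec == "SHEET":
                try:
                    ss.append(("sheet", line[21].strip() or "A", int(line[22:26]), int(line[33:37])))
                except ValueError:
                    pass

    system = MolecularSystem(atoms=atoms, ss_elements=ss)
    seen = set()
    for a, b in conect:
        if a in serial_to_index and b in serial_to_index:
            i, j = serial_to_index[a], serial_to_index[b]
            key = (min(i, j), max(i, j))
            if i != j and key not in seen:
                system.bonds.append((key[0], key[1], 1))
                seen.add(key)
    _perceive_residue_bonds(system)
    return system


read_receptor = read_pdb


def _perceive_residue_bonds(system: MolecularSystem) -> None:
    """Intra-residue bonds by distance plus peptide bonds between
    consecutive residues of the same chain (C_i-N_{i+1} under 2.0 A)."""
    residues = system.residues()
    keys = list(residues)
    existing = {(min(i, j), max(i, j)) for i, j, _ in system.bonds}

    for idx in residues.values():
        sub = system.subset(idx)
        perceive_bonds(sub)
        for si, sj, o in sub.bonds:
            key = (min(idx[si], idx[sj]), max(idx[si], idx[sj]))
            if key not in existing:
                system.bonds.append((key[0], key[1], o))
                existing.add(key)

    for (ka, ia), (kb, ib) in zip(
        [(k, residues[k]) for k in keys], [(k, residues[k]) for k in keys[1:]]
    ):
        if ka[0] != kb[0]:
            continue
        if system.atoms[ia[0]].record_class != PROTEIN or system.atoms[ib[0]].record_class != PROTEIN:
            continue
        c = next((i for i in ia if system.atoms[i].name == "C"), None)
        n = next((i for i in ib if system.atoms[i].name == "N"), None)
        if c is None or n is None:
            continue
        if np.linalg.norm(system.atoms[c].coords - system.atoms[n].coords) < 2.0:
            key = (min(c, n), max(c, n))
            if key not in existing:
                system.bonds.append((key[0], key[1], 1))
                existing.add(key)


def write_pdb(system: MolecularSystem, path: str | Path) -> None:
    """Write ATOM/HETATM (+CONECT for non-peptide bonds); caps carry the
    dedicated segment id so they survive a round trip."""
    lines = []
    for i, a in enumerate(system.atoms):
        het = a.record_class in {WATER, ION, LIGAND}
        rec = "HETATM" if het else "ATOM  "
        name = a.name if len(a.name) == 4 else f" {a.name}"
        charge = ""
        if a.formal_charge:
            charge = f"{abs(a.formal_charge)}{'+' if a.formal_charge > 0 else '-'}"
        segid = CAP_SEGID if a.record_class == CAP else ""
        lines.append(
            f"{rec}{i + 1:>5} {name:<4} {a.res_name:<3} {a.chain_id:>1}{a.res_seq:>4}    "
            f"{a.coords[0]:8.3f}{a.coords[1]:8.3f}{a.coords[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
            f"      {segid:<4}{a.element.upper():>2}{charge:<2}"
        )
    residues = system.residues()
    res_of = {}
    for key, idx in residues.items():
        for i in idx:
            res_of[i] = key
    for i, j, _ in sorted(system.bonds):
        # peptide/intra-residue bonds are re-perceived on read; only record
        # bonds that distance perception cannot recover is not knowable here,
        # so emit CONECT for ligand/cap bonds to be safe
        if system.atoms[i].record_class in {LIGAND, CAP} or system.atoms[j].record_class in {LIGAND, CAP}:
            lines.append(f"CONECT{i + 1:>5}{j + 1:>5}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def write_xyz(system: MolecularSystem, path: str | Path, comment: str = "") -> None:
    lines = [str(len(system.atoms)), comment]
    for a in system.atoms:
        lines.append(f"{a.element:<2} {a.coords[0]:14.6f} {a.coords[1]:14.6f} {a.coords[2]:14.6f}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# pose libraries (SDF / MOL2) via RDKit


def _require_rdkit():
    from rdkit import Chem  # noqa: F401

    return Chem


def mol_to_system(mol, record_class: str = LIGAND) -> MolecularSystem:
    conf = mol.GetConformer()
    atoms = []
    for i, at in enumerate(mol.GetAtoms()):
        pos = conf.GetAtomPosition(i)
        atoms.append(
            Atom(
                at.GetSymbol(),
                f"{at.GetSymbol()}{i + 1}",
                np.array([pos.x, pos.y, pos.z]),
                res_name="LIG",
                res_seq=1,
                chain_id="X",
                formal_charge=at.GetFormalCharge(),
                record_class=record_class,
            )
        )
    bonds = []
    for b in mol.GetBonds():
        order = int(b.GetBondTypeAsDouble()) or 1
        bonds.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    return MolecularSystem(atoms=atoms, bonds=bonds)


def system_to_mol(system: MolecularSystem):
    Chem = _require_rdkit()
    from rdkit.Geometry import Point3D

    mol = Chem.RWMol()
    for a in system.atoms:
        at = Chem.Atom(a.element)
        at.SetFormalCharge(a.formal_charge)
        at.SetNoImplicit(True)
        mol.AddAtom(at)
    for i, j, order in system.bonds:
        bt = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE, 3: Chem.BondType.TRIPLE}.get(order, Chem.BondType.SINGLE)
        mol.AddBond(i, j, bt)
    conf = Chem.Conformer(len(system.atoms))
    for i, a in enumerate(system.atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, a.coords)))
    mol.AddConformer(conf)
    return mol.GetMol()


def read_poses(path: str | Path, manifest: LibraryManifest) -> list[DockedPose]:
    """Read an SDF or MOL2 pose library; every record must have a manifest row."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in {".sdf", ".sd", ".mol"}:
        records = _read_sdf_records(path)
    elif suffix == ".mol2":
        records = _read_mol2_records(path)
    else:
        raise ParseError(f"unsupported pose library format {suffix!r}")

    poses = []
    for state_id, mol, de in records:
        if mol is None or mol.GetNumAtoms() == 0:
            raise ParseError(f"pose record {state_id!r} in {path.name} has no atoms")
        if state_id not in manifest:
            raise ParseError(f"pose record {state_id!r} has no manifest row")
        poses.append(
            DockedPose(
                state_id=state_id,
                parent_id=manifest.parent(state_id),
                ligand=mol_to_system(mol),
                docking_energy=de,
                is_ligand=manifest.is_ligand(state_id),
            )
        )
    return poses


def _read_sdf_records(path: Path):
    Chem = _require_rdkit()
    out = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        for mol in supplier:
            if mol is None:
                raise ParseError(f"unparseable SDF record in {path.name}")
            name = mol.GetProp("_Name") if mol.HasProp("_Name") else ""
            de = None
            for tag in ("docking_energy", "DE"):
                if mol.HasProp(tag):
                    de = float(mol.GetProp(tag))
                    break
            out.append((name.strip(), mol, de))
    return out


def _read_mol2_records(path: Path):
    Chem = _require_rdkit()
    text = Path(path).read_text()
    blocks = text.split("@<TRIPOS>MOLECULE")
    out = []
    for block in blocks[1:]:
        body = "@<TRIPOS>MOLECULE" + block
        name = block.strip().splitlines()[0].strip()
        mol = Chem.MolFromMol2Block(body, sanitize=False, removeHs=False)
        if mol is None:
            raise ParseError(f"unparseable MOL2 record {name!r} in {path.name}")
        # MOL2 carries partial charges, not formal ones; without explicit
        # hydrogens RDKit's valence-based guess is unreliable, so formal
        # charges default to neutral (poses needing charges should use SDF)
        for at in mol.GetAtoms():
            at.SetFormalCharge(0)
        out.append((name, mol, None))
    return out


def write_sdf(poses: list[DockedPose], path: str | Path) -> None:
    Chem = _require_rdkit()
    with Chem.SDWriter(str(path)) as writer:
        writer.SetKekulize(False)
        for pose in poses:
            mol = system_to_mol(pose.ligand)
            mol.SetProp("_Name", pose.state_id)
            if pose.docking_energy is not None:
                mol.SetProp("docking_energy", f"{pose.docking_energy:.4f}")
            writer.write(mol)


# ---------------------------------------------------------------------------
# manifest


def read_manifest(path: str | Path) -> LibraryManifest:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"state_id", "parent_id", "label"}
    if not required.issubset(df.columns):
        raise ParseError(f"manifest must have columns {sorted(required)}, got {list(df.columns)}")
    return LibraryManifest.from_records(list(df[["state_id", "parent_id", "label"]].itertuples(index=False, name=None)))


def write_manifest(manifest: LibraryManifest, path: str | Path) -> None:
    rows = [
        {"state_id": sid, "parent_id": pid, "label": "ligand" if lig else "decoy"}
        for sid, (pid, lig) in manifest.rows.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# formal charges and environment selection


def assign_formal_charges(
    system: MolecularSystem, charge_termini: bool = False
) -> MolecularSystem:
    """Assign formal charges by residue rule: Asp/Glu -1, Arg/Lys +1, His 0.

    Ions get their nominal charges (Ca2+, Na+, Cl-, ...); waters are
    neutral; ligand-class atoms keep the charges that came with the pose
    record. Chain termini are neutral unless ``charge_termini``. Idempotent:
    charges are recomputed, not accumulated.
    """
    out = system.copy()
    residues = out.residues()
    chain_first_last: dict[str, tuple] = {}
    for key, idx in residues.items():
        if out.atoms[idx[0]].record_class == PROTEIN:
            chain = key[0]
            if chain not in chain_first_last:
                chain_first_last[chain] = (key, key)
            else:
                chain_first_last[chain] = (chain_first_last[chain][0], key)

    for key, idx in residues.items():
        cls = out.atoms[idx[0]].record_class
        res_name = out.atoms[idx[0]].res_name.upper()
        if cls == WATER:
            for i in idx:
                out.atoms[i].formal_charge = 0
        elif cls == ION:
            for i in idx:
                out.atoms[i].formal_charge = ION_CHARGES.get(out.atoms[i].element.upper(), 0)
        elif cls == PROTEIN:
            for i in idx:
                out.atoms[i].formal_charge = 0
            if res_name in RESIDUE_CHARGE:
                bearer = _charge_bearer_index(out, idx, res_name)
                out.atoms[bearer].formal_charge = RESIDUE_CHARGE[res_name]
            elif res_name not in STANDARD_AA:
                logger.warning("no charge rule for residue %s %s; assigned 0", res_name, key)
            if charge_termini:
                first, last = chain_first_last[key[0]]
                if key == first:
                    n = next((i for i in idx if out.atoms[i].name == "N"), idx[0])
                    out.atoms[n].formal_charge += 1
                if key == last:
                    c = next(
                        (i for i in idx if out.atoms[i].name in {"OXT", "O"}), idx[-1]
                    )
                    out.atoms[c].formal_charge += -1
        # ligand and cap classes untouched
    return out


def _charge_bearer_index(system: MolecularSystem, idx: list[int], res_name: str) -> int:
    names = {system.atoms[i].name: i for i in idx}
    for candidate in CHARGE_BEARER[res_name]:
        if candidate in names:
            return names[candidate]
    return idx[-1]


def select_environment(
    receptor: MolecularSystem,
    reference_ligand: MolecularSystem | None,
    water_cutoff: float = 4.0,
    ion_cutoff: float = 8.0,
) -> MolecularSystem:
    """Keep only waters/ions near the reference ligand (heavy-atom minima).

    Retention radii default to 4 A for waters and 8 A for ions; protein
    atoms pass through untouched. Without a reference ligand all waters and
    ions are dropped (with a warning).
    """
    if water_cutoff <= 0 or ion_cutoff <= 0:
        raise ValueError("cutoffs must be positive")
    ref_heavy = None
    if reference_ligand is not None and len(reference_ligand.atoms):
        hi = reference_ligand.heavy_indices
        if len(hi):
            ref_heavy = reference_ligand.coords[hi]
    if ref_heavy is None:
        logger.warning("no reference ligand: dropping all waters and ions")

    keep: list[int] = []
    for key, idx in receptor.residues().items():
        cls = receptor.atoms[idx[0]].record_class
        if cls not in {WATER, ION}:
            keep.extend(idx)
            continue
        if ref_heavy is None:
            continue
        cutoff = water_cutoff if cls == WATER else ion_cutoff
        heavy = [i for i in idx if receptor.atoms[i].is_heavy]
        if not heavy:
            continue
        xyz = np.array([receptor.atoms[i].coords for i in heavy])
        dmin = np.min(np.linalg.norm(xyz[:, None, :] - ref_heavy[None, :, :], axis=2))
        if dmin <= cutoff:
            keep.extend(idx)
    return receptor.subset(keep)
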