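"""Desk-scale synthetic fixtures: toy pockets, pose libraries, ranked lists.

Real benchmarks for this kind of rescoring need curated ligand/decoy
libraries, a docking program, and hours of engine time. The generators
here stand in for all of that at test scale:

* a mini-protein "pocket" — simplified residues (backbone N/CA/C/O plus a
  single pseudo-sidechain CB atom) laid out along a spherical shell, the
  charged residues ringing the cavity the way polar binding sites do;
* a pose library with designed energetic separation — ligands are placed
  charge- and shape-complementary to the rim (their interaction energy on
  the toy surface is lower by a controlled margin), decoys match the
  ligands in atom count and net charge but sit with mismatched geometry;
  a few molecules are emitted as two protonation-like states to exercise
  state collapsing, and one pose deliberately clashes with the pocket to
  exercise failure handling;
* binormal score/label vectors with a prescribed expected AUC, used as
  oracles for the screening metrics.

Everything is deterministic per seed and flows through the same public
formats (PDB/SDF + manifest TSV) as real data.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

from .core import LIGAND, Atom, DockedPose, LibraryManifest, MolecularSystem
from .molio import _perceive_residue_bonds, assign_formal_charges

RESIDUE_CYCLE = ("ASP", "ALA", "LYS", "SER", "GLU", "ALA", "ARG", "SER")
CA_STEP = 4.2  # A along the shell; keeps perceived peptide bonds intact
N_CA = 1.47
CA_C = 1.53
C_O = 1.23
CA_CB = 1.53
ZIGZAG = np.radians(25.0)  # backbone pitch off the chain tangent


def make_toy_pocket(
    seed: int = 0, n_residues: int = 30, pocket_radius: float = 8.0
) -> MolecularSystem:
    """Mini-protein shell around the origin with a charged rim.

    Backbone atoms run along a spherical spiral of the given radius; each
    pseudo-sidechain CB points inward so the charge rule's charges face
    the cavity. Deterministic per seed (seed moves the spiral phase and
    adds a small coordinate jitter).
    """
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi)
    theta0, theta1 = np.radians(55.0), np.radians(125.0)

    # walk the spiral with constant target chord, then project to the shell
    ca = []
    theta = theta0
    phi = phase
    for k in range(n_residues):
        ca.append(
            pocket_radius
            * np.array(
                [np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi), np.cos(theta)]
            )
        )
        dtheta = (theta1 - theta0) / max(n_residues - 1, 1)
        arc_polar = pocket_radius * dtheta
        arc_az = np.sqrt(max(CA_STEP**2 - arc_polar**2, 0.25))
        phi += arc_az / (pocket_radius * np.sin(theta))
        theta += dtheta
    ca = np.array(ca)
    ca += rng.normal(scale=0.04, size=ca.shape)

    atoms: list[Atom] = []
    for k in range(n_residues):
        res_name = RESIDUE_CYCLE[k % len(RESIDUE_CYCLE)]
        res_seq = k + 1
        incoming = ca[k] - ca[k - 1] if k > 0 else ca[1] - ca[0]
        outgoing = ca[k + 1] - ca[k] if k < n_residues - 1 else ca[-1] - ca[-2]
        incoming = incoming / np.linalg.norm(incoming)
        outgoing = outgoing / np.linalg.norm(outgoing)
        radial = ca[k] / np.linalg.norm(ca[k])

        def add(element, name, xyz):
            atoms.append(
                Atom(element, name, xyz, res_name=res_name, res_seq=res_seq,
                     chain_id="A", record_class="protein")
            )

        # zig-zag off the chain tangent keeps backbone angles bent, so
        # torsion coordinates through N-CA-C are always well defined
        n_dir = np.cos(ZIGZAG) * incoming + np.sin(ZIGZAG) * radial
        c_dir = np.cos(ZIGZAG) * outgoing + np.sin(ZIGZAG) * radial
        n_dir /= np.linalg.norm(n_dir)
        c_dir /= np.linalg.norm(c_dir)
        add("N", "N", ca[k] - N_CA * n_dir)
        add("C", "CA", ca[k])
        add("C", "C", ca[k] + CA_C * c_dir)
        add("O", "O", ca[k] + CA_C * c_dir + C_O * radial)
        add("C", "CB", ca[k] - CA_CB * radial)

    system = MolecularSystem(atoms=atoms)
    _perceive_residue_bonds(system)
    return system


def _rigid_star(center: np.ndarray, orient: np.ndarray, charge: int,
                extra_h: bool = False) -> MolecularSystem:
    """Small rigid molecule: central carbon with four 1.4 A substituents,
    the charged nitrogen/oxygen pointing along ``orient``. No rotatable
    bonds, so its conformational entropy term is exactly zero."""
    orient = orient / np.linalg.norm(orient)
    # orthonormal frame around the orientation axis
    ref = np.array([0.0, 0.0, 1.0]) if abs(orient[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    u = np.cross(orient, ref)
    u /= np.linalg.norm(u)
    v = np.cross(orient, u)
    atoms = [Atom("C", "C1", center, res_name="LIG", chain_id="X", record_class=LIGAND)]
    head = "N" if charge >= 0 else "O"
    atoms.append(
        Atom(head, f"{head}2", center + 1.4 * orient, res_name="LIG", chain_id="X",
             formal_charge=charge, record_class=LIGAND)
    )
    atoms.append(Atom("C", "C3", center - 1.4 * orient, res_name="LIG", chain_id="X",
                      record_class=LIGAND))
    atoms.append(Atom("O", "O4", center + 1.4 * u, res_name="LIG", chain_id="X",
                      record_class=LIGAND))
    atoms.append(Atom("C", "C5", center + 1.4 * v, res_name="LIG", chain_id="X",
                      record_class=LIGAND))
    bonds = [(0, 1, 1), (0, 2, 1), (0, 3, 1), (0, 4, 1)]
    if extra_h:
        atoms.append(Atom("H", "H6", center - 1.0 * u, res_name="LIG", chain_id="X",
                          record_class=LIGAND))
        bonds.append((0, len(atoms) - 1, 1))
    return MolecularSystem(atoms=atoms, bonds=bonds)


def make_library(
    pocket: MolecularSystem,
    seed: int = 0,
    n_ligands: int = 20,
    n_decoys: int = 180,
    margin: float = 5.0,
    n_dual_state: int = 3,
    include_clash: bool = True,
) -> tuple[list[DockedPose], LibraryManifest]:
    """Pose library with designed energetic separation.

    Ligand poses park their charged head a Lennard-Jones-minimum distance
    from an oppositely charged rim atom; decoy poses have the same atom
    count and net charge but aim at a like-charged rim atom from farther
    out, so on the toy surface the mean ligand interaction energy is lower
    than the decoy mean by at least ``margin`` (checked by the tests). The
    first ``n_dual_state`` ligands and decoys are emitted as two
    protonation-like states; one decoy pose deliberately clashes with the
    pocket to exercise failed-job handling.
    """
    rng = np.random.default_rng(seed)
    charged = assign_formal_charges(pocket)
    rim = [(i, a.formal_charge) for i, a in enumerate(charged.atoms) if a.formal_charge]
    neg_rim = [i for i, q in rim if q < 0]
    pos_rim = [i for i, q in rim if q > 0]
    if not neg_rim or not pos_rim:
        raise ValueError("pocket has no charged rim; cannot design a library")
    xyz = charged.coords

    poses: list[DockedPose] = []
    manifest_rows: list[tuple[str, str, str]] = []

    def place(target_idx: int, head_charge: int, head_distance: float,
              jitter: float) -> tuple[np.ndarray, np.ndarray]:
        site = xyz[target_idx]
        inward = -site / np.linalg.norm(site)  # toward the cavity center
        head = site + head_distance * inward + rng.normal(scale=jitter, size=3)
        center = head + 1.4 * inward
        return center, -inward  # orient the head back toward the rim atom

    for m in range(n_ligands):
        parent = f"lig{m:03d}"
        head_charge = 1 if m % 2 == 0 else -1
        target = neg_rim[m % len(neg_rim)] if head_charge > 0 else pos_rim[m % len(pos_rim)]
        n_states = 2 if m < n_dual_state else 1
        for s in range(n_states):
            center, orient = place(target, head_charge, 3.4 + 0.15 * s, 0.08)
            mol = _rigid_star(center, orient, head_charge, extra_h=(s == 1))
            sid = f"{parent}_s{s + 1}"
            poses.append(DockedPose(sid, parent, mol, is_ligand=True))
            manifest_rows.append((sid, parent, "ligand"))

    clash_assigned = False
    for m in range(n_decoys):
        parent = f"dec{m:03d}"
        head_charge = 1 if m % 2 == 0 else -1
        # aimed at a like-charged rim atom: the contact that stabilizes a
        # ligand is repulsive here, so the interaction energy sits higher
        target = pos_rim[m % len(pos_rim)] if head_charge > 0 else neg_rim[m % len(neg_rim)]
        # the repulsive contact scales like 1/r^2, so the designed mean
        # separation grows with the requested margin as the head moves in
        contact = float(np.clip(3.4 * np.sqrt(5.0 / margin), 2.4, 4.5))
        n_states = 2 if m < n_dual_state else 1
        for s in range(n_states):
            center, orient = place(target, head_charge, contact + 0.15 * s, 0.2)
            mol = _rigid_star(center, orient, head_charge, extra_h=(s == 1))
            sid = f"{parent}_s{s + 1}"
            if include_clash and not clash_assigned and m == n_decoys - 1:
                # overlap the head with the rim atom: unphysical geometry
                shift = xyz[target] - mol.atoms[1].coords + np.array([0.05, 0.0, 0.0])
                for a in mol.atoms:
                    a.coords = a.coords + shift
                clash_assigned = True
            poses.append(DockedPose(sid, parent, mol, is_ligand=False))
            manifest_rows.append((sid, parent, "decoy"))

    return poses, LibraryManifest.from_records(manifest_rows)


def make_torsion_chain(n_rotatable: int) -> MolecularSystem:
    """Unbranched carbon chain with exactly ``n_rotatable`` free torsions.

    Bonds at 1.53 A and tetrahedral angles, started all-anti. On the toy
    surface each internal torsion sees the 3-fold cosine term, so the
    molecule has about 3^N low-energy conformers — the landscape used to
    validate the Monte-Carlo entropy estimator against rotamer counting.
    """
    if n_rotatable < 0:
        raise ValueError("n_rotatable must be >= 0")
    n_atoms = n_rotatable + 3 if n_rotatable > 0 else 2
    bond, angle = 1.53, np.radians(109.47)
    coords = [np.zeros(3), np.array([bond, 0.0, 0.0])]
    direction_flip = 1.0
    for _ in range(2, n_atoms):
        prev, prev2 = coords[-1], coords[-2]
        axis = (prev - prev2) / np.linalg.norm(prev - prev2)
        # in-plane zig-zag: all-anti backbone
        perp = np.array([-axis[1], axis[0], 0.0])
        if np.linalg.norm(perp) < 1e-8:
            perp = np.array([0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        step = bond * (np.cos(np.pi - angle) * axis + np.sin(np.pi - angle) * perp * direction_flip)
        coords.append(prev + step)
        direction_flip *= -1.0
    atoms = [
        Atom("C", f"C{i + 1}", c, res_name="LIG", chain_id="X", record_class=LIGAND)
        for i, c in enumerate(coords)
    ]
    bonds = [(i, i + 1, 1) for i in range(n_atoms - 1)]
    return MolecularSystem(atoms=atoms, bonds=bonds)


def make_ranked_list(
    seed: int, n: int, auc_target: float, ligand_fraction: float = 0.1
) -> tuple[np.ndarray, np.ndarray]:
    """Score/label vectors from a binormal model with a prescribed AUC.

    Scores are lower-is-better; with ligand scores N(-mu, 1) and decoy
    scores N(0, 1), the expected AUC is Phi(mu / sqrt(2)), so
    mu = sqrt(2) * Phi^-1(AUC). AUC 1.0 yields disjoint supports.
    """
    if not (0.5 <= auc_target <= 1.0):
        raise ValueError("auc_target must be in [0.5, 1.0]")
    rng = np.random.default_rng(seed)
    n_lig = max(1, int(round(ligand_fraction * n)))
    labels = np.zeros(n, dtype=bool)
    labels[:n_lig] = True
    scores = np.empty(n)
    if auc_target >= 1.0:
        scores[labels] = rng.uniform(-12.0, -10.0, size=n_lig)
        scores[~labels] = rng.uniform(0.0, 2.0, size=n - n_lig)
    else:
        mu = np.sqrt(2.0) * norm.ppf(auc_target)
        scores[labels] = rng.normal(-mu, 1.0, size=n_lig)
        scores[~labels] = rng.normal(0.0, 1.0, size=n - n_lig)
    perm = rng.permutation(n)
    return scores[perm], labels[perm]
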