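"""Reduced binding-site systems for QM evaluation.

A full receptor is far too large for semi-empirical single points, so all
energies are evaluated on a binding-site cluster: every residue with a
heavy atom within a distance threshold (default 8 A) of any heavy atom of
any docked pose in the library, expanded to avoid fragmenting secondary
structure or leaving one-residue loop stubs, then cut out of the chain with
each severed peptide bond replaced by a cap hydrogen along the former bond
vector. One reduced system is built per target (the union over the whole
library) so the isolated-pocket energy is a shared reference across all
poses. Thresholds below ~6 A are known to degrade scoring, so the selection
warns when configured that tight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import CAP, ION, PROTEIN, WATER, Atom, DockedPose, MolecularSystem, ResidueKey

logger = logging.getLogger(__name__)

N_CAP_LENGTH = 1.01  # A, H replacing the preceding carbonyl C on a fragment N-terminus
C_CAP_LENGTH = 1.09  # A, H replacing the following amide N on a fragment C-terminus
MIN_RECOMMENDED_CUTOFF = 6.0


@dataclass
class ReducedSystem:
    """Capped binding-site cluster with provenance back to the receptor."""

    system: MolecularSystem
    fragments: list[tuple[str, list[int]]]  # (chain id, contiguous res_seq run)
    provenance: dict[int, int] = field(default_factory=dict)  # cluster idx -> receptor idx
    cap_provenance: dict[int, tuple[int, int]] = field(default_factory=dict)
    # cap cluster idx -> (retained receptor atom, removed receptor atom) of the severed bond

    @property
    def total_charge(self) -> int:
        return self.system.total_charge


def residues_within(
    receptor: MolecularSystem, poses: list[DockedPose], cutoff: float = 8.0
) -> set[ResidueKey]:
    """Protein residues with any heavy atom within ``cutoff`` of any heavy
    atom of any pose (union over the whole library); hydrogens are ignored
    on both sides."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if cutoff < MIN_RECOMMENDED_CUTOFF:
        logger.warning(
            "cutout threshold %.1f A is below %.1f A; small thresholds degrade scoring",
            cutoff,
            MIN_RECOMMENDED_CUTOFF,
        )
    if not poses:
        raise ValueError("residues_within requires at least one pose")

    pose_xyz = []
    for pose in poses:
        hi = pose.ligand.heavy_indices
        if len(hi):
            pose_xyz.append(pose.ligand.coords[hi])
    if not pose_xyz:
        raise ValueError("poses contain no heavy atoms")
    tree = cKDTree(np.vstack(pose_xyz))

    selected: set[ResidueKey] = set()
    for key, idx in receptor.residues().items():
        if receptor.atoms[idx[0]].record_class != PROTEIN:
            continue
        heavy = [i for i in idx if receptor.atoms[i].is_heavy]
        if not heavy:
            continue
        d, _ = tree.query(np.array([receptor.atoms[i].coords for i in heavy]))
        if np.min(d) <= cutoff:
            selected.add(key)
    return selected


def _chain_order(receptor: MolecularSystem) -> dict[str, list[int]]:
    """Residue sequence numbers per chain, file order (protein only)."""
    order: dict[str, list[int]] = {}
    for (chain, seq), idx in receptor.residues().items():
        if receptor.atoms[idx[0]].record_class == PROTEIN:
            order.setdefault(chain, []).append(seq)
    return order


def defragment(
    selected: set[ResidueKey],
    receptor: MolecularSystem,
    max_gap: int = 2,
    min_fragment: int = 2,
) -> set[ResidueKey]:
    """Expand a residue selection so the cutout has no awkward fragments.

    Gaps of at most ``max_gap`` residues between selected stretches on the
    same chain are filled; fragments shorter than ``min_fragment`` are
    extended by flanking residues (C-side preferred, N-side fallback); when
    helix/sheet annotations are present, a fragment boundary inside an
    annotated element is pushed out to the element boundary. Pure set
    expansion: output is always a superset of the input.
    """
    order = _chain_order(receptor)
    out = set(selected)

    for chain, seqs in order.items():
        pos_of = {s: p for p, s in enumerate(seqs)}
        sel_pos = sorted(pos_of[s] for c, s in out if c == chain and s in pos_of)
        if not sel_pos:
            continue
        # fill small gaps
        filled = set(sel_pos)
        for a, b in zip(sel_pos, sel_pos[1:]):
            if 1 < b - a <= max_gap + 1:
                filled.update(range(a + 1, b))
        # grow short fragments: C-side preferred, N-side fallback
        changed = True
        while changed:
            changed = False
            for frag in _runs(sorted(filled)):
                while len(frag) < min_fragment:
                    c_side = frag[-1] + 1
                    n_side = frag[0] - 1
                    if c_side < len(seqs) and c_side not in filled:
                        filled.add(c_side)
                        frag.append(c_side)
                    elif n_side >= 0 and n_side not in filled:
                        filled.add(n_side)
                        frag.insert(0, n_side)
                    else:
                        break
                    changed = True
        # snap fragment boundaries out of annotated secondary-structure elements
        for kind, ss_chain, first, last in receptor.ss_elements:
            if ss_chain != chain or first not in pos_of or last not in pos_of:
                continue
            lo, hi = pos_of[first], pos_of[last]
            for frag in _runs(sorted(filled)):
                overlaps = frag[0] <= hi and frag[-1] >= lo
                if not overlaps:
                    continue
                if lo < frag[0] <= hi:
                    filled.update(range(lo, frag[0]))
                if lo <= frag[-1] < hi:
                    filled.update(range(frag[-1] + 1, hi + 1))
        out.update((chain, seqs[p]) for p in filled)
    return out


def _runs(sorted_positions: list[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for p in sorted_positions:
        if runs and p == runs[-1][-1] + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    return runs


def build_reduced(receptor: MolecularSystem, selected: set[ResidueKey]) -> ReducedSystem:
    """Cut the selected residues (plus all retained waters/ions) out of the
    receptor and cap every severed backbone bond with a hydrogen.

    An N-terminal cut places H on the fragment's first backbone N at
    1.01 A along the former bond to the preceding carbonyl C; a C-terminal
    cut places H on the fragment's last carbonyl C at 1.09 A along the
    former bond to the following amide N.
    """
    if not selected:
        raise ValueError("selected residue set is empty")
    residues = receptor.residues()
    order = _chain_order(receptor)

    for key in sorted(selected):
        if key not in residues:
            raise ValueError(f"selected residue {key} not present in receptor")
        names = {receptor.atoms[i].name for i in residues[key]}
        missing = {"N", "CA", "C"} - names
        if missing:
            raise ValueError(
                f"residue {key} is missing backbone atoms {sorted(missing)}"
            )

    keep: list[int] = []
    for key, idx in residues.items():
        cls = receptor.atoms[idx[0]].record_class
        if cls in {WATER, ION} or key in selected:
            keep.extend(idx)

    cluster = receptor.subset(keep)
    provenance = {new: old for new, old in enumerate(keep)}
    rev = {old: new for new, old in provenance.items()}

    def backbone_atom(key: ResidueKey, name: str) -> int:
        for i in residues[key]:
            if receptor.atoms[i].name == name:
                return i
        raise ValueError(f"residue {key} is missing backbone atom {name}")

    fragments: list[tuple[str, list[int]]] = []
    cap_provenance: dict[int, tuple[int, int]] = {}
    cap_atoms: list[Atom] = []
    cap_bonds: list[tuple[int, int]] = []

    for chain, seqs in order.items():
        pos_sel = sorted(i for i, s in enumerate(seqs) if (chain, s) in selected)
        for frag in _runs(pos_sel):
            frag_seqs = [seqs[p] for p in frag]
            fragments.append((chain, frag_seqs))
            first_key = (chain, frag_seqs[0])
            last_key = (chain, frag_seqs[-1])
            # N-terminal cap when a preceding residue was cut away
            if frag[0] > 0:
                n_idx = backbone_atom(first_key, "N")
                prev_c = backbone_atom((chain, seqs[frag[0] - 1]), "C")
                cap_atoms.append(
                    _make_cap(receptor, n_idx, prev_c, N_CAP_LENGTH, first_key)
                )
                cap_bonds.append((rev[n_idx], len(cap_atoms) - 1))
                cap_provenance[len(cap_atoms) - 1] = (n_idx, prev_c)
            # C-terminal cap when a following residue was cut away
            if frag[-1] < len(seqs) - 1:
                c_idx = backbone_atom(last_key, "C")
                next_n = backbone_atom((chain, seqs[frag[-1] + 1]), "N")
                cap_atoms.append(
                    _make_cap(receptor, c_idx, next_n, C_CAP_LENGTH, last_key)
                )
                cap_bonds.append((rev[c_idx], len(cap_atoms) - 1))
                cap_provenance[len(cap_atoms) - 1] = (c_idx, next_n)

    n0 = len(cluster.atoms)
    for atom in cap_atoms:
        cluster.atoms.append(atom)
    for host, cap_local in cap_bonds:
        cluster.bonds.append((host, n0 + cap_local, 1))

    reduced = ReducedSystem(
        system=cluster,
        fragments=fragments,
        provenance=provenance,
        cap_provenance={n0 + k: v for k, v in cap_provenance.items()},
    )
    return reduced


def _make_cap(
    receptor: MolecularSystem, host: int, removed: int, length: float, key: ResidueKey
) -> Atom:
    host_atom = receptor.atoms[host]
    direction = receptor.atoms[removed].coords - host_atom.coords
    norm = np.linalg.norm(direction)
    if norm < 1e-9:
        raise ValueError(f"degenerate backbone geometry at residue {key}")
    return Atom(
        element="H",
        name="HCP",
        coords=host_atom.coords + length * direction / norm,
        res_name=host_atom.res_name,
        res_seq=host_atom.res_seq,
        chain_id=host_atom.chain_id,
        formal_charge=0,
        record_class=CAP,
    )


def write_fragment_report(reduced: ReducedSystem, path: str | Path) -> None:
    rows = [
        {
            "chain": chain,
            "first_res": seqs[0],
            "last_res": seqs[-1],
            "n_residues": len(seqs),
        }
        for chain, seqs in reduced.fragments
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
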