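"""Restrained local relaxation of docked complexes and unbound reference
states.

The relaxed-scoring path re-minimizes each docked complex before the QM
single points. Receptor flexibility is local: only residues within 4 A of
any docked molecule of the library (plus the ligand itself) move; everything
else is frozen in place. Five cycles of minimization are run with a
harmonic positional restraint on the movable *heavy* atoms whose weight is
stepped down 50, 10, 5, 1, 0 kcal/mol (the last cycle is unrestrained);
hydrogens are never restrained. Minimization happens on the classical toy
surface in all-Cartesian coordinates (a QM-level minimization would defeat
the throughput the score exists for), so a backend without gradients flags
the relaxation as failed rather than guessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .core import LIGAND, PROTEIN, DockedPose, MolecularSystem, ResidueKey

logger = logging.getLogger(__name__)

DEFAULT_WEIGHTS = (50.0, 10.0, 5.0, 1.0, 0.0)  # kcal mol^-1 A^-2
DEFAULT_GTOL = 1e-3  # kcal mol^-1 A^-1, gradient-norm tolerance
DEFAULT_MAXITER = 500


@dataclass
class RelaxResult:
    system: MolecularSystem
    cycle_energies: list[float] = field(default_factory=list)  # backend energy at cycle end
    failed: bool = False
    reason: str | None = None


def free_region(
    receptor: MolecularSystem, poses: list[DockedPose], cutoff: float = 4.0
) -> set[ResidueKey]:
    """Residues whose heavy atoms come within ``cutoff`` of any heavy atom
    of any docked pose in the library — these move during relaxation."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not poses:
        raise ValueError("free_region requires at least one pose")
    pose_xyz = np.vstack(
        [p.ligand.coords[p.ligand.heavy_indices] for p in poses if len(p.ligand.heavy_indices)]
    )
    tree = cKDTree(pose_xyz)
    out: set[ResidueKey] = set()
    for key, idx in receptor.residues().items():
        if receptor.atoms[idx[0]].record_class != PROTEIN:
            continue
        heavy = [i for i in idx if receptor.atoms[i].is_heavy]
        if not heavy:
            continue
        d, _ = tree.query(np.array([receptor.atoms[i].coords for i in heavy]))
        if np.min(d) <= cutoff:
            out.add(key)
    return out


def movable_atom_indices(
    complex_system: MolecularSystem, free_residues: set[ResidueKey]
) -> np.ndarray:
    """Atom indices allowed to move: all ligand atoms plus all atoms of the
    free protein residues."""
    out = [
        i
        for i, a in enumerate(complex_system.atoms)
        if a.record_class == LIGAND
        or (a.record_class == PROTEIN and (a.chain_id, a.res_seq) in free_residues)
    ]
    return np.array(out, dtype=int)


def restrained_relax(
    complex_system: MolecularSystem,
    backend,
    movable: np.ndarray,
    weights: tuple[float, ...] = DEFAULT_WEIGHTS,
    gtol: float = DEFAULT_GTOL,
    maxiter: int = DEFAULT_MAXITER,
    reset_reference: bool = True,
) -> RelaxResult:
    """Cyclic restrained minimization of the movable atoms.

    Objective per cycle: G_backend + w * sum over movable heavy atoms of
    |x - x_ref|^2, with x_ref the cycle-start coordinates (or the original
    coordinates when ``reset_reference`` is off). Frozen atoms never move.
    """
    if not getattr(backend, "supports_gradient", False):
        return RelaxResult(
            system=complex_system.copy(),
            failed=True,
            reason=f"backend {getattr(backend, 'name', '?')!r} provides no gradients",
        )
    movable = np.asarray(movable, dtype=int)
    if movable.size == 0:
        res = backend.single_point(complex_system)
        return RelaxResult(system=complex_system.copy(), cycle_energies=[res.total] * len(weights))

    work = complex_system.copy()
    heavy_mask = np.array([work.atoms[i].is_heavy for i in movable])
    restrained = movable[heavy_mask]  # hydrogens are never restrained

    xyz = work.coords
    x0_ref = xyz.copy()
    cycle_energies: list[float] = []
    for w in weights:
        x_ref = xyz.copy() if reset_reference else x0_ref

        def objective(flat: np.ndarray):
            full = xyz.copy()
            full[movable] = flat.reshape(-1, 3)
            e, g = backend.energy_and_gradient(work, full)
            disp = full[restrained] - x_ref[restrained]
            e += w * float(np.sum(disp * disp))
            g = g.copy()
            g[restrained] += 2.0 * w * disp
            return e, g[movable].ravel()

        result = minimize(
            objective,
            xyz[movable].ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
        )
        xyz = xyz.copy()
        xyz[movable] = result.x.reshape(-1, 3)
        e_plain, _ = backend.energy_and_gradient(work, xyz)
        cycle_energies.append(float(e_plain))

    work.set_coords(xyz)
    return RelaxResult(system=work, cycle_energies=cycle_energies)


def unbound_state(system: MolecularSystem, backend, gtol: float = DEFAULT_GTOL,
                  maxiter: int = DEFAULT_MAXITER) -> RelaxResult:
    """Unrestrained local minimization of an isolated protein or ligand,
    starting from the given conformation; its energy is the free-state
    reference entering the deformation terms."""
    if not getattr(backend, "supports_gradient", False):
        return RelaxResult(
            system=system.copy(),
            failed=True,
            reason=f"backend {getattr(backend, 'name', '?')!r} provides no gradients",
        )
    work = system.copy()

    def objective(flat: np.ndarray):
        e, g = backend.energy_and_gradient(work, flat.reshape(-1, 3))
        return e, g.ravel()

    result = minimize(
        objective,
        work.coords.ravel(),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter, "gtol": gtol, "ftol": 1e-12},
    )
    work.set_coords(result.x.reshape(-1, 3))
    return RelaxResult(system=work, cycle_energies=[float(result.fun)])
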