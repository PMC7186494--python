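"""Deterministic classical energy surface for desk-scale testing and
synthetic screens.

The functional form is a minimal molecular-mechanics surface with an
implicit-solvation term:

    G = sum_bonds k_b (r - r0)^2
      + sum_torsions (V3/2) (1 + cos 3*phi)
      + sum_nonbonded [ eps ((sigma/r)^12 - 2 (sigma/r)^6)
                        + 332.06 q_i q_j / (4 r^2) ]
      - tau * sum_i q_i^2

in kcal/mol with distances in Angstrom and charges in elementary units.
The Coulomb term uses a distance-dependent dielectric (4r); the last term
is a Born-like self-solvation penalty rewarding charged atoms in solvent.
Analytic gradients are provided so the surface can be minimized.

Nonbonded pairs exclude directly bonded atoms (1-2) and atoms sharing a
bonded neighbor (1-3); all 1-4 and further pairs interact. The surface is
exactly invariant under translation, rotation and atom relabeling.
"""

from __future__ import annotations

import time

import numpy as np

from ..core import COVALENT_RADII, MolecularSystem
from .base import CONVERGED, FAILED, OVERLAP_THRESHOLD, BackendConfig, EnergyResult

K_BOND = 300.0  # kcal mol^-1 A^-2
V3 = 2.0  # kcal/mol, 3-fold torsion barrier
EPS_LJ = 0.1  # kcal/mol
SIGMA_LJ = 3.4  # A, position of the 12-6 minimum
TAU = 1.0  # kcal mol^-1 e^-2, self-solvation strength
COULOMB = 332.06  # kcal mol^-1 A e^-2

# equilibrium bond lengths (A) per element pair; anything else falls back to
# the sum of covalent radii
R0_TABLE = {
    frozenset({"C"}): 1.53,
    frozenset({"C", "N"}): 1.47,
    frozenset({"C", "O"}): 1.43,
    frozenset({"C", "H"}): 1.09,
    frozenset({"N", "H"}): 1.01,
    frozenset({"O", "H"}): 0.96,
    frozenset({"C", "S"}): 1.81,
    frozenset({"N"}): 1.45,
    frozenset({"O"}): 1.48,
    frozenset({"S", "H"}): 1.34,
}


def equilibrium_length(el_i: str, el_j: str) -> float:
    key = frozenset({el_i, el_j})
    if key in R0_TABLE:
        return R0_TABLE[key]
    return COVALENT_RADII[el_i.upper()] + COVALENT_RADII[el_j.upper()]


class ToyTopology:
    """Precomputed index arrays for fast repeated evaluation of one system."""

    def __init__(self, system: MolecularSystem):
        n = len(system.atoms)
        self.n = n
        self.charges = np.array([a.formal_charge for a in system.atoms], dtype=float)

        self.bond_i = np.array([b[0] for b in system.bonds], dtype=int)
        self.bond_j = np.array([b[1] for b in system.bonds], dtype=int)
        self.bond_r0 = np.array(
            [
                equilibrium_length(system.atoms[i].element, system.atoms[j].element)
                for i, j, _ in system.bonds
            ]
        )

        adj: list[set[int]] = [set() for _ in range(n)]
        for i, j, _ in system.bonds:
            adj[i].add(j)
            adj[j].add(i)

        quads = []
        for j, k, _ in system.bonds:
            for i in adj[j] - {k}:
                for l in adj[k] - {j}:
                    if i != l:
                        quads.append((i, j, k, l))
        self.torsions = np.array(quads, dtype=int).reshape(-1, 4)

        excluded = {(min(i, j), max(i, j)) for i, j, _ in system.bonds}
        for center in range(n):
            neigh = sorted(adj[center])
            for a in range(len(neigh)):
                for b in range(a + 1, len(neigh)):
                    excluded.add((neigh[a], neigh[b]))
        iu, ju = np.triu_indices(n, k=1)
        mask = np.array([(i, j) not in excluded for i, j in zip(iu, ju)], dtype=bool) if n > 1 else np.array([], dtype=bool)
        self.nb_i = iu[mask]
        self.nb_j = ju[mask]
        self.nb_qq = self.charges[self.nb_i] * self.charges[self.nb_j]

        self.solvation = -TAU * float(np.sum(self.charges**2))

    # -- energy ------------------------------------------------------------

    def energy(self, xyz: np.ndarray) -> float:
        return self.energy_gradient(xyz, need_grad=False)[0]

    def gas_energy(self, xyz: np.ndarray) -> float:
        return self.energy(xyz) - self.solvation

    def energy_gradient(self, xyz: np.ndarray, need_grad: bool = True):
        """Total energy (incl. solvation) and dG/dx (kcal mol^-1 A^-1)."""
        x = np.asarray(xyz, dtype=float).reshape(self.n, 3)
        grad = np.zeros_like(x) if need_grad else None
        energy = self.solvation

        if len(self.bond_i):
            d = x[self.bond_i] - x[self.bond_j]
            r = np.linalg.norm(d, axis=1)
            dr = r - self.bond_r0
            energy += float(np.sum(K_BOND * dr**2))
            if need_grad:
                f = (2.0 * K_BOND * dr / r)[:, None] * d
                np.add.at(grad, self.bond_i, f)
                np.add.at(grad, self.bond_j, -f)

        if len(self.torsions):
            energy += self._torsion_terms(x, grad, need_grad)

        if len(self.nb_i):
            d = x[self.nb_i] - x[self.nb_j]
            r2 = np.sum(d * d, axis=1)
            r = np.sqrt(r2)
            sr6 = (SIGMA_LJ**2 / r2) ** 3
            lj = EPS_LJ * (sr6**2 - 2.0 * sr6)
            coul = (COULOMB / 4.0) * self.nb_qq / r2
            energy += float(np.sum(lj) + np.sum(coul))
            if need_grad:
                # dE/dr terms divided by r, applied along the pair vector
                dlj = EPS_LJ * (-12.0 * sr6**2 + 12.0 * sr6) / r2
                dcoul = -2.0 * (COULOMB / 4.0) * self.nb_qq / (r2 * r2)
                f = (dlj + dcoul)[:, None] * d
                np.add.at(grad, self.nb_i, f)
                np.add.at(grad, self.nb_j, -f)

        return energy, grad

    def _torsion_terms(self, x: np.ndarray, grad, need_grad: bool) -> float:
        t = self.torsions
        b1 = x[t[:, 1]] - x[t[:, 0]]
        b2 = x[t[:, 2]] - x[t[:, 1]]
        b3 = x[t[:, 3]] - x[t[:, 2]]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        b2n = np.linalg.norm(b2, axis=1)
        m1 = np.cross(n1, b2 / b2n[:, None])
        cos_term = np.sum(n1 * n2, axis=1)
        sin_term = np.sum(m1 * n2, axis=1)
        phi = np.arctan2(sin_term, cos_term)
        energy = float(np.sum((V3 / 2.0) * (1.0 + np.cos(3.0 * phi))))
        if need_grad:
            dedphi = -(3.0 * V3 / 2.0) * np.sin(3.0 * phi)
            # near-collinear torsions have an ill-defined angle; their
            # gradient is suppressed instead of diverging as |b1 x b2| -> 0
            n1sq = np.maximum(np.sum(n1 * n1, axis=1), 1e-6)
            n2sq = np.maximum(np.sum(n2 * n2, axis=1), 1e-6)
            # signs follow this module's atan2 dihedral convention
            dphi_da = (b2n / n1sq)[:, None] * n1
            dphi_dd = -(b2n / n2sq)[:, None] * n2
            p = -np.sum(b1 * b2, axis=1) / b2n**2
            q = -np.sum(b3 * b2, axis=1) / b2n**2
            dphi_db = (p - 1.0)[:, None] * dphi_da - q[:, None] * dphi_dd
            dphi_dc = (q - 1.0)[:, None] * dphi_dd - p[:, None] * dphi_da
            for col, dphi in zip(range(4), (dphi_da, dphi_db, dphi_dc, dphi_dd)):
                np.add.at(grad, t[:, col], dedphi[:, None] * dphi)
        return energy


class ToyBackend:
    """Deterministic classical backend; never fails on finite, non-clashing
    geometries, and supports analytic gradients (so it also drives the
    restrained-relaxation and conformer-search machinery)."""

    name = "toy"
    supports_gradient = True

    def __init__(self, config: BackendConfig | None = None):
        self.config = config or BackendConfig(backend="toy")
        self._topo_cache: dict[str, ToyTopology] = {}

    def topology(self, system: MolecularSystem) -> ToyTopology:
        # cache keyed on composition/bonding only (coords vary during use)
        key = (
            ",".join(f"{a.element}{a.formal_charge}" for a in system.atoms)
            + "|"
            + str(sorted((min(i, j), max(i, j)) for i, j, _ in system.bonds))
        )
        topo = self._topo_cache.get(key)
        if topo is None:
            topo = ToyTopology(system)
            if len(self._topo_cache) > 64:
                self._topo_cache.clear()
            self._topo_cache[key] = topo
        return topo

    def single_point(self, system: MolecularSystem) -> EnergyResult:
        t0 = time.perf_counter()
        clash = _closest_contact(system)
        if clash is not None and clash[0] < OVERLAP_THRESHOLD:
            return EnergyResult(
                status=FAILED,
                wall_seconds=time.perf_counter() - t0,
                reason=f"overlapping atoms {clash[1]}-{clash[2]} at {clash[0]:.3f} A",
            )
        topo = self.topology(system)
        total = topo.energy(system.coords)
        return EnergyResult(
            status=CONVERGED,
            total=total,
            gas=total - topo.solvation,
            solvation=topo.solvation,
            sasa=None,
            wall_seconds=time.perf_counter() - t0,
        )

    def energy_and_gradient(self, system: MolecularSystem, xyz: np.ndarray):
        return self.topology(system).energy_gradient(xyz)


def _closest_contact(system: MolecularSystem):
    if len(system.atoms) < 2:
        return None
    from scipy.spatial import cKDTree

    xyz = system.coords
    tree = cKDTree(xyz)
    pairs = tree.query_pairs(r=OVERLAP_THRESHOLD, output_type="ndarray")
    if len(pairs) == 0:
        return None
    d = np.linalg.norm(xyz[pairs[:, 0]] - xyz[pairs[:, 1]], axis=1)
    k = int(np.argmin(d))
    return float(d[k]), int(pairs[k, 0]), int(pairs[k, 1])


def toy_energy(system: MolecularSystem) -> EnergyResult:
    """Convenience single-shot evaluation with default toy settings."""
    return ToyBackend().single_point(system)
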