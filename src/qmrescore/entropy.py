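"""Ligand conformational entropy lost upon binding.

The bound molecule is assumed to occupy a single conformational state, so
the entropy change is dS = -R ln(Omega), where Omega counts the accessible
free-state conformations. Two estimators are provided:

* ``rot`` — rotamer counting: each of the N free torsional bonds is given
  three rotational states, Omega = 3^N. Fast, but known to over-count
  low-energy conformers (and to hurt enrichment), so it is not the default.
* ``conf`` — Metropolis Monte-Carlo sampling in torsion space with local
  minimization after every accepted move; Omega is the number of distinct
  minimized conformers within a 3 kcal/mol window of the lowest one, all
  assumed equally probable.

The penalty entering the docking score is -T*dS = R*T*ln(Omega) >= 0,
evaluated at 298.15 K by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .core import MolecularSystem

logger = logging.getLogger(__name__)

R_GAS = 1.987e-3  # kcal mol^-1 K^-1
DEFAULT_T = 298.15  # K
DEFAULT_WINDOW = 3.0  # kcal/mol energy window for conformer counting
DEFAULT_DISTINCT = 30.0  # degrees; larger max circular torsion deviation => distinct
DEFAULT_MC_TEMPERATURE = 300.0  # K, Metropolis acceptance temperature


@dataclass
class EntropyEstimate:
    omega: int
    method: str  # 'rot' | 'conf'
    n_rotatable: int
    delta_s: float  # kcal mol^-1 K^-1
    minus_t_delta_s: float  # kcal/mol
    temperature: float
    conformer_energies: list[float] = field(default_factory=list)
    seed: int | None = None


@dataclass
class Conformer:
    torsions: np.ndarray  # degrees, one per rotatable bond
    energy: float  # kcal/mol
    coords: np.ndarray


# ---------------------------------------------------------------------------
# torsion machinery


def dihedral_angle(p0, p1, p2, p3) -> float:
    """Signed dihedral in degrees."""
    b1 = np.asarray(p1) - np.asarray(p0)
    b2 = np.asarray(p2) - np.asarray(p1)
    b3 = np.asarray(p3) - np.asarray(p2)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m1 = np.cross(n1, b2 / np.linalg.norm(b2))
    return float(np.degrees(np.arctan2(np.dot(m1, n2), np.dot(n1, n2))))


def circular_difference(a: float, b: float) -> float:
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


@dataclass
class Rotor:
    """One rotatable bond: axis atoms, reference atoms defining the
    dihedral coordinate, and the atom set that moves when it turns."""

    axis: tuple[int, int]  # (a, b): rotation axis a -> b
    reference: tuple[int, int, int, int]  # dihedral i-a-b-l
    moving: list[int]  # atoms on the b side (b itself lies on the axis)


def _bond_graph(system: MolecularSystem) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(system.atoms)))
    for i, j, order in system.bonds:
        g.add_edge(i, j, order=order)
    return g


def _ring_edges(g: nx.Graph) -> set[frozenset[int]]:
    edges: set[frozenset[int]] = set()
    for cycle in nx.cycle_basis(g):
        for a, b in zip(cycle, cycle[1:] + cycle[:1]):
            edges.add(frozenset({a, b}))
    return edges


def _is_amide(system: MolecularSystem, g: nx.Graph, c: int, n: int) -> bool:
    """C-N bond where C also carries a double-bonded O."""
    if system.atoms[c].element != "C" or system.atoms[n].element != "N":
        return False
    for o in g.neighbors(c):
        if system.atoms[o].element == "O" and g.edges[c, o].get("order", 1) >= 2:
            return True
    return False


def rotatable_bonds(system: MolecularSystem) -> list[Rotor]:
    """Non-ring single bonds between heavy atoms, each end bearing at least
    one further heavy neighbor; amide C-N bonds excluded."""
    g = _bond_graph(system)
    rings = _ring_edges(g)
    rotors: list[Rotor] = []
    for i, j, order in system.bonds:
        if order != 1 or frozenset({i, j}) in rings:
            continue
        ai, aj = system.atoms[i], system.atoms[j]
        if not (ai.is_heavy and aj.is_heavy):
            continue
        heavy_i = [k for k in g.neighbors(i) if k != j and system.atoms[k].is_heavy]
        heavy_j = [k for k in g.neighbors(j) if k != i and system.atoms[k].is_heavy]
        if not heavy_i or not heavy_j:
            continue
        if _is_amide(system, g, i, j) or _is_amide(system, g, j, i):
            continue
        h = g.copy()
        h.remove_edge(i, j)
        moving = sorted(nx.node_connected_component(h, j) - {j})
        rotors.append(
            Rotor(axis=(i, j), reference=(min(heavy_i), i, j, min(heavy_j)), moving=moving)
        )
    return rotors


def count_rotatable_bonds(system: MolecularSystem) -> int:
    return len(rotatable_bonds(system))


def get_torsions(coords: np.ndarray, rotors: list[Rotor]) -> np.ndarray:
    return np.array(
        [dihedral_angle(*(coords[k] for k in r.reference)) for r in rotors]
    )


def set_torsions(coords: np.ndarray, rotors: list[Rotor], targets: np.ndarray) -> np.ndarray:
    """Coordinates with each rotor's dihedral driven to the target (deg)."""
    out = coords.copy()
    for rotor, target in zip(rotors, targets):
        current = dihedral_angle(*(out[k] for k in rotor.reference))
        # rotating the b-side by +delta about the a->b axis decreases the
        # signed dihedral under this sign convention
        delta = np.radians(current - target)
        a, b = rotor.axis
        axis = out[b] - out[a]
        axis = axis / np.linalg.norm(axis)
        moving = rotor.moving
        if moving:
            # Rodrigues rotation about the bond axis through atom b
            v = out[moving] - out[b]
            c, s = np.cos(delta), np.sin(delta)
            out[moving] = (
                v * c + np.cross(axis, v) * s + np.outer(v @ axis, axis) * (1.0 - c)
            ) + out[b]
    return out


# ---------------------------------------------------------------------------
# Omega estimators


def omega_rot(n_rotatable: int) -> int:
    """Rotamer-count estimator: three states per free torsional bond."""
    if n_rotatable < 0 or int(n_rotatable) != n_rotatable:
        raise ValueError("N must be a non-negative integer")
    return 3 ** int(n_rotatable)


def sample_conformers(
    molecule: MolecularSystem,
    backend,
    steps: int | None = None,
    temperature: float = DEFAULT_MC_TEMPERATURE,
    seed: int = 0,
) -> list[Conformer]:
    """Metropolis MC over torsion space with local minimization of the
    torsions after each accepted move; deterministic for a fixed seed.

    Each step perturbs one randomly chosen rotor by a uniform angle in
    (-180, 180]. Every minimized geometry is recorded; duplicates are
    resolved later by the distinct-conformer criterion.
    """
    rotors = rotatable_bonds(molecule)
    n = len(rotors)
    base = molecule.coords

    # fast path: evaluate the precomputed topology directly when the
    # backend exposes one (the toy surface); otherwise go through the full
    # single-point contract
    topo = backend.topology(molecule) if hasattr(backend, "topology") else None

    def energy_of(coords: np.ndarray) -> float:
        if topo is not None:
            return float(topo.energy(coords))
        work = molecule.copy()
        work.set_coords(coords)
        res = backend.single_point(work)
        if not res.converged:
            raise _SamplingFailure(res.reason or "backend failure")
        return res.total

    if n == 0:
        return [Conformer(torsions=np.zeros(0), energy=energy_of(base), coords=base)]
    if steps is None:
        steps = 1000 * n

    rng = np.random.default_rng(seed)

    def energy_t(t: np.ndarray) -> float:
        return energy_of(set_torsions(base, rotors, t))

    def minimize_t(t0: np.ndarray) -> tuple[np.ndarray, float]:
        # quasi-Newton in torsion space stays inside the starting basin;
        # the jacobian is taken numerically through the torsion-setting map
        # because sequentially applied torsions are coupled coordinates
        res = minimize(energy_t, t0, method="L-BFGS-B", options={"ftol": 1e-10, "gtol": 1e-6})
        return np.asarray(res.x, dtype=float), float(res.fun)

    kT = R_GAS * temperature
    t = get_torsions(base, rotors)
    try:
        e = energy_t(t)
    except _SamplingFailure as exc:
        logger.warning("initial conformer failed (%s); starting from zero torsions", exc)
        t = np.zeros(n)
        e = energy_t(t)

    conformers: list[Conformer] = []
    tmin, emin = minimize_t(t)
    conformers.append(Conformer(tmin, emin, set_torsions(base, rotors, tmin)))

    for _ in range(steps):
        proposal = t.copy()
        k = int(rng.integers(n))
        proposal[k] = ((proposal[k] + rng.uniform(-180.0, 180.0) + 180.0) % 360.0) - 180.0
        try:
            e_new = energy_t(proposal)
        except _SamplingFailure as exc:
            logger.debug("skipping failed conformer: %s", exc)
            continue
        if e_new <= e or rng.random() < np.exp(-(e_new - e) / kT):
            t, e = proposal, e_new
            tmin, emin = minimize_t(t)
            conformers.append(Conformer(tmin, emin, set_torsions(base, rotors, tmin)))
    return conformers


class _SamplingFailure(RuntimeError):
    pass


def omega_conf(
    conformers: list[Conformer],
    window: float = DEFAULT_WINDOW,
    distinct_threshold: float = DEFAULT_DISTINCT,
) -> int:
    """Distinct conformers within the low-energy window, all equi-probable.

    Distinctness: two conformers are the same unless some torsion differs
    by more than ``distinct_threshold`` degrees (circular).
    """
    if not conformers:
        raise ValueError("conformer list is empty")
    e_min = min(c.energy for c in conformers)
    pool = sorted(
        (c for c in conformers if c.energy - e_min <= window), key=lambda c: c.energy
    )
    kept: list[Conformer] = []
    for cand in pool:
        if all(
            max(
                (circular_difference(a, b) for a, b in zip(cand.torsions, ref.torsions)),
                default=0.0,
            )
            > distinct_threshold
            for ref in kept
        ):
            kept.append(cand)
    return max(len(kept), 1)


def entropy_term(
    omega: int,
    temperature: float = DEFAULT_T,
    method: str = "conf",
    n_rotatable: int = 0,
    conformer_energies: list[float] | None = None,
    seed: int | None = None,
) -> EntropyEstimate:
    """dS = -R ln(Omega); the score penalty is -T*dS = R*T*ln(Omega)."""
    if omega < 1:
        raise ValueError("Omega must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    delta_s = -R_GAS * float(np.log(omega))
    return EntropyEstimate(
        omega=int(omega),
        method=method,
        n_rotatable=n_rotatable,
        delta_s=delta_s,
        minus_t_delta_s=-temperature * delta_s,
        temperature=temperature,
        conformer_energies=list(conformer_energies or []),
        seed=seed,
    )


def estimate_entropy(
    molecule: MolecularSystem,
    backend=None,
    method: str = "conf",
    temperature: float = DEFAULT_T,
    seed: int = 0,
    steps: int | None = None,
    mc_temperature: float = DEFAULT_MC_TEMPERATURE,
    window: float = DEFAULT_WINDOW,
    distinct_threshold: float = DEFAULT_DISTINCT,
) -> EntropyEstimate:
    """Full entropy estimate for one molecule with the chosen estimator."""
    n = count_rotatable_bonds(molecule)
    if method == "rot":
        return entropy_term(omega_rot(n), temperature, "rot", n, seed=seed)
    if method != "conf":
        raise ValueError(f"unknown entropy method {method!r}")
    if n == 0:
        return entropy_term(1, temperature, "conf", 0, seed=seed)
    if backend is None:
        raise ValueError("conf estimator needs an energy backend")
    conformers = sample_conformers(molecule, backend, steps, mc_temperature, seed)
    omega = omega_conf(conformers, window, distinct_threshold)
    if omega > omega_rot(n):
        logger.info(
            "Omega_conf=%d exceeds rotamer count %d for N=%d", omega, omega_rot(n), n
        )
    e_min = min(c.energy for c in conformers)
    energies = sorted(c.energy - e_min for c in conformers if c.energy - e_min <= window)
    return entropy_term(omega, temperature, "conf", n, conformer_energies=energies, seed=seed)


def write_entropy_report(
    estimates: dict[str, EntropyEstimate], path: str | Path
) -> None:
    rows = [
        {
            "state_id": sid,
            "n_rotatable": est.n_rotatable,
            "method": est.method,
            "omega": est.omega,
            "delta_s": est.delta_s,
            "minus_t_delta_s": est.minus_t_delta_s,
            "seed": est.seed,
        }
        for sid, est in estimates.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
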