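"""Assembly of the QM docking score (QMDS) variants.

The score approximates an end-point binding free energy by single-point
energies on the docked complex and its isolated parts:

    QMDS = dG_o - T*dS                   (plain variants)
    QMDS = dG_o + dG_conf(P) + dG_conf(L) - T*dS   ("d" variants)

with dG_o = G(PL) - G_o(P) - G_o(L) evaluated in the conformations taken
from the docked complex, and deformation penalties dG_conf(X) =
G_o(X) - G(X) against the relaxed free states. Variant 1 scores the raw
docked complex; variant 2 first relaxes it under the restraint schedule.
Algebraically the "d" form collapses to G(PL) - G(P) - G(L) - T*dS; both
routes are computed from the same component energies, so the identity holds
to round-off by construction and is asserted in the tests.

Scores are rankings, not absolute binding free energies: any failed
component energy yields a failed record (excluded from enrichment), never
a number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .backends.base import BackendConfig, EnergyResult
from .core import DockedPose, MolecularSystem, ResidueKey
from .cutout import ReducedSystem
from .entropy import EntropyEstimate, estimate_entropy
from .relax import movable_atom_indices, restrained_relax, unbound_state

logger = logging.getLogger(__name__)

VARIANTS = ("qmds1", "qmds1d", "qmds2", "qmds2d")


@dataclass
class ScoreComponents:
    g_pl: float | None = None  # complex, bound conformation
    g_op: float | None = None  # pocket, bound conformation
    g_ol: float | None = None  # ligand, bound conformation
    g_p: float | None = None  # pocket, relaxed free state
    g_l: float | None = None  # ligand, relaxed free state
    minus_t_delta_s: float | None = None  # -T*dS >= 0
    statuses: dict[str, str] = field(default_factory=dict)


@dataclass
class ScoreRecord:
    state_id: str
    parent_id: str
    variant: str
    components: ScoreComponents
    qmds: float | None = None
    status: str = "converged"
    reason: str | None = None

    @property
    def converged(self) -> bool:
        return self.status == "converged"


def delta_g_o(g_pl: float, g_op: float, g_ol: float) -> float:
    """Interaction term in the docked conformations."""
    return g_pl - g_op - g_ol


def deformation(g_ox: float, g_x: float) -> float:
    """Strain of species X: bound-conformation energy minus free-state energy."""
    return g_ox - g_x


def assemble(
    components: ScoreComponents, variant: str, state_id: str = "", parent_id: str = ""
) -> ScoreRecord:
    """Build one score record; missing components give a failed record."""
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    needed = ["g_pl", "g_op", "g_ol", "minus_t_delta_s"]
    if variant.endswith("d"):
        needed += ["g_p", "g_l"]
    missing = [k for k in needed if getattr(components, k) is None]
    if missing:
        return ScoreRecord(
            state_id, parent_id, variant, components,
            status="failed", reason=f"missing components: {', '.join(missing)}",
        )
    dgo = delta_g_o(components.g_pl, components.g_op, components.g_ol)
    value = dgo + components.minus_t_delta_s
    if variant.endswith("d"):
        value += deformation(components.g_op, components.g_p)
        value += deformation(components.g_ol, components.g_l)
    return ScoreRecord(state_id, parent_id, variant, components, qmds=value)


class _ComponentCache:
    """Single-point results keyed by (system hash, backend config hash)."""

    def __init__(self, backend):
        self.backend = backend
        cfg = getattr(backend, "config", None) or BackendConfig()
        self.cfg_hash = cfg.config_hash()
        self._store: dict[tuple[str, str], EnergyResult] = {}

    def single_point(self, system: MolecularSystem) -> EnergyResult:
        key = (system.content_hash(), self.cfg_hash)
        if key not in self._store:
            self._store[key] = self.backend.single_point(system)
        return self._store[key]


def score_library(
    reduced: ReducedSystem | MolecularSystem,
    poses: list[DockedPose],
    backend,
    variants: tuple[str, ...] = ("qmds1",),
    entropies: dict[str, EntropyEstimate] | None = None,
    entropy_method: str = "conf",
    entropy_seed: int = 0,
    temperature: float = 298.15,
    free_residues: set[ResidueKey] | None = None,
    relax_weights: tuple[float, ...] = (50.0, 10.0, 5.0, 1.0, 0.0),
) -> list[ScoreRecord]:
    """Score every pose with every requested variant.

    The pocket-in-bound-conformation energy and the relaxed pocket free
    state are per-target quantities, computed once and reused for all
    poses; ligand free states are minimized once per state id. Failed
    engine jobs poison only the records that need them.
    """
    for v in variants:
        if v not in VARIANTS:
            raise ValueError(f"unknown variant {v!r}")
    pocket = reduced.system if isinstance(reduced, ReducedSystem) else reduced
    cache = _ComponentCache(backend)

    # per-target components
    g_op_res = cache.single_point(pocket)  # shared by all variant-1 records
    g_p_res: EnergyResult | None = None
    need_free_p = any(v.endswith("d") for v in variants)
    if need_free_p:
        p_free = unbound_state(pocket, backend)
        g_p_res = (
            cache.single_point(p_free.system)
            if not p_free.failed
            else EnergyResult(status="failed", reason=p_free.reason)
        )

    need_relaxed = any(v.startswith("qmds2") for v in variants)
    n_pocket = len(pocket.atoms)

    records: list[ScoreRecord] = []
    for pose in poses:
        mtds: float | None = None
        mtds_reason = None
        try:
            est = (entropies or {}).get(pose.state_id)
            if est is None:
                est = estimate_entropy(
                    pose.ligand,
                    backend=backend,
                    method=entropy_method,
                    temperature=temperature,
                    seed=entropy_seed,
                )
            mtds = est.minus_t_delta_s
        except Exception as exc:  # entropy failure poisons this pose only
            mtds_reason = f"entropy estimate failed: {exc}"
            logger.warning("%s: %s", pose.state_id, mtds_reason)

        complex_docked = pocket.merged_with(pose.ligand)
        g_pl1 = cache.single_point(complex_docked)
        g_ol1 = cache.single_point(pose.ligand)

        g_l_res: EnergyResult | None = None
        if any(v.endswith("d") for v in variants):
            l_free = unbound_state(pose.ligand, backend)
            g_l_res = (
                cache.single_point(l_free.system)
                if not l_free.failed
                else EnergyResult(status="failed", reason=l_free.reason)
            )

        relaxed = None
        if need_relaxed:
            movable = movable_atom_indices(
                complex_docked, free_residues if free_residues is not None else set()
            )
            if g_pl1.converged:  # do not try to relax clashing geometries
                relaxed = restrained_relax(complex_docked, backend, movable, relax_weights)
            else:
                relaxed = None

        for variant in variants:
            comp = ScoreComponents(minus_t_delta_s=mtds)
            if variant.startswith("qmds1"):
                comp.g_pl = g_pl1.total
                comp.g_op = g_op_res.total
                comp.g_ol = g_ol1.total
                comp.statuses = {
                    "g_pl": g_pl1.status, "g_op": g_op_res.status, "g_ol": g_ol1.status,
                }
            else:
                if relaxed is None or relaxed.failed:
                    reason = (relaxed.reason if relaxed else None) or (
                        g_pl1.reason or "relaxation unavailable"
                    )
                    records.append(
                        ScoreRecord(
                            pose.state_id, pose.parent_id, variant, comp,
                            status="failed", reason=f"relaxation failed: {reason}",
                        )
                    )
                    continue
                rsys = relaxed.system
                g_pl2 = cache.single_point(rsys)
                pocket2 = rsys.subset(list(range(n_pocket)))
                ligand2 = rsys.subset(list(range(n_pocket, len(rsys.atoms))))
                g_op2 = cache.single_point(pocket2)
                g_ol2 = cache.single_point(ligand2)
                comp.g_pl = g_pl2.total
                comp.g_op = g_op2.total
                comp.g_ol = g_ol2.total
                comp.statuses = {
                    "g_pl": g_pl2.status, "g_op": g_op2.status, "g_ol": g_ol2.status,
                }
            if variant.endswith("d"):
                comp.g_p = g_p_res.total if g_p_res is not None else None
                comp.g_l = g_l_res.total if g_l_res is not None else None
                comp.statuses["g_p"] = g_p_res.status if g_p_res else "failed"
                comp.statuses["g_l"] = g_l_res.status if g_l_res else "failed"
            record = assemble(comp, variant, pose.state_id, pose.parent_id)
            if record.status == "failed" and mtds_reason:
                record.reason = mtds_reason
            records.append(record)
    return records


def write_scores(records: list[ScoreRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        c = r.components
        dgo = dcp = dcl = None
        if None not in (c.g_pl, c.g_op, c.g_ol):
            dgo = delta_g_o(c.g_pl, c.g_op, c.g_ol)
        if None not in (c.g_op, c.g_p):
            dcp = deformation(c.g_op, c.g_p)
        if None not in (c.g_ol, c.g_l):
            dcl = deformation(c.g_ol, c.g_l)
        rows.append(
            {
                "state_id": r.state_id, "parent_id": r.parent_id, "variant": r.variant,
                "G_PL": c.g_pl, "G_oP": c.g_op, "G_oL": c.g_ol,
                "G_P": c.g_p, "G_L": c.g_l,
                "dGo": dgo, "dGconfP": dcp, "dGconfL": dcl,
                "mTdS": c.minus_t_delta_s, "QMDS": r.qmds, "status": r.status,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_scores(path: str | Path) -> list[ScoreRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for row in df.itertuples(index=False):
        comp = ScoreComponents(
            g_pl=_opt(row.G_PL), g_op=_opt(row.G_oP), g_ol=_opt(row.G_oL),
            g_p=_opt(row.G_P), g_l=_opt(row.G_L), minus_t_delta_s=_opt(row.mTdS),
        )
        records.append(
            ScoreRecord(
                state_id=str(row.state_id), parent_id=str(row.parent_id),
                variant=row.variant, components=comp,
                qmds=_opt(row.QMDS), status=row.status,
            )
        )
    return records


def _opt(v):
    return None if pd.isna(v) else float(v)
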