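"""End-to-end orchestration: receptor + pose library -> scores -> metrics.

This is the programmatic face of the whole tool; the CLI commands are thin
wrappers around these functions. The stages compose through plain data, so
any of them can also be run and inspected on its own.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .backends.base import get_backend
from .config import PipelineConfig
from .core import DockedPose, LibraryManifest, MolecularSystem
from .cutout import ReducedSystem, build_reduced, defragment, residues_within
from .entropy import EntropyEstimate, estimate_entropy
from .molio import assign_formal_charges, select_environment
from .relax import free_region
from .scoring import ScoreRecord, score_library
from .screenmetrics import HitList, build_hitlist, evaluate

logger = logging.getLogger(__name__)


@dataclass
class ScreenResult:
    reduced: ReducedSystem
    records: list[ScoreRecord]
    entropies: dict[str, EntropyEstimate]
    hitlists: dict[str, HitList] = field(default_factory=dict)
    metrics: dict[str, dict[str, float]] = field(default_factory=dict)

    def records_for(self, variant: str) -> list[ScoreRecord]:
        return [r for r in self.records if r.variant == variant]

    @property
    def failed_fraction(self) -> float:
        if not self.records:
            return 0.0
        return sum(not r.converged for r in self.records) / len(self.records)


def prepare_receptor(
    receptor: MolecularSystem, poses: list[DockedPose], config: PipelineConfig
) -> tuple[MolecularSystem, ReducedSystem]:
    """Charge assignment, water/ion retention, binding-site cutout.

    The retention reference is the union of all docked poses (the library
    defines the site); the cutout is likewise one reduced system per
    target, shared by every pose.
    """
    charged = assign_formal_charges(receptor, charge_termini=config.charge_termini)
    reference = MolecularSystem(
        atoms=[a.copy() for p in poses for a in p.ligand.atoms]
    )
    trimmed = select_environment(
        charged, reference, config.cutoffs.water, config.cutoffs.ion
    )
    selected = residues_within(trimmed, poses, config.cutoffs.cutout)
    selected = defragment(selected, trimmed, config.max_gap, config.min_fragment)
    reduced = build_reduced(trimmed, selected)
    return trimmed, reduced


def compute_entropies(
    poses: list[DockedPose], config: PipelineConfig, backend=None
) -> dict[str, EntropyEstimate]:
    if backend is None:
        from .backends.base import BackendConfig

        name = config.entropy.backend or config.backend.backend
        backend = get_backend(BackendConfig(**{**config.backend.__dict__, "backend": name}))
    out: dict[str, EntropyEstimate] = {}
    for pose in poses:
        out[pose.state_id] = estimate_entropy(
            pose.ligand,
            backend=backend,
            method=config.entropy.method,
            temperature=config.entropy.temperature,
            seed=config.entropy.seed,
            steps=config.entropy.steps,
            mc_temperature=config.entropy.mc_temperature,
            window=config.entropy.window,
            distinct_threshold=config.entropy.distinct_threshold,
        )
    return out


def run_screen(
    receptor: MolecularSystem,
    poses: list[DockedPose],
    manifest: LibraryManifest,
    config: PipelineConfig | None = None,
) -> ScreenResult:
    """Score the whole library and evaluate screening power per variant."""
    config = config or PipelineConfig()
    backend = get_backend(config.backend)
    _, reduced = prepare_receptor(receptor, poses, config)
    entropies = compute_entropies(poses, config, backend=backend)
    movable = None
    if any(v.startswith("qmds2") for v in config.variants):
        movable = free_region(reduced.system, poses, config.cutoffs.free_region)
    records = score_library(
        reduced,
        poses,
        backend,
        variants=config.variants,
        entropies=entropies,
        temperature=config.entropy.temperature,
        free_residues=movable,
        relax_weights=config.relax_weights,
    )
    result = ScreenResult(reduced=reduced, records=records, entropies=entropies)
    for variant in config.variants:
        variant_records = result.records_for(variant)
        try:
            hl = build_hitlist(variant_records, manifest)
            result.hitlists[variant] = hl
            result.metrics[variant] = evaluate(hl, config.ef_percentages)
        except ValueError as exc:
            logger.warning("no metrics for %s: %s", variant, exc)
    return result


def write_run_manifest(
    path: str | Path, config: PipelineConfig, command: str, extra: dict | None = None
) -> None:
    """Machine-readable provenance for a pipeline run."""
    payload = {
        "command": command,
        "version": __version__,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "seeds": {"entropy": config.entropy.seed},
    }
    payload.update(extra or {})
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
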