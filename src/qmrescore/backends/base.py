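"""Single-point energy contract shared by all backends.

Every energy evaluation in the pipeline goes through
``Backend.single_point(system) -> EnergyResult``; scores are assembled only
from converged results, and a failed evaluation is data (it propagates to a
failed score record and exclusion from the enrichment), never an exception.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

CONVERGED = "converged"
FAILED = "failed"

#: closest allowed interatomic distance (A); below this the geometry is
#: considered unphysical and the evaluation fails
OVERLAP_THRESHOLD = 0.3


@dataclass
class BackendConfig:
    backend: str = "toy"
    solvent_eps: float = 78.4  # relative permittivity of the continuum solvent (water)
    engine_keywords: list[str] = field(default_factory=list)
    engine_executable: str | None = None
    timeout: float = 600.0
    scratch_dir: str | None = None

    def __post_init__(self) -> None:
        if self.solvent_eps < 1:
            raise ValueError("solvent relative permittivity must be >= 1")

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "backend": self.backend,
                "eps": self.solvent_eps,
                "keywords": sorted(self.engine_keywords),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class EnergyResult:
    """One single-point evaluation in kcal/mol (total includes solvation)."""

    status: str
    total: float | None = None
    gas: float | None = None
    solvation: float | None = None
    sasa: float | None = None  # solvent-accessible surface area, A^2
    wall_seconds: float = 0.0
    reason: str | None = None

    def __post_init__(self) -> None:
        if self.status == CONVERGED:
            if self.total is None or self.gas is None or self.solvation is None:
                raise ValueError("converged result must carry total/gas/solvation")
            if abs(self.total - (self.gas + self.solvation)) > 1e-6:
                raise ValueError("total must equal gas + solvation")
        elif self.status == FAILED:
            self.total = self.gas = self.solvation = None
        else:
            raise ValueError(f"unknown status {self.status!r}")

    @property
    def converged(self) -> bool:
        return self.status == CONVERGED


def get_backend(config: BackendConfig):
    from . import mopac, toy

    if config.backend == "toy":
        return toy.ToyBackend(config)
    if config.backend == "engine":
        return mopac.EngineBackend(config)
    raise ValueError(f"unknown backend {config.backend!r}")


def scratch_path(config: BackendConfig, state_id: str, role: str, ext: str) -> Path:
    """Scratch layout <workdir>/<state_id>/<role>.{mop,out}."""
    base = Path(config.scratch_dir or "scratch")
    d = base / state_id
    d.mkdir(parents=True, exist_ok=True)
    return d / f"{role}.{ext}"
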