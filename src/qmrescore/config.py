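"""Pipeline configuration: one structured object, loadable from YAML.

Defaults encode the published protocol parameters: 8 A binding-site cutout
(warn under 6), 4 A free region for relaxation, 4 A water and 8 A ion
retention, the 50/10/5/1/0 kcal/mol restraint schedule, COSMO water
permittivity 78.4, and the conformer-count entropy estimator at 298.15 K.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .backends.base import BackendConfig


@dataclass
class CutoffConfig:
    cutout: float = 8.0  # A, binding-site residue selection
    free_region: float = 4.0  # A, movable residues during relaxation
    water: float = 4.0  # A, retained crystallographic waters
    ion: float = 8.0  # A, retained ions

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v <= 0:
                raise ValueError(f"cutoff {name} must be positive, got {v}")


@dataclass
class EntropyConfig:
    method: str = "conf"  # 'conf' (default) or 'rot'
    temperature: float = 298.15  # K
    seed: int = 0
    mc_temperature: float = 300.0  # K, Metropolis acceptance
    steps: int | None = None  # default 1000 * N rotatable bonds
    window: float = 3.0  # kcal/mol conformer-count window
    distinct_threshold: float = 30.0  # degrees
    backend: str | None = None  # override sampling backend; default = active


@dataclass
class PipelineConfig:
    receptor: str | None = None
    poses: str | None = None
    manifest: str | None = None
    workdir: str = "qmrescore_run"
    cutoffs: CutoffConfig = field(default_factory=CutoffConfig)
    backend: BackendConfig = field(default_factory=BackendConfig)
    entropy: EntropyConfig = field(default_factory=EntropyConfig)
    variants: tuple[str, ...] = ("qmds1", "qmds1d", "qmds2", "qmds2d")
    ef_percentages: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0)
    charge_termini: bool = False
    max_gap: int = 2  # defragmentation: largest filled selection gap (residues)
    min_fragment: int = 2  # smallest allowed cutout fragment (residues)
    relax_weights: tuple[float, ...] = (50.0, 10.0, 5.0, 1.0, 0.0)
    reset_reference: bool = True  # restraint reference resets each cycle

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "cutoffs" in kwargs:
            kwargs["cutoffs"] = CutoffConfig(**kwargs["cutoffs"])
        if "backend" in kwargs:
            kwargs["backend"] = BackendConfig(**kwargs["backend"])
        if "entropy" in kwargs:
            kwargs["entropy"] = EntropyConfig(**kwargs["entropy"])
        for key in ("variants", "ef_percentages", "relax_weights"):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("variants", "ef_percentages", "relax_weights"):
            d[key] = list(d[key])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
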