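"""File-dialect adapter for an external semi-empirical engine.

Jobs are written in the MOPAC input dialect — PM7 Hamiltonian, single-SCF
(no geometry optimization), COSMO continuum solvent at the configured
permittivity, and the linear-scaling localized-orbital keyword (MOZYME) for
systems above 300 atoms. Outputs are parsed for the final heat of
formation, the dielectric (solvation) energy and the COSMO surface area;
anything short of a normal termination is reported as a failed result, not
an exception, so a crashed or timed-out job simply drops its molecule from
the screen.

The engine binary itself is optional: writing and parsing are plain text
operations, so jobs can be farmed out and collected later.
"""

from __future__ import annotations

import re
import subprocess
import time
from pathlib import Path

from ..core import MolecularSystem
from .base import CONVERGED, FAILED, BackendConfig, EnergyResult

EV_TO_KCAL = 23.060548

MOZYME_THRESHOLD = 300  # atoms; above this the linear-scaling keyword is added

_HEAT_RE = re.compile(r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+\.\d+)\s*KCAL/MOL")
_DIELECTRIC_RE = re.compile(r"DIELECTRIC ENERGY\s*=\s*(-?\d+\.\d+)\s*EV")
_AREA_RE = re.compile(r"COSMO AREA\s*=\s*(-?\d+\.\d+)\s*SQUARE ANGSTROMS")
_DONE_MARKER = "== MOPAC DONE =="


def write_engine_input(system: MolecularSystem, config: BackendConfig) -> str:
    """Render a single-point job file; byte-stable for fixed input.

    Keyword order is frozen: Hamiltonian, linear scaling (large systems),
    single SCF, charge, solvent permittivity, then any extra keywords in
    sorted order. Geometry follows in Cartesian with optimization flags 0.
    """
    if any(a.formal_charge is None for a in system.atoms):
        raise ValueError("system charge must be set before writing an engine job")
    keywords = ["PM7"]
    if len(system.atoms) > MOZYME_THRESHOLD:
        keywords.append("MOZYME")
    keywords.append("1SCF")
    keywords.append(f"CHARGE={system.total_charge}")
    keywords.append(f"EPS={config.solvent_eps:.2f}")
    keywords.extend(sorted(config.engine_keywords))
    lines = [" ".join(keywords), "qmrescore single-point job", ""]
    for a in system.atoms:
        lines.append(
            f"{a.element:<2} {a.coords[0]:14.6f} 0 {a.coords[1]:14.6f} 0 {a.coords[2]:14.6f} 0"
        )
    return "\n".join(lines) + "\n"


def parse_engine_output(text: str) -> EnergyResult:
    """Extract energies from an engine output stream.

    The total is the final heat of formation (kcal/mol, includes COSMO
    solvation); the solvation component is the dielectric energy (printed
    in eV, converted at parse time); the COSMO area is captured as SASA
    metadata. A missing normal-termination marker or heat-of-formation line
    flags the job failed.
    """
    if _DONE_MARKER not in text:
        return EnergyResult(status=FAILED, reason="no normal-termination marker")
    m = _HEAT_RE.search(text)
    if m is None:
        return EnergyResult(status=FAILED, reason="no final heat of formation in output")
    total = float(m.group(1))
    solvation = 0.0
    md = _DIELECTRIC_RE.search(text)
    if md is not None:
        solvation = float(md.group(1)) * EV_TO_KCAL
    sasa = None
    ma = _AREA_RE.search(text)
    if ma is not None:
        sasa = float(ma.group(1))
    return EnergyResult(
        status=CONVERGED, total=total, gas=total - solvation, solvation=solvation, sasa=sasa
    )


class EngineBackend:
    """Runs the external engine when configured with an executable;
    otherwise every evaluation is a failed result (jobs can still be
    written and parsed by hand through the module functions)."""

    name = "engine"
    supports_gradient = False

    def __init__(self, config: BackendConfig):
        self.config = config

    def single_point(self, system: MolecularSystem) -> EnergyResult:
        t0 = time.perf_counter()
        exe = self.config.engine_executable
        if not exe:
            return EnergyResult(status=FAILED, reason="no engine executable configured")
        scratch = Path(self.config.scratch_dir or "scratch")
        scratch.mkdir(parents=True, exist_ok=True)
        job = scratch / "job.mop"
        job.write_text(write_engine_input(system, self.config))
        try:
            subprocess.run(
                [exe, str(job)],
                timeout=self.config.timeout,
                capture_output=True,
                check=False,
            )
        except subprocess.TimeoutExpired:
            return EnergyResult(
                status=FAILED,
                reason=f"engine timed out after {self.config.timeout}s",
                wall_seconds=time.perf_counter() - t0,
            )
        out = job.with_suffix(".out")
        if not out.exists():
            return EnergyResult(
                status=FAILED, reason="engine produced no output file",
                wall_seconds=time.perf_counter() - t0,
            )
        result = parse_engine_output(out.read_text())
        result.wall_seconds = time.perf_counter() - t0
        return result
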