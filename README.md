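# qmrescore

Semi-empirical quantum-mechanical rescoring of docked protein–ligand poses,
with screening-power evaluation.

## The problem

High-throughput docking screens thousands-to-millions of molecules against a
(mostly rigid) receptor and ranks them by a docking score. Classical
force-field scores miss electronic effects — polarization, charge transfer,
halogen bonding — that a quantum-mechanical energy captures, and
semi-empirical Hamiltonians with continuum solvation (PM7 + COSMO) are now
fast enough to re-score an entire docked library one single point at a time.
`qmrescore` implements that rescoring pipeline for computational chemists:
it takes a prepared receptor (PDB) plus one docked pose per molecule state
(SDF/MOL2 with a ligand/decoy manifest), and produces a QM-based ranking and
its screening-power metrics.

## The score

For each docked complex PL the QM docking score is

```
QMDS = ΔG_o^QM + ΔG_conf^QM(P) + ΔG_conf^QM(L) − TΔS
ΔG_o^QM      = G^QM(PL) − G_o^QM(P) − G_o^QM(L)
ΔG_conf^QM(X) = G_o^QM(X) − G^QM(X),   X ∈ {P, L}
ΔS           = −R ln Ω
```

where the `o` subscript marks energies evaluated in the conformations frozen
out of the docked complex, `G(X)` is the energy of the locally minimized free
state, and Ω counts the free-state ligand conformations (rotamer count 3^N
over the N rotatable bonds, or a Monte-Carlo conformer search in a 3 kcal/mol
window — the default, since rotamer counting over-counts). Four variants are
assembled: rigid (`qmds1`) or relaxed under a 50/10/5/1/0 kcal·mol⁻¹·Å⁻²
harmonic restraint schedule (`qmds2`), each with (`…d`) or without the
deformation terms. All energies are single points on a reduced binding-site
cluster — every residue with a heavy atom within 8 Å of any docked pose,
defragmented and hydrogen-capped — with waters kept within 4 Å and ions
within 8 Å of the ligands, and Asp/Glu −1, Arg/Lys +1 formal charges.

Scores are rankings: the absolute numbers are not binding free energies.
Screening power is measured by enrichment factors EF(1), EF(2), EF(5),
EF(10) (top-set rule N_x = ⌈x·N/100⌉; states of one molecule collapse to
their lowest score; molecules whose QM jobs failed are excluded) and by
ROC/AUC with ties credited half a pair.

Two energy backends satisfy one single-point contract: a deterministic
classical toy surface with analytic gradients (drives tests, synthetic
screens, relaxation, and conformer sampling) and a file-dialect adapter for
an external PM7+COSMO engine (MOPAC-style job writer and output parser; the
binary is optional, jobs can be farmed out and parsed later).

## Worked example

`examples/run_synthetic_screen.py` generates a 30-residue toy pocket with a
charged rim and a 20-ligand / 180-decoy pose library whose ligands are
placed charge- and shape-complementary to the pocket (decoys match them in
atom count and net charge but sit against like charges), then scores the
library rigid on the toy backend:

```
library: 206 pose states, 199 molecules ranked
failed QM evaluations excluded: 1
  EF1 =   9.95   (1 = random, higher = better early enrichment)
  EF2 =   9.95   (1 = random, higher = better early enrichment)
  EF5 =   9.95   (1 = random, higher = better early enrichment)
 EF10 =   9.95   (1 = random, higher = better early enrichment)
  AUC =  1.000   (0.5 = random, 1.0 = perfect separation)
```

206 pose states collapse to 200 parent molecules (six molecules carry two
protonation-like states); the one deliberately clashing decoy pose fails its
energy evaluation and leaves the totals, hence 199 ranked molecules. EF(x)
is capped at N/Hits = 10 here, so 9.95 means every top slot is a true
ligand. The other examples (`binding_site_cutout.py`, `ligand_entropy.py`,
`score_variants.py`, `engine_job_files.py`) walk the individual stages the
same way.

The same pipeline runs from the shell:

```
qmrescore synth --out-dir run --seed 0
qmrescore score --receptor run/receptor.pdb --poses run/poses.sdf \
                --manifest run/manifest.tsv --out-dir run
qmrescore evaluate --scores run/scores.tsv --manifest run/manifest.tsv \
                   --out-dir run
```

Exit codes: 0 success, 2 input error, 3 when more than half of the library
failed the QM stage.

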