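# Methods

## Score model

The pipeline treats binding as an end-point process evaluated with single
points: the score of a docked complex PL is the interaction term
`ΔG_o = G(PL) − G_o(P) − G_o(L)` in the conformations taken from the docked
complex, optionally plus the deformation (strain) penalties
`ΔG_conf(X) = G_o(X) − G(X)` against locally minimized free states, minus
`TΔS` for the ligand conformational freedom lost on binding. The
deformation-explicit form is algebraically identical to
`G(PL) − G(P) − G(L) − TΔS`; both are assembled from the same component
energies, so the identity holds to round-off and the test suite asserts it
below 1e-9 kcal/mol. No MD averaging is performed — each component is one
single-point evaluation — and scores are used strictly as rankings.

Four variants: `qmds1` (single points on the raw docked complex),
`qmds1d` (plus deformation terms), `qmds2`/`qmds2d` (the complex is first
relaxed, see below). Under rigid scoring the pocket terms `G_o(P)` and
`ΔG_conf(P)` are per-target constants; the pipeline computes them once and
reuses them, which the tests also assert.

## Reduced binding-site system

Semi-empirical single points on a whole receptor are unnecessary and slow,
so every energy is evaluated on a binding-site cluster built once per
target:

* **Selection.** A protein residue enters the cluster when any of its heavy
  atoms lies within 8 Å (default) of any heavy atom of any docked pose in
  the library — the union over the library, so the same cluster serves
  every pose and the pocket reference energy is comparable across
  molecules. Hydrogens never count toward the threshold. Selections are
  KD-tree accelerated and are verified against an all-pairs brute force in
  the tests. Cutoffs below 6 Å are accepted but warned about, since small
  clusters put continuum solvent where protein used to be.
* **Defragmentation.** Gaps of at most `max_gap = 2` residues between
  selected stretches on a chain are filled, fragments shorter than
  `min_fragment = 2` are extended (C-side first, N-side as fallback), and
  when HELIX/SHEET annotations are present a fragment boundary inside an
  annotated element is pushed to the element boundary. These deterministic
  rules replace a manual inspection step; both knobs are configurable.
* **Capping.** Each severed peptide bond is replaced by one hydrogen on the
  retained atom along the former bond vector: 1.01 Å on a fragment's
  N-terminal nitrogen, 1.09 Å on its C-terminal carbonyl carbon. Cap
  positions are purely geometric (no optimization). Every cluster atom
  except caps maps back to a receptor atom with identical coordinates; the
  provenance map records both directions.
* **Environment.** Waters are retained within 4 Å and ions within 8 Å
  (heavy-atom minimum distance) of the docked ligands; all retained waters
  and ions join every cluster. Formal charges follow residue rules
  (Asp/Glu −1, Arg/Lys +1, His neutral as protonated in the input, ions at
  nominal charge, termini neutral unless configured otherwise), and the
  cluster charge is the sum over its members.

## Energy backends

All evaluations go through one contract: `single_point(system) →
EnergyResult` with total/gas/solvation energies in kcal/mol, optional
solvent-accessible surface area, and a converged/failed status. Failures —
atom overlaps under 0.3 Å, engine timeouts, truncated outputs — are data:
they produce failed score records and exclusion from the enrichment, never
exceptions that abort a screen.

**Toy surface.** A deterministic classical surface used for testing,
synthetic screens, relaxation and conformer sampling:

```
G = Σ_bonds k_b (r − r₀)²  +  Σ_torsions (V₃/2)(1 + cos 3φ)
  + Σ_nonbonded [ ε((σ/r)¹² − 2(σ/r)⁶) + 332.06 q_i q_j / (4r²) ]
  − τ Σ_i q_i²
```

with k_b = 300 kcal·mol⁻¹·Å⁻², r₀ from a small element-pair table, V₃ = 2,
ε = 0.1, σ = 3.4 Å, τ = 1 kcal·mol⁻¹·e⁻², distance-dependent dielectric 4r,
and a Born-like self-solvation term (the only solvation dependence is on
the charges, so it cancels in interaction energies but not in charged-state
comparisons). Nonbonded pairs exclude 1-2 and 1-3; 1-4 and beyond interact.
Analytic gradients are provided and checked against central finite
differences at 1e-5; near-collinear torsions get a clamped gradient
(|b₁×b₂|² floored at 1e-6) because the dihedral is undefined there. The
surface is exactly invariant under translation, rotation and relabeling.

**Engine adapter.** Jobs are written in the MOPAC input dialect — `PM7`,
`MOZYME` above 300 atoms, `1SCF`, `CHARGE=n`, `EPS=78.40` (configurable
permittivity), Cartesian geometry with optimization flags 0 — in a frozen
keyword order so output is byte-stable. The parser extracts the final heat
of formation (kcal/mol, includes COSMO solvation), the dielectric energy
(eV, converted at 23.060548 kcal/mol/eV) and the COSMO area; a missing
normal-termination marker flags the job failed. The captured surface area
is metadata only — nothing in the score uses it. The engine binary is
optional; the write→parse path is exercised entirely on bundled text
fixtures.

## Relaxation

The relaxed variants minimize each complex on the toy surface in Cartesian
coordinates with a frozen shell: residues with heavy atoms within 4 Å of
any docked molecule of the library, plus all ligand atoms, move; everything
else is fixed. Five cycles run with a harmonic positional restraint
`w·Σ|x − x_ref|²` on the movable *heavy* atoms (hydrogens are never
restrained) at w = 50, 10, 5, 1, 0 kcal·mol⁻¹·Å⁻², `x_ref` resetting to the
cycle-start coordinates (a flag keeps the original reference instead).
Each cycle runs L-BFGS-B to a gradient norm of 1e-3 kcal·mol⁻¹·Å⁻¹ or 500
iterations; both are configurable, and the tolerance choice is benign
because only energy differences of fully converged single points enter the
score. Unbound reference states (the pocket once per target, each ligand
once per state) are unrestrained local minimizations from the bound
conformation, so deformation penalties are nonnegative whenever the
minimizer descends. A torsional-coordinate receptor treatment would need a
rotamer-tree engine; the frozen-shell Cartesian scheme keeps the same
locality with far less machinery. Backends without gradients report
relaxation as failed rather than approximating it.

## Conformational entropy

`ΔS = −R ln Ω` with R = 1.987e-3 kcal·mol⁻¹·K⁻¹ at T = 298.15 K (default;
the temperature is configurable). Rotatable bonds are non-ring single bonds
between heavy atoms whose both ends carry a further heavy neighbor, minus
amide C–N bonds. The `rot` estimator sets Ω = 3^N; the default `conf`
estimator runs Metropolis Monte-Carlo in torsion space (1000·N steps, one
rotor perturbed per step by a uniform angle, acceptance at 300 K, seed 0 by
default) with an L-BFGS-B minimization of the torsions after every accepted
move, then counts conformers within 3 kcal/mol of the lowest, deduplicated
at a 30° maximum circular torsion deviation. The torsion-space jacobian is
taken numerically through the torsion-setting map because sequentially
applied torsions are coupled coordinates. On chains of independent 3-fold
wells the sampler recovers Ω = 3^N exactly (a parameter-recovery test);
when a frustrated landscape yields Ω < 3^N that is the intended behavior of
the estimator, and Ω > 3^N is logged. Sampling energies come from the
active backend by default, with a config override.

## Hit lists and metrics

One variant's score records collapse to one row per parent molecule: failed
states are dropped (and molecules with no surviving state leave both the
numerator and N_total), the minimum score over surviving states wins, and
ties order lexicographically by parent id so reruns are byte-identical.
`EF(x) = (Hits_x/N_x)/(Hits_total/N_total)` with `N_x = ⌈x·N_total/100⌉` —
the ceiling keeps the top set non-empty for any x > 0 and is declared in
the metrics output; EF(100) is exactly 1. ROC/AUC use scikit-learn's
threshold sweep on negated scores, which credits ties half a pair and
equals the Mann–Whitney statistic; the tests verify both EF and AUC against
independent brute-force oracles at 1e-12. Enrichment curves are the
(% screened, % ligands found) step function. Note one subtlety: deleting a
tail decoy lowers N_total and with it the EF normalization, so EF can dip
by (N−1)/N even though the ranking improved; the top-set ligand fraction is
the monotone quantity.

## Synthetic study system

The generators exist so every stage runs and is testable offline, and they
define the default study conditions:

* **Pocket.** 30 simplified residues (backbone N/CA/C/O plus one
  pseudo-sidechain CB; an 8-residue charge cycle ASP·ALA·LYS·SER·GLU·ALA·
  ARG·SER) along a spherical spiral of radius 8 Å, CB atoms pointing at the
  cavity so the charge rules produce a charged rim. The backbone zig-zags
  25° off the chain tangent, keeping bond angles bent and torsion
  coordinates well defined. Deterministic per seed (spiral phase plus
  0.04 Å jitter).
* **Library.** 20 ligands and 180 decoys of identical size (five-atom rigid
  stars, so their entropy term is exactly zero and the screen stays fast)
  and matched net charge. Ligands park their charged head one LJ minimum
  (3.4 Å) from an oppositely charged rim atom; decoys aim at a like-charged
  rim atom, with the contact distance scaled so the designed mean
  ligand–decoy separation tracks the requested margin (5 kcal/mol default,
  verified numerically in the tests). Three ligands and three decoys are
  emitted as two protonation-like states to exercise state collapsing, and
  one decoy pose deliberately overlaps the pocket to exercise failed-job
  exclusion.
* **Ranked lists.** Binormal score model with ligand scores N(−μ, 1),
  decoy scores N(0, 1), μ = √2·Φ⁻¹(AUC_target); AUC 1.0 uses disjoint
  supports.

What passing on this system shows — and what it does not: the synthetic
pocket has no real chemistry (no aromatics, no hydrogen-bond geometry, no
crystallographic water networks), the separation between ligands and decoys
is designed rather than emergent, and the toy surface is not PM7. The tests
therefore validate the *pipeline* — selection, capping, charge bookkeeping,
component assembly, exclusion rules, metrics — not the physical accuracy of
any particular Hamiltonian. Scoring real targets requires the engine
backend and real docked poses.

## Numerical choices and degenerate inputs

Distance thresholds are inclusive (≤). Bond perception uses 1.25× the sum
of covalent radii, with waters and ions never bonding across residues.
Element inference for PDB files without an element column follows a fixed
rule table; a lone `CA` atom in its own HETATM residue is calcium,
inside an amino acid it is the alpha carbon. Atom overlaps below 0.3 Å fail
the evaluation. Component caching keys on a hash of rounded coordinates
(1e-6 Å), composition, bonding and backend configuration. Problem sizes in
the test suite and acceptance script (20–30 residue pockets, 50–206 pose
libraries, 1000·N MC steps) were chosen as the smallest systems that
exercise every rule with comfortable statistical head-room.

## Known limitations

No protonation/tautomer assignment (inputs must arrive protonated), no
vibrational or receptor conformational entropy, no MD averaging, no
multi-pose consensus, no absolute-affinity calibration, and the engine
adapter implements one input/output dialect. MOL2 pose records contribute
no formal charges (the format carries partial charges); use SDF with charge
blocks when charges matter.
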