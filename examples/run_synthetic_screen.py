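"""End-to-end virtual screen on a synthetic pocket.

Generates a toy binding pocket and a 20-ligand / 180-decoy pose library
with designed energetic separation, rescores every pose with the rigid
(no-relaxation) score variant on the toy backend, and evaluates screening
power. EF(x) is the ligand enrichment in the top x% of the ranked list
relative to random picking; AUC is the probability that a random ligand
outranks a random decoy. The deliberately clashing decoy pose fails its
energy evaluation and is excluded from the totals.
"""

from qmrescore import PipelineConfig, make_library, make_toy_pocket, run_screen
from qmrescore.molio import assign_formal_charges

pocket = make_toy_pocket(seed=0, n_residues=30)
poses, manifest = make_library(
    assign_formal_charges(pocket), seed=0, n_ligands=20, n_decoys=180, margin=5.0
)
config = PipelineConfig(variants=("qmds1",))
result = run_screen(pocket, poses, manifest, config)

metrics = result.metrics["qmds1"]
print(f"library: {len(poses)} pose states, {metrics['N_total']:.0f} molecules ranked")
print(f"failed QM evaluations excluded: {metrics['N_excluded_states']:.0f}")
for key in ("EF1", "EF2", "EF5", "EF10"):
    print(f"{key:>5s} = {metrics[key]:6.2f}   (1 = random, higher = better early enrichment)")
print(f"  AUC = {metrics['AUC']:6.3f}   (0.5 = random, 1.0 = perfect separation)")
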