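"""Build the reduced binding-site system used for all QM evaluations.

Residues with a heavy atom within 8 Angstrom of any docked pose are kept
(union over the library), the selection is defragmented so no one-residue
stubs or small chain gaps remain, and every severed peptide bond is capped
with a hydrogen along the former bond vector.
"""

import numpy as np

from qmrescore import (
    assign_formal_charges,
    build_reduced,
    defragment,
    make_library,
    make_toy_pocket,
    residues_within,
)

pocket = assign_formal_charges(make_toy_pocket(seed=0, n_residues=40, pocket_radius=11.0))
poses, _ = make_library(pocket, seed=0, n_ligands=1, n_decoys=0,
                        n_dual_state=0, include_clash=False)

selected = residues_within(pocket, poses, cutoff=8.0)
print(f"residues within 8 A of any pose: {len(selected)} of {len(pocket.residues())}")

expanded = defragment(selected, pocket, max_gap=2, min_fragment=2)
print(f"after defragmentation: {len(expanded)} residues")

reduced = build_reduced(pocket, expanded)
caps = [i for i, a in enumerate(reduced.system.atoms) if a.record_class == "cap"]
print(f"cluster: {len(reduced.system.atoms)} atoms in {len(reduced.fragments)} fragment(s), "
      f"{len(caps)} cap hydrogens, total charge {reduced.total_charge:+d} e")
for cap_idx in caps:
    host_idx, _ = reduced.cap_provenance[cap_idx]
    host = pocket.atoms[host_idx]
    r = np.linalg.norm(reduced.system.atoms[cap_idx].coords - host.coords)
    print(f"  cap on {host.res_name}{host.res_seq} {host.name}: bond length {r:.3f} A")
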