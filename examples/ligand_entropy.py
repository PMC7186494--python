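"""Conformational-entropy penalty of a flexible ligand.

The score charges every molecule R*T*ln(Omega) for the conformational
freedom it gives up on binding. Omega is estimated two ways: rotamer
counting (3 states per rotatable bond, 3^N) and Monte-Carlo conformer
search in torsion space with a 3 kcal/mol energy window. On a chain with
independent 3-fold torsional wells the two agree exactly; on frustrated
molecules the MC count is lower, which is why it is the default.
"""

from qmrescore import ToyBackend, estimate_entropy
from qmrescore.synthetic import make_torsion_chain

backend = ToyBackend()
for n in (0, 1, 2, 3):
    mol = make_torsion_chain(n)
    rot = estimate_entropy(mol, method="rot")
    conf = estimate_entropy(mol, backend=backend, method="conf", seed=0)
    print(
        f"N={n}: Omega_rot = 3^{n} = {rot.omega:3d}  Omega_conf = {conf.omega:3d}  "
        f"-T*dS = {conf.minus_t_delta_s:.3f} kcal/mol at {conf.temperature} K"
    )
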