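"""Write an external-engine job file and parse an engine output stream.

The engine adapter speaks the MOPAC input dialect: PM7 Hamiltonian, single
SCF, COSMO solvation at water permittivity, explicit total charge, and
Cartesian geometry with optimization flags off. Jobs can be farmed out to
any machine with the engine installed and the outputs parsed afterwards —
no engine binary is needed to run this example.
"""

from qmrescore import BackendConfig, parse_engine_output, write_engine_input
from qmrescore.core import Atom, MolecularSystem

water = MolecularSystem(
    atoms=[
        Atom("O", "O", [0.0, 0.0, 0.0], res_name="HOH", record_class="water"),
        Atom("H", "H1", [0.9572, 0.0, 0.0], res_name="HOH", record_class="water"),
        Atom("H", "H2", [-0.2399, 0.9266, 0.0], res_name="HOH", record_class="water"),
    ],
    bonds=[(0, 1, 1), (0, 2, 1)],
)
print("--- job file ---")
print(write_engine_input(water, BackendConfig()), end="")

# a minimal output stream of the kind the engine writes back
output = """\
          FINAL HEAT OF FORMATION =        -57.79930 KCAL/MOL =    -241.83227 KJ/MOL
          COSMO AREA              =        194.57 SQUARE ANGSTROMS
          DIELECTRIC ENERGY       =         -0.42158 EV
 == MOPAC DONE ==
"""
result = parse_engine_output(output)
print("--- parsed ---")
print(f"status     {result.status}")
print(f"total      {result.total:.5f} kcal/mol (includes solvation)")
print(f"solvation  {result.solvation:.5f} kcal/mol (dielectric energy, eV -> kcal/mol)")
print(f"SASA       {result.sasa:.2f} A^2")
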