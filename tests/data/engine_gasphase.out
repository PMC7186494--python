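                 PM7 CALCULATION RESULTS

 *  PM7      - The PM7 Hamiltonian to be used
 *  1SCF     - DO 1 SCF AND THEN STOP
 *  CHARGE=0 - CHARGE ON SYSTEM = 0

          FINAL HEAT OF FORMATION =       -123.45678 KCAL/MOL =    -516.54317 KJ/MOL

          SCF CALCULATIONS        =          1

 == MOPAC DONE ==
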