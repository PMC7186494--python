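 *******************************************************************************
 ** Site#: 0         For non-commercial use only    Version 22.1.0 64BITS     **
 *******************************************************************************

                 PM7 CALCULATION RESULTS

 *  PM7      - The PM7 Hamiltonian to be used
 *  1SCF     - DO 1 SCF AND THEN STOP

       SCF FIELD WAS NOT ACHIEVED AFTER 2000 ITERATIONS
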