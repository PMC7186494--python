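 *******************************************************************************
 ** Site#: 0         For non-commercial use only    Version 22.1.0 64BITS     **
 *******************************************************************************
 ** Cite this program as: ...                                                 **
 *******************************************************************************

                 PM7 CALCULATION RESULTS

 *  PM7      - The PM7 Hamiltonian to be used
 *  1SCF     - DO 1 SCF AND THEN STOP
 *  CHARGE=0 - CHARGE ON SYSTEM = 0
 *  EPS=78.40- USE ANDREAS KLAMT'S COSMO IMPLICIT SOLVATION MODEL

          FINAL HEAT OF FORMATION =        -57.79930 KCAL/MOL =    -241.83227 KJ/MOL

          COSMO AREA              =        194.57 SQUARE ANGSTROMS
          COSMO VOLUME            =        221.84 CUBIC ANGSTROMS

          DIELECTRIC ENERGY       =         -0.42158 EV

          IONIZATION POTENTIAL    =         10.825462 EV
          HOMO LUMO ENERGIES (EV) =        -10.825  2.669
          NO. OF FILLED LEVELS    =          4
          MOLECULAR WEIGHT        =         18.0153

          SCF CALCULATIONS        =          1

          WALL-CLOCK TIME         =          0.041 SECONDS
          COMPUTATION TIME        =          0.040 SECONDS

 == MOPAC DONE ==
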