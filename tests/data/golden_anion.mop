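PM7 1SCF CHARGE=-1 EPS=78.40
qmrescore single-point job

Cl       0.000000 0       0.000000 0       0.000000 0
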