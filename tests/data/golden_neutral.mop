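PM7 1SCF CHARGE=0 EPS=78.40
qmrescore single-point job

O        0.000000 0       0.000000 0       0.000000 0
H        0.957200 0       0.000000 0       0.000000 0
H       -0.239900 0       0.926600 0       0.000000 0
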