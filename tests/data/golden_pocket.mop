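PM7 1SCF CHARGE=0 EPS=78.40
qmrescore single-point job

N       -5.113219 0      -3.733331 0       4.593990 0
C       -4.278088 0      -4.943064 0       4.592807 0
C       -3.408870 0      -6.202175 0       4.591577 0
O       -4.067502 0      -6.963183 0       5.298662 0
C       -3.458813 0      -3.996444 0       3.713263 0
N       -1.711722 0      -6.055818 0       3.516705 0
C       -0.787000 0      -7.195467 0       3.433106 0
C        0.612119 0      -7.783637 0       3.239655 0
O        0.491287 0      -8.888384 0       3.766753 0
C       -0.636698 0      -5.821269 0       2.777448 0
N        1.954344 0      -6.573542 0       2.270360 0
C        3.333061 0      -7.017757 0       2.019936 0
C        4.801783 0      -6.760599 0       1.676970 0
O        5.312495 0      -7.835903 0       1.986477 0
C        2.697785 0      -5.680184 0       1.634939 0
N        5.097799 0      -4.982939 0       0.972525 0
C        6.472181 0      -4.613689 0       0.604245 0
C        7.594242 0      -3.674041 0       0.158217 0
O        8.592932 0      -4.385956 0       0.251455 0
C        5.229907 0      -3.728135 0       0.488266 0
N        6.919009 0      -2.005802 0      -0.280633 0
C        7.902901 0      -1.008793 0      -0.726537 0
C        8.340447 0       0.343889 0      -1.291961 0
O        9.555505 0       0.188789 0      -1.403665 0
C        6.391487 0      -0.815863 0      -0.587588 0
N        6.871669 0       1.491954 0      -1.515102 0
C        7.164639 0       2.827830 0      -2.054087 0
C        6.826104 0       4.158750 0      -2.728584 0
O        7.931579 0       4.595072 0      -3.045521 0
C        5.789537 0       2.285087 0      -1.659848 0
N        5.061922 0       4.372371 0      -2.702170 0
C        4.610762 0       5.624502 0      -3.326288 0
C        3.592263 0       6.468895 0      -4.094767 0
O        4.301399 0       7.333944 0      -4.606350 0
C        3.728666 0       4.548466 0      -2.689928 0
N        1.929069 0       5.777465 0      -3.858333 0
C        0.858331 0       6.507251 0      -4.552473 0
C       -0.256111 0       7.266825 0      -5.274945 0
O       -0.123942 0       8.268835 0      -5.975951 0
C        0.693926 0       5.260850 0      -3.680490 0
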