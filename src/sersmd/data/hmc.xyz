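33
idealized 5-hydroxymethyl-2'-deoxycytidine (synthetic geometry, MMFF-optimized); Angstrom
C     -0.748451    -0.922463    -0.709849
C     -2.917403    -0.111814    -0.678289
C     -2.604446     0.876639     0.382356
C     -1.353320     0.820829     0.846908
N     -4.188096    -0.210928    -1.181982
N     -0.428392    -0.081220     0.358591
N     -2.042567    -0.933114    -1.169260
H     -4.319396    -1.085134    -1.681266
H     -4.913314    -0.052099    -0.483999
C     -3.636944     1.857797     0.824382
H     -1.015361     1.505933     1.618926
O      0.087816    -1.662203    -1.221981
H     -3.954660     2.486051    -0.014215
H     -3.256153     2.510572     1.617137
H     -5.373738     1.840900     1.689115
O     -4.773785     1.163382     1.329883
C      0.936719    -0.027055     0.874172
H      0.920761     0.542493     1.812666
C      1.628934    -1.355773     1.173518
H      2.057775    -1.327907     2.184017
H      0.964603    -2.225374     1.157472
C      2.736085    -1.433100     0.145552
H      2.414238    -1.962449    -0.755707
O      3.876796    -2.099048     0.667589
H      3.644655    -3.041567     0.749714
C      3.015556     0.033500    -0.146196
H      3.684851     0.471617     0.605347
O      1.750705     0.720590    -0.040676
C      3.597199     0.267405    -1.536757
H      2.913474    -0.082381    -2.317209
H      4.560828    -0.236003    -1.656343
O      3.792541     1.668589    -1.743911
H      2.942488     2.083334    -1.500853
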