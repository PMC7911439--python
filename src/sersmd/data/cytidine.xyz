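29
idealized 2'-deoxycytidine (synthetic geometry, MMFF-optimized); Angstrom
C      1.948480     0.582110    -1.560734
C      3.616691     0.902113     0.008226
C      2.646514     0.956781     1.117182
C      1.366562     0.823846     0.775160
N      4.952504     1.034137     0.269728
N      0.994164     0.648515    -0.538828
N      3.275736     0.723712    -1.228292
H      5.289804     0.646219     1.141332
H      5.519594     0.765810    -0.529678
H      2.981976     1.115413     2.130969
H      0.583823     0.864083     1.524719
O      1.616582     0.387184    -2.728116
C     -0.399860     0.476769    -0.928514
H     -0.598353     1.084964    -1.820389
C     -0.769983    -0.980100    -1.180029
H     -0.293224    -1.633220    -0.439193
H     -0.471261    -1.312504    -2.178749
C     -2.262549    -0.958670    -0.964556
H     -2.677340    -1.948229    -0.753764
O     -2.876764    -0.475568    -2.162066
H     -3.839800    -0.483023    -2.017024
C     -2.421388     0.054045     0.171078
H     -3.332902     0.647596     0.036806
O     -1.290110     0.948175     0.106549
C     -2.435874    -0.601806     1.553422
H     -1.518219    -1.172920     1.731550
H     -2.493530     0.168548     2.330442
O     -3.553338    -1.470123     1.684352
H     -3.557936    -1.793857     2.602772
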