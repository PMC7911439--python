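# topology sidecar for hmc (1-based indices; angles/torsions derived from bonds)
bond 1 6
bond 1 7
bond 1 12
bond 2 3
bond 2 5
bond 2 7
bond 3 4
bond 3 10
bond 4 6
bond 4 11
bond 5 8
bond 5 9
bond 6 17
bond 10 13
bond 10 14
bond 10 16
bond 15 16
bond 17 18
bond 17 19
bond 17 28
bond 19 20
bond 19 21
bond 19 22
bond 22 23
bond 22 24
bond 22 26
bond 24 25
bond 26 27
bond 26 28
bond 26 29
bond 29 30
bond 29 31
bond 29 32
bond 32 33
ring 6 1 7 2 3 4
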