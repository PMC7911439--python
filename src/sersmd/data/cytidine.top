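# topology sidecar for cytidine (1-based indices; angles/torsions derived from bonds)
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
bond 6 13
bond 13 14
bond 13 15
bond 13 24
bond 15 16
bond 15 17
bond 15 18
bond 18 19
bond 18 20
bond 18 22
bond 20 21
bond 22 23
bond 22 24
bond 22 25
bond 25 26
bond 25 27
bond 25 28
bond 28 29
ring 6 1 7 2 3 4
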