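# Class-I intramolecular force-field parameter table for nucleosides and
# graphene, pre-filled with published class-I magnitudes for the atom
# classes present.  Editable plain text.
#
# Conventions:
#   bond     E = k (r - r0)^2 [1 + c3 (r - r0)]      k in kcal/mol/A^2, r0 in A,
#                                                    optional c3 in 1/A (cubic stretch)
#   angle    E = ka (theta - theta0)^2               ka in kcal/mol/rad^2, theta0 in deg
#   torsion  E = (V/2) (1 + cos(n phi - phase))      V in kcal/mol, phase in deg;
#                                                    multiple lines per class quadruple add
#   lj       per-class epsilon (kcal/mol), sigma (A); cross terms by Lorentz-Berthelot
# '*' is a wildcard for the outer classes of angles/torsions.

[bonds]
C2 C2   469.0  1.400
C2 C3   317.0  1.510
C3 C3   310.0  1.526
C2 N2   448.0  1.365
C3 N2   337.0  1.475
C2 O2   570.0  1.229
C3 O3   320.0  1.410
C2 HC   367.0  1.080
C3 HC   340.0  1.090
N2 HN   434.0  1.010
O3 HO   553.0  0.960
CG CG   469.0  1.420

[angles]
*  C2 *   63.0  120.0
*  C3 *   50.0  109.5
*  N2 *   70.0  121.0
*  O3 *   55.0  108.5
CG CG CG  63.0  120.0

[torsions]
* C2 C2 *   7.2  2  180.0
* C2 N2 *   4.8  2  180.0
* C3 C3 *   0.31 3    0.0
* C3 C2 *   0.40 3    0.0
* C3 N2 *   0.30 3    0.0
* C3 O3 *   0.50 3    0.0

[lj]
C2  0.0860  3.400
C3  0.1090  3.400
CG  0.1090  3.400
N2  0.1700  3.250
O2  0.2100  2.960
O3  0.2104  3.070
HC  0.0157  2.500
HN  0.0157  1.200
HO  0.0010  1.000
P   0.2000  3.740
AU  0.0390  2.900
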