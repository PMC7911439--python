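"""Unit system and physical constants.

Internal units throughout the package:

==========  =========================
quantity    unit
==========  =========================
length      angstrom (Å)
time        femtosecond (fs)
mass        atomic mass unit (amu)
energy      kcal/mol
velocity    Å/fs
force       kcal/mol/Å
==========  =========================

Frequencies are carried in THz internally and converted to wavenumbers
(cm^-1) only at the reporting boundary, so the conversion constant lives in
exactly one place.
"""

# Boltzmann constant, kcal/mol/K
KB = 1.987204259e-3

# acceleration conversion: (kcal/mol/Å) / amu -> Å/fs^2
FORCE_TO_ACC = 4.184e-4

# 1 THz expressed in cm^-1 (1e12 Hz / c, c in cm/s)
THZ_TO_CM1 = 33.35641

# 1 eV in kcal/mol (EAM tables are tabulated in eV)
EV_TO_KCALMOL = 23.060548

# Å/ps -> Å/fs (center-of-mass drive velocities are configured in Å/ps)
APS_TO_AFS = 1e-3

ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999,
    "P": 30.973762, "S": 32.06, "Au": 196.966569,
}

# single-bond covalent radii (Å), used only for bond inference on bare inputs
COVALENT_RADII = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66,
    "P": 1.07, "S": 1.05, "Au": 1.36,
}


def thz_to_cm1(f_thz):
    """Convert frequency from THz to wavenumbers (cm^-1)."""
    return f_thz * THZ_TO_CM1


def cm1_to_thz(f_cm1):
    """Convert wavenumbers (cm^-1) to THz."""
    return f_cm1 / THZ_TO_CM1
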