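"""Physical constants and unit conversions.

Internal units are atomic units throughout: energies in hartree, lengths in
bohr, masses in electron masses (m_e), with hbar = 1.  Wavenumbers (cm^-1)
and amu appear only at I/O boundaries.
"""

# CODATA 2018
HARTREE_TO_INVCM = 219474.6313632
INVCM_TO_HARTREE = 1.0 / HARTREE_TO_INVCM

AMU_TO_ME = 1822.888486209  # atomic mass unit in electron masses
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

# Boltzmann constant in cm^-1 / K (k_B T at 300 K ~ 208.5 cm^-1)
KB_INVCM = 0.695034800

# atomic unit of time in femtoseconds
AU_TIME_FS = 0.02418884326509

# Atomic masses (amu) for the elements this package meets in practice.
ATOMIC_MASSES_AMU = {
    "H": 1.00782503207,
    "D": 2.01410177785,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.99491461956,
    "F": 18.99840322,
    "S": 31.97207100,
    "Cl": 34.96885268,
}


def masses_me(elements):
    """Atomic masses in electron masses for a list of element symbols."""
    return [ATOMIC_MASSES_AMU[el] * AMU_TO_ME for el in elements]
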