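"""Physical constants and per-element reference data.

Unit conventions: geometry is Å at the API surface and bohr inside the
integral engine; energies are hartree internally and converted to kcal/mol
only at reporting boundaries (interaction energies, calibration).
"""

# CODATA 2018
BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM
HARTREE_TO_KCALMOL = 627.5094740631

ATOMIC_NUMBERS = {
    "H": 1, "He": 2,
    "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8, "F": 9, "Ne": 10,
    "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15, "S": 16, "Cl": 17,
    "Ar": 18,
}

ELEMENT_SYMBOLS = {z: sym for sym, z in ATOMIC_NUMBERS.items()}

# Standard atomic weights (u), used for centers of mass.
ATOMIC_MASSES = {
    "H": 1.00794, "He": 4.002602,
    "Li": 6.941, "Be": 9.012182, "B": 10.811, "C": 12.0107,
    "N": 14.0067, "O": 15.9994, "F": 18.9984032, "Ne": 20.1797,
    "Na": 22.98976928, "Mg": 24.305, "Al": 26.9815386, "Si": 28.0855,
    "P": 30.973762, "S": 32.065, "Cl": 35.453, "Ar": 39.948,
}

# Frozen-core convention: number of core *orbitals* excluded from the
# correlation treatment (He core for Li-Ne, Ne core for Na-Ar).
CORE_ORBITALS = {z: 0 for z in range(1, 3)}
CORE_ORBITALS.update({z: 1 for z in range(3, 11)})
CORE_ORBITALS.update({z: 5 for z in range(11, 19)})
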