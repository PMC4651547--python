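"""Physical constants and unit conversions used throughout samscan.

All energies are kcal/mol, lengths Å, charges elementary charges (e),
dipoles Debye. Centralizing the conversions keeps every module on the
same footing.
"""

#: Coulomb constant k_e in kcal·Å·mol⁻¹·e⁻² (CHARMM/AMBER convention).
COULOMB_K = 332.0636

#: 1 e·Å expressed in Debye.
EA_TO_DEBYE = 4.8032

#: Energy of a 1 Debye dipole in a 1 V/Å field, in kcal/mol.
#: Fixed by convention to the same numerical value as EA_TO_DEBYE
#: (1 D·V/Å = 0.2082 e·V ≈ 4.80 kcal/mol); documented here once.
DEBYE_FIELD_TO_KCAL = 4.8032

#: Avogadro's number, mol⁻¹.
AVOGADRO = 6.02214076e23

#: Atomic masses (g/mol) for the elements this package encounters.
#: Unknown elements fall back to unit mass.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "FE": 55.845,
    "NI": 58.693,
    "MG": 24.305,
    "ZN": 65.38,
    "AU": 196.967,
    "SE": 78.971,
}


def element_mass(element: str) -> float:
    """Atomic mass of *element* in g/mol; 1.0 if unknown or empty."""
    return ATOMIC_MASSES.get(element.strip().upper(), 1.0)
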