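"""Frozen physical constants used across the package."""

# Standard atomic weights (g/mol), frozen to four decimal places.
ATOMIC_WEIGHTS = {
    "H": 1.0079,
    "C": 12.0107,
    "N": 14.0067,
    "O": 15.9994,
    "S": 32.0650,
    "Na": 22.9898,
    "P": 30.9738,
}

# Adduct mass additions for ESI m/z arithmetic.
ADDUCT_MASSES = {
    "+H": ATOMIC_WEIGHTS["H"],
    "+Na": ATOMIC_WEIGHTS["Na"],
    "+2Na": 2 * ATOMIC_WEIGHTS["Na"],
}

THREE_LETTER = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
ONE_LETTER = {v: k for k, v in THREE_LETTER.items()}
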