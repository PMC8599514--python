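"""Physical constants and per-residue reference tables.

All tables are keyed by one-letter amino-acid codes and cover the 20
standard residue types.  Masses are *average* (isotope-abundance-weighted)
residue masses in g/mol, i.e. the mass contributed by a residue inside a
chain; a free peptide adds one water.  Random-coil chemical shifts are the
Wishart et al. (1995) aqueous GGXGG values, the usual baseline for
chemical-shift-deviation analysis; cysteine uses the reduced form.
"""

from __future__ import annotations

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

WATER_MASS = 18.0153  # g/mol
DISULFIDE_MASS_LOSS = 2.016  # 2 H removed per S-S bridge, g/mol

#: Average residue (chain) masses, g/mol.
RESIDUE_MASS = {
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155,
    "F": 147.1766, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "K": 128.1741, "L": 113.1594, "M": 131.1926, "N": 114.1038,
    "P": 97.1167, "Q": 128.1307, "R": 156.1875, "S": 87.0782,
    "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}

#: Eisenberg consensus hydrophobicity scale (dimensionless).
EISENBERG_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

#: Coarse polarity classes used for amphipathicity summaries and colouring.
POLARITY_CLASS = {
    "A": "hydrophobic", "V": "hydrophobic", "L": "hydrophobic",
    "I": "hydrophobic", "M": "hydrophobic", "F": "hydrophobic",
    "W": "hydrophobic", "Y": "hydrophobic",
    "S": "polar", "T": "polar", "N": "polar", "Q": "polar", "H": "polar",
    "K": "cationic", "R": "cationic",
    "D": "anionic", "E": "anionic",
    "G": "glycine", "C": "cysteine", "P": "proline",
}

#: Random-coil 1H chemical shifts (ppm), Wishart et al. (1995), water,
#: GGXGG peptides; reduced cysteine.  Proline has no amide proton.
RANDOM_COIL_HN = {
    "A": 8.24, "C": 8.32, "D": 8.34, "E": 8.42, "F": 8.30,
    "G": 8.33, "H": 8.42, "I": 8.00, "K": 8.29, "L": 8.16,
    "M": 8.28, "N": 8.40, "P": None, "Q": 8.32, "R": 8.23,
    "S": 8.31, "T": 8.15, "V": 8.03, "W": 8.25, "Y": 8.12,
}

RANDOM_COIL_HA = {
    "A": 4.32, "C": 4.55, "D": 4.64, "E": 4.35, "F": 4.62,
    "G": 3.96, "H": 4.73, "I": 4.17, "K": 4.32, "L": 4.34,
    "M": 4.48, "N": 4.74, "P": 4.42, "Q": 4.34, "R": 4.34,
    "S": 4.47, "T": 4.35, "V": 4.12, "W": 4.66, "Y": 4.55,
}

#: Standard pseudoatom upper-bound corrections (Wuthrich), Angstrom.
PSEUDOATOM_CORRECTION = {
    "methylene": 1.0,
    "methyl": 1.0,
    "isopropyl": 2.4,
    "aromatic-ring": 2.0,
}

#: Amide-proton CSD -> hydrogen-bond-length model, delta = A * d**-3 - B.
HBOND_MODEL_A = 19.2  # ppm * A^3
HBOND_MODEL_B = 2.3   # ppm

THREE_TO_ONE = {
    "ALA": "A", "CYS": "C", "ASP": "D", "GLU": "E", "PHE": "F",
    "GLY": "G", "HIS": "H", "ILE": "I", "LYS": "K", "LEU": "L",
    "MET": "M", "ASN": "N", "PRO": "P", "GLN": "Q", "ARG": "R",
    "SER": "S", "THR": "T", "VAL": "V", "TRP": "W", "TYR": "Y",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
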