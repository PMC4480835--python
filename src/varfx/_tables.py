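"""Amino-acid property tables used by the built-in feature providers.

All tables cover exactly the 20 canonical residues (one-letter codes).
Scales:

* ``HYDROPHOBICITY`` — Kyte–Doolittle hydropathy index (range −4.5 … +4.5).
* ``CHARGE`` — formal side-chain charge at physiological pH; His is
  assigned +0.1 to reflect partial protonation.
* ``VOLUME`` — residue volumes in Å³ (Zamyatnin-style scale).
* ``POLARITY`` — Grantham polarity.
* ``HELIX_PROPENSITY`` — Chou–Fasman alpha-helix propensity P(a).

``contact_potential_table`` builds a symmetric 20×20 pairwise contact
potential from the hydropathy scale via the one-term eigen-approximation
e(i,j) = −(h_i + h_j)/9, which reproduces the dominant additive structure of
statistical contact-energy matrices.  Any user-supplied symmetric 20×20
table can be used in its place.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

HYDROPHOBICITY = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

CHARGE = {
    "A": 0.0, "R": 1.0, "N": 0.0, "D": -1.0, "C": 0.0,
    "Q": 0.0, "E": -1.0, "G": 0.0, "H": 0.1, "I": 0.0,
    "L": 0.0, "K": 1.0, "M": 0.0, "F": 0.0, "P": 0.0,
    "S": 0.0, "T": 0.0, "W": 0.0, "Y": 0.0, "V": 0.0,
}

VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

POLARITY = {
    "A": 8.1, "R": 10.5, "N": 11.6, "D": 13.0, "C": 5.5,
    "Q": 10.5, "E": 12.3, "G": 9.0, "H": 10.4, "I": 5.2,
    "L": 4.9, "K": 11.3, "M": 5.7, "F": 5.2, "P": 8.0,
    "S": 9.2, "T": 8.6, "W": 5.4, "Y": 6.2, "V": 5.9,
}

HELIX_PROPENSITY = {
    "A": 1.42, "R": 0.98, "N": 0.67, "D": 1.01, "C": 0.70,
    "Q": 1.11, "E": 1.51, "G": 0.57, "H": 1.00, "I": 1.08,
    "L": 1.21, "K": 1.16, "M": 1.45, "F": 1.13, "P": 0.57,
    "S": 0.77, "T": 0.83, "W": 1.08, "Y": 0.69, "V": 1.06,
}

#: curated AAindex-style per-residue scales exposed by name
AAINDEX_SCALES = {
    "hydropathy_kd": HYDROPHOBICITY,
    "polarity_grantham": POLARITY,
    "helix_chou_fasman": HELIX_PROPENSITY,
}


def contact_potential_table() -> np.ndarray:
    """Symmetric 20x20 contact potential, hydropathy eigen-approximation."""
    h = np.array([HYDROPHOBICITY[a] for a in AMINO_ACIDS])
    return -(h[:, None] + h[None, :]) / 9.0


def validate_contact_table(table: np.ndarray) -> np.ndarray:
    table = np.asarray(table, dtype=float)
    if table.shape != (20, 20):
        raise ValueError(f"contact potential table must be 20x20, got {table.shape}")
    if not np.allclose(table, table.T):
        raise ValueError("contact potential table must be symmetric")
    return table
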