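"""Per-residue physical property tables used by the coarse design energy.

All tables cover the 20 standard amino acids, one-letter codes in
:data:`AMINO_ACIDS` order.

``RESIDUE_VOLUME`` holds mean residue volumes in cubic angstroms
(Zamyatnin-type consensus values, as tabulated across protein-volume
surveys).  ``KYTE_DOOLITTLE`` is the standard hydropathy scale.  The
contact potential, burial terms and secondary-structure propensities are
knowledge-based-style tables derived from these scales; only their
orderings (hydrophobic pairing favourable, helix breakers penalised, and
so on) are meaningful, and nothing downstream asserts their magnitudes.
"""

from __future__ import annotations

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

# Mean residue volumes, A^3.
RESIDUE_VOLUME = {
    "A": 88.6, "R": 173.4, "N": 114.1, "D": 111.1, "C": 108.5,
    "Q": 143.8, "E": 138.4, "G": 60.1, "H": 153.2, "I": 166.7,
    "L": 166.7, "K": 168.6, "M": 162.9, "F": 189.9, "P": 112.7,
    "S": 89.0, "T": 116.1, "W": 227.8, "Y": 193.6, "V": 140.0,
}

# Kyte-Doolittle hydropathy (positive = hydrophobic).
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Residues counted as polar/charged for buried-polar conflict detection.
POLAR_RESIDUES = frozenset("DEKRNQH")


def contact_potential() -> np.ndarray:
    """Symmetric 20x20 contact potential (dimensionless, lower = better).

    ``P[a, b] = -(h_a + h_b) / 4`` on the hydropathy scale, so burying a
    pair of hydrophobic residues against each other is favourable and
    pairing exposed-charge residues in the core is penalised.
    """
    h = np.array([KYTE_DOOLITTLE[aa] for aa in AMINO_ACIDS])
    return -(h[:, None] + h[None, :]) / 4.0


def burial_term() -> dict[str, np.ndarray]:
    """Per-burial-class, per-residue transfer-style term (lower = better)."""
    h = np.array([KYTE_DOOLITTLE[aa] for aa in AMINO_ACIDS])
    return {
        "core": -h / 2.0,
        "boundary": np.zeros_like(h),
        "surface": h / 4.0,
    }


_HELIX_FORMERS = set("ALMEKRQI")
_STRAND_FORMERS = set("VIYFWT")


def ss_propensity() -> dict[str, np.ndarray]:
    """Per-element-kind, per-residue propensity (lower = better)."""
    helix = np.zeros(20)
    strand = np.zeros(20)
    for aa, i in AA_INDEX.items():
        if aa in _HELIX_FORMERS:
            helix[i] = -0.5
        if aa in _STRAND_FORMERS:
            strand[i] = -0.5
        if aa == "G":
            helix[i] = 0.5
            strand[i] = 0.5
        if aa == "P":
            helix[i] = 2.0
            strand[i] = 2.0
    return {"helix": helix, "strand": strand}
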