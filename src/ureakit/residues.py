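"""Amino-acid constant tables: naming, polarity, similarity classes, radii.

Radii are Bondi van der Waals radii (Å). Maximum accessible surface areas
are the theoretical Gly-X-Gly tripeptide values of Tien et al. (2013);
sidechain maxima are the residue totals minus the glycine total (backbone
contribution), floored at a small positive value.
"""

from __future__ import annotations

__all__ = [
    "AMINO_ACIDS",
    "THREE_TO_ONE",
    "ONE_TO_THREE",
    "POLAR_RESIDUES",
    "SIMILARITY_CLASSES",
    "VDW_RADII",
    "MAX_ASA_TOTAL",
    "MAX_ASA_SIDECHAIN",
    "one_letter",
    "three_letter",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Sidechains able to donate or accept a hydrogen bond with a urea molecule.
#: Trp is included for its indole NH; Gly (no sidechain) is not.
POLAR_RESIDUES = frozenset("STCYNQDEKRHW")

#: Fixed physicochemical groupings for the optional similarity conservation
#: mode (aliphatic, aromatic, basic, acidic, hydroxyl, amide, small, Cys, Pro).
SIMILARITY_CLASSES = (
    frozenset("ILVM"),
    frozenset("FWY"),
    frozenset("KRH"),
    frozenset("DE"),
    frozenset("ST"),
    frozenset("NQ"),
    frozenset("AG"),
    frozenset("C"),
    frozenset("P"),
)

#: Bondi (1964) van der Waals radii, Å.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
    "SE": 1.90,
}

#: Theoretical maximum ASA (Å², Gly-X-Gly, Tien et al. 2013).
MAX_ASA_TOTAL = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
}

_GLY_BACKBONE = MAX_ASA_TOTAL["GLY"]
MAX_ASA_SIDECHAIN = {
    name: max(total - _GLY_BACKBONE, 25.0) for name, total in MAX_ASA_TOTAL.items()
}
# Glycine exposure is judged on its Calpha (see structure.cavity_exposed);
# normalise it against a modest alpha-carbon reference area.
MAX_ASA_SIDECHAIN["GLY"] = 45.0


def one_letter(name: str) -> str:
    """Resolve a 1- or 3-letter residue name to its 1-letter code."""
    name = name.strip().upper()
    if len(name) == 1:
        if name not in ONE_TO_THREE:
            raise KeyError(f"unknown residue {name!r}")
        return name
    if name in THREE_TO_ONE:
        return THREE_TO_ONE[name]
    raise KeyError(f"unknown residue {name!r}")


def three_letter(name: str) -> str:
    """Resolve a 1- or 3-letter residue name to its 3-letter code."""
    name = name.strip().upper()
    if len(name) == 3 and name in THREE_TO_ONE:
        return name
    if len(name) == 1 and name in ONE_TO_THREE:
        return ONE_TO_THREE[name]
    raise KeyError(f"unknown residue {name!r}")
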